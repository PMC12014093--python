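import itertools
import random
from fractions import Fraction

import pytest

from heddc.exact import (
    CostParams,
    OracleLimitError,
    SearchLimits,
    build_cost_tables,
    exact_eddc,
    prune_rules,
    read_cost_table_tsv,
    successors,
    weighted_levenshtein,
    write_cost_table_tsv,
)
from heddc.units import EPSILON, UnitSet


def dijkstra_eddc(s: str, t: str, units: UnitSet, max_len: int) -> Fraction:
    """Uniform-cost enumeration over the full move graph: no heuristic, no
    upper-bound pruning.  Independent cross-check for the best-first oracle
    (usable only on tiny strings)."""
    import heapq

    from heddc.exact import _moves

    params = CostParams()
    hcosts = [params.half_unit(u) for u in units]
    ph = (2, 2, 2)
    dist = {s: 0}
    heap = [(0, s)]
    while heap:
        g, w = heapq.heappop(heap)
        if g > dist.get(w, 1 << 60):
            continue
        if w == t:
            return Fraction(g, 2)
        for _, _, _, hc, w2 in _moves(w, units.seqs, hcosts, ph):
            if len(w2) > max_len:
                continue
            g2 = g + hc
            if g2 < dist.get(w2, 1 << 60):
                dist[w2] = g2
                heapq.heappush(heap, (g2, w2))
    raise AssertionError("target unreachable")


class TestSuccessors:
    def test_duplication_and_contraction(self, aaag_ag):
        succ = successors("AG", aaag_ag)
        assert (
            any(
                op.kind == "duplicate_unit" and res == "AGAG" and op.cost == 1
                for op, res in succ
            )
        )
        succ2 = successors("AGAG", aaag_ag)
        assert any(
            op.kind == "contract_unit" and res == "AG" and op.cost == 1
            for op, res in succ2
        )

    def test_empty_string_has_only_insertions(self, aaag_ag):
        succ = successors("", aaag_ag)
        assert len(succ) == 4
        assert all(op.kind == "insert" for op, _ in succ)

    def test_neighbor_counts(self, aaag_ag):
        succ = successors("AAAG", aaag_ag)
        kinds = [op.kind for op, _ in succ]
        assert kinds.count("substitute") == 3 * 4
        assert kinds.count("insert") == 4 * 5
        assert kinds.count("delete") == 4
        # one AAAG occurrence and one internal AG occurrence
        assert kinds.count("duplicate_unit") == 2


class TestWeightedLevenshtein:
    @pytest.mark.parametrize(
        "s,t,expected",
        [("AAAG", "AG", 2), ("AG", "AG", 0), ("AG", "", 2), ("", "", 0)],
    )
    def test_defaults(self, s, t, expected):
        assert weighted_levenshtein(s, t) == expected

    def test_matches_edlib_on_random_strings(self):
        import edlib

        rng = random.Random(3)
        for _ in range(25):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
            t = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 12)))
            expected = (
                edlib.align(s, t, task="distance")["editDistance"]
                if s and t
                else len(s) + len(t)
            )
            assert weighted_levenshtein(s, t) == expected

    def test_non_half_integer_cost_rejected(self):
        with pytest.raises(ValueError, match="half-integer"):
            weighted_levenshtein("A", "G", CostParams(c_sub=Fraction(1, 3)))


class TestExactOracle:
    def test_identity_and_symmetry(self, aaag_ag):
        strings = ["", "A", "AG", "GA", "AAG", "AGAG", "AAAG"]
        for s, t in itertools.combinations(strings, 2):
            a, _ = exact_eddc(s, t, aaag_ag)
            b, _ = exact_eddc(t, s, aaag_ag)
            assert a == b > 0
        for s in strings:
            c, script = exact_eddc(s, s, aaag_ag)
            assert c == 0 and script == []

    def test_triangle_inequality(self, aaag_ag):
        rng = random.Random(11)
        strings = ["".join(rng.choice("AG") for _ in range(rng.randint(0, 5)))
                   for _ in range(6)]
        d = {}
        for s, t in itertools.combinations_with_replacement(strings, 2):
            d[(s, t)] = d[(t, s)] = exact_eddc(s, t, aaag_ag)[0]
        for a, b, c in itertools.permutations(strings, 3):
            assert d[(a, c)] <= d[(a, b)] + d[(b, c)]

    def test_bounded_by_levenshtein(self, aaag_ag):
        rng = random.Random(5)
        for _ in range(20):
            s = "".join(rng.choice("AG") for _ in range(rng.randint(0, 6)))
            t = "".join(rng.choice("AG") for _ in range(rng.randint(0, 6)))
            assert exact_eddc(s, t, aaag_ag)[0] <= weighted_levenshtein(s, t)

    def test_contraction_closed_form(self, aaag_ag):
        # (alpha)^k -> alpha by k-1 contractions at |alpha|/2 each; no
        # cheaper script exists because every op sheds at most 2*cost bases
        for alpha in aaag_ag.seqs:
            for k in range(1, 6):
                c, _ = exact_eddc(alpha * k, alpha, aaag_ag)
                assert c == Fraction((k - 1) * len(alpha), 2)

    def test_two_contractions(self, aaag_ag):
        c, script = exact_eddc("AAAG" * 3, "AAAG", aaag_ag)
        assert c == 4
        assert [op.kind for op in script] == ["contract_unit"] * 2

    def test_matches_uniform_cost_enumeration(self):
        U = UnitSet(["AG"])
        rng = random.Random(23)
        pairs = set()
        while len(pairs) < 40:
            s = "".join(rng.choice("AG") for _ in range(rng.randint(0, 5)))
            t = "".join(rng.choice("AG") for _ in range(rng.randint(0, 5)))
            pairs.add((s, t))
        for s, t in sorted(pairs):
            fast, script = exact_eddc(s, t, U)
            slow = dijkstra_eddc(s, t, U, max_len=len(s) + len(t) + 4)
            assert fast == slow, (s, t)
            assert sum(op.cost for op in script) == fast

    def test_script_replays_to_target(self, aaag_ag):
        s, t = "AAAGAAAG", "AGAG"
        cost, script = exact_eddc(s, t, aaag_ag)
        w = s
        for op in script:
            p = op.position
            if op.kind == "substitute":
                w = w[:p] + op.payload + w[p + 1 :]
            elif op.kind == "insert":
                w = w[:p] + op.payload + w[p:]
            elif op.kind == "delete":
                w = w[:p] + w[p + 1 :]
            elif op.kind == "duplicate_unit":
                u = op.payload.seq
                assert w[p : p + len(u)] == u
                w = w[: p + len(u)] + u + w[p + len(u) :]
            else:
                u = op.payload.seq
                assert w[p : p + 2 * len(u)] == u + u
                w = w[:p] + w[p + len(u) :]
        assert w == t
        assert sum(op.cost for op in script) == cost

    def test_expansion_budget_error(self, aaag_ag):
        with pytest.raises(OracleLimitError, match="expansions"):
            exact_eddc(
                "AAAG" * 5,
                "AG" * 9,
                aaag_ag,
                limits=SearchLimits(max_expansions=0),
            )

    def test_max_len_validation(self, aaag_ag):
        with pytest.raises(ValueError, match="max_len"):
            exact_eddc("AAAG", "AG", aaag_ag, limits=SearchLimits(max_len=2))


class TestCostTables:
    def test_known_entries(self, aaag_ag, aaag_ag_table):
        t = aaag_ag_table
        assert t.cost2("AAAG", "AG", "AAAG") == 1  # contract the inner AGAG
        assert t.cost1("AG", EPSILON) == 2  # two deletions, nothing cheaper
        assert t.cost1("AAAG", "AG") == 2

    def test_invariants(self, aaag_ag, aaag_ag_table):
        t = aaag_ag_table
        seqs = aaag_ag.seqs
        for x in seqs:
            assert t.cost1(x, x) == 0
            assert t.cost1(x, EPSILON) <= len(x)
            for z in seqs:
                assert t.cost1(x, z) == t.cost1(z, x)
                assert t.cost1(x, z) >= 0
        # two-step realization can never undercut a table entry
        for x in seqs:
            for y in seqs:
                for z in list(seqs) + [EPSILON]:
                    for p in seqs:
                        for q in seqs:
                            assert (
                                t.cost2(x, y, z)
                                <= t.cost1(x, p) + t.cost1(y, q) + t.cost2(p, q, z)
                            )

    def test_pruning_keeps_unbeaten_rule(self, aaag_ag, aaag_ag_table):
        pruned = prune_rules(aaag_ag_table, aaag_ag)
        assert ("AAAG", "AG", "AAAG") in pruned.active_rules

    def test_pruning_keeps_zero_cost_rules(self, aaag_ag, aaag_ag_table):
        pruned = prune_rules(aaag_ag_table, aaag_ag)
        for x, y, z in aaag_ag_table.all_rules():
            if aaag_ag_table.cost2_half[x][y][z] == 0:
                # equality via another (p,q) needs three zero terms; check
                found_zero_path = any(
                    aaag_ag_table.cost1_half[x][p]
                    + aaag_ag_table.cost1_half[y][q]
                    + aaag_ag_table.cost2_half[p][q][z]
                    == 0
                    for p in aaag_ag.seqs
                    for q in aaag_ag.seqs
                    if (p, q) != (x, y)
                )
                assert found_zero_path or (x, y, z) in pruned.active_rules

    def test_augmented_set_prunes_something(self, aaag_ag_aag, aaag_ag_aag_table):
        pruned = prune_rules(aaag_ag_aag_table, aaag_ag_aag)
        assert len(pruned.active_rules) < len(aaag_ag_aag_table.all_rules())

    def test_tsv_round_trip(self, aaag_ag, aaag_ag_table, tmp_path):
        pruned = prune_rules(aaag_ag_table, aaag_ag)
        p = tmp_path / "costs.tsv"
        write_cost_table_tsv(pruned, p)
        back = read_cost_table_tsv(p)
        assert back.unit_seqs == pruned.unit_seqs
        assert back.cost1_half == pruned.cost1_half
        assert back.cost2_half == pruned.cost2_half
        assert back.active_rules == pruned.active_rules

    def test_oracle_limit_names_offender(self, aaag_ag):
        with pytest.raises(OracleLimitError, match="cost\\("):
            build_cost_tables(
                aaag_ag, limits=SearchLimits(max_expansions=1)
            )


class TestCostParams:
    def test_unit_cost_cap(self):
        params = CostParams(unit_op_cost=lambda u: Fraction(2 * len(u)))
        with pytest.raises(ValueError, match="exceeds"):
            params.half_unit(UnitSet(["AG"])[0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            CostParams(c_sub=Fraction(-1)).half_sub()
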