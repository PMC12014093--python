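"""The unit edit model and an exact EDDC oracle for short strings.

Five edit operations act on nucleotide strings: substitution, insertion and
deletion of single bases (cost 1 each by default), plus *duplication* of a
unit occurrence (``...α... -> ...αα...``) and *contraction* of a doubled
unit (``...αα... -> ...α...``), each costing ``|α|/2`` by default — cheaper
than the equivalent run of single-base edits, reflecting how frequently
replication slippage copies or drops whole units.  The minimum summed cost
over all operation sequences transforming one string into another is the
edit distance with duplication and contraction (EDDC).

The oracle here computes EDDC exactly by best-first (A*) search over string
states, with an admissible heuristic — the indel-weighted alignment bound
``|W| + |t| - 2*LCS(W, t)``, scaled by the worst change-per-cost ratio of
the move set and evaluated with a bit-parallel LCS — plus branch-and-bound
pruning at the weighted-Levenshtein upper bound.  It is
deliberately independent of the dynamic-programming estimator it is used to
validate.  All costs are exact half-integers, carried internally as integer
half-units so every comparison is exact.

The module also builds the per-unit cost tables ``cost(x -> z)`` and
``cost(xy -> z)`` that the estimator's recursion consumes, and prunes
redundant conversion rules from them.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Optional, Sequence

import edlib

from .units import EPSILON, Unit, UnitSet

_INF = 1 << 60


class OracleLimitError(RuntimeError):
    """The exact search exceeded its node or length budget."""


def _as_half(value: Fraction | int | float, what: str) -> int:
    f = Fraction(value)
    half = f * 2
    if half.denominator != 1:
        raise ValueError(f"{what} must be an exact half-integer, got {f}")
    if half < 0:
        raise ValueError(f"{what} must be nonnegative, got {f}")
    return int(half)


def _default_unit_cost(u: Unit) -> Fraction:
    return Fraction(len(u), 2)


@dataclass(frozen=True)
class CostParams:
    """Costs of the five edit operations.

    ``unit_op_cost`` maps a unit to the (shared) cost of duplicating or
    contracting it; the default ``|α|/2`` keeps slippage cheaper than the
    equivalent ``|α|`` single-base edits.  All costs must be nonnegative
    exact half-integers.
    """

    c_sub: Fraction = Fraction(1)
    c_ins: Fraction = Fraction(1)
    c_del: Fraction = Fraction(1)
    unit_op_cost: Callable[[Unit], Fraction] = _default_unit_cost

    def half_sub(self) -> int:
        return _as_half(self.c_sub, "substitution cost")

    def half_ins(self) -> int:
        return _as_half(self.c_ins, "insertion cost")

    def half_del(self) -> int:
        return _as_half(self.c_del, "deletion cost")

    def half_unit(self, u: Unit) -> int:
        c = Fraction(self.unit_op_cost(u))
        if c > len(u):
            raise ValueError(
                f"unit operation cost {c} for {u.seq!r} exceeds |unit|"
            )
        return _as_half(c, f"unit operation cost for {u.seq!r}")


@dataclass(frozen=True)
class EditOp:
    """One edit operation applied at ``position`` of the current string."""

    kind: str  # substitute | insert | delete | duplicate_unit | contract_unit
    position: int
    payload: str | Unit | None
    cost: Fraction


@dataclass(frozen=True)
class SearchLimits:
    """Budgets for the exact search.

    ``max_len`` caps intermediate string lengths (default
    ``|s| + |t| + 2*max_unit_len``); ``max_expansions`` caps the number of
    expanded nodes and ``max_states`` the number of distinct string states
    held in memory; ``upper_bound`` optionally injects a known achievable
    cost to tighten pruning.
    """

    max_len: Optional[int] = None
    max_expansions: int = 2_000_000
    max_states: int = 3_000_000
    upper_bound: Optional[Fraction] = None


def _lev(a: str, b: str) -> int:
    """Plain unit-cost Levenshtein distance (edlib-backed)."""
    if not a or not b:
        return len(a) + len(b)
    return edlib.align(a, b, task="distance")["editDistance"]


def weighted_levenshtein(
    s: str, t: str, params: CostParams | None = None
) -> Fraction:
    """Levenshtein distance with the substitution/indel costs of ``params``."""
    params = params or CostParams()
    cs, ci, cd = params.half_sub(), params.half_ins(), params.half_del()
    n, m = len(s), len(t)
    prev = [j * ci for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * cd] + [0] * m
        si = s[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (0 if si == t[j - 1] else cs),
                prev[j] + cd,
                cur[j - 1] + ci,
            )
        prev = cur
    return Fraction(prev[m], 2)


def _moves(w: str, useqs: Sequence[str], hcosts, params_h):
    """Yield (kind, position, payload, half_cost, result) for every neighbor.

    Deterministic order: substitutions, insertions, deletions, duplications
    (per unit, position ascending), contractions.
    """
    hs, hi, hd = params_h
    n = len(w)
    for i in range(n):
        ch = w[i]
        for b in "ACGT":
            if b != ch:
                yield ("substitute", i, b, hs, w[:i] + b + w[i + 1 :])
    for i in range(n + 1):
        for b in "ACGT":
            yield ("insert", i, b, hi, w[:i] + b + w[i:])
    for i in range(n):
        yield ("delete", i, w[i], hd, w[:i] + w[i + 1 :])
    for ui, u in enumerate(useqs):
        hu = hcosts[ui]
        L = len(u)
        start = w.find(u)
        while start != -1:
            end = start + L
            yield ("duplicate_unit", start, u, hu, w[:end] + u + w[end:])
            if w[end : end + L] == u:
                yield ("contract_unit", start, u, hu, w[:start] + w[end:])
            start = w.find(u, start + 1)


def successors(
    W: str, units: UnitSet, params: CostParams | None = None
) -> list[tuple[EditOp, str]]:
    """All single-edit neighbors of ``W`` with their operations and costs."""
    units = UnitSet.coerce(units)
    params = params or CostParams()
    useqs = units.seqs
    hcosts = [params.half_unit(u) for u in units]
    ph = (params.half_sub(), params.half_ins(), params.half_del())
    out: list[tuple[EditOp, str]] = []
    for kind, pos, payload, hc, w2 in _moves(W, useqs, hcosts, ph):
        if kind in ("duplicate_unit", "contract_unit"):
            payload = units[units.index(payload)]
        out.append((EditOp(kind, pos, payload, Fraction(hc, 2)), w2))
    return out


def _heuristic_factor(units: UnitSet, params: CostParams) -> Fraction | None:
    """Per-change cost ratio making the indel-weighted alignment bound
    admissible.

    The bound is the weighted Levenshtein distance to the target with
    substitution weight 2 and indel weight 1 (in half-cost units), which
    equals ``|W| + |t| - 2*LCS(W, t)`` because a substitution there costs
    exactly one deletion plus one insertion.  A single edit of half-cost
    ``c`` moves that quantity by at most 2 (substitution), 1 (indel) or
    ``|α|`` (unit duplication/contraction), so dividing by the worst
    change-per-half-cost ratio never overestimates the remaining cost.
    Returns None (heuristic disabled) if some string-changing operation is
    free.
    """
    hs, hi, hd = params.half_sub(), params.half_ins(), params.half_del()
    r = Fraction(0)
    for change, h in [(2, hs), (1, hi), (1, hd)] + [
        (len(u), params.half_unit(u)) for u in units
    ]:
        if h == 0:
            return None
        r = max(r, Fraction(change, h))
    return r if r > 0 else None


def _solve4(rows: list[tuple], rhs: list[Fraction]) -> Optional[list[Fraction]]:
    """Solve a 4x4 rational linear system; None if singular."""
    n = 4
    a = [[Fraction(rows[i][j]) for j in range(n)] + [Fraction(rhs[i])]
         for i in range(n)]
    for col in range(n):
        piv = next((r for r in range(col, n) if a[r][col] != 0), None)
        if piv is None:
            return None
        a[col], a[piv] = a[piv], a[col]
        inv = a[col][col]
        a[col] = [x / inv for x in a[col]]
        for r in range(n):
            if r != col and a[r][col] != 0:
                factor = a[r][col]
                a[r] = [x - factor * y for x, y in zip(a[r], a[col])]
    return [a[i][n] for i in range(n)]


_DUAL_CACHE: dict[tuple, tuple] = {}


def _dual_vertices(units: UnitSet, hcosts, hs: int, hi: int, hd: int):
    """Vertices of the dual polytope of the base-composition relaxation.

    Relaxing each edit operation to its effect on the (A, C, G, T) count
    vector gives a min-cost integer program whose LP value lower-bounds the
    true remaining cost.  By LP duality that value is ``max_y y . delta``
    over the polytope ``{y : y . move_vec <= move_cost}``; the polytope is
    bounded (indel constraints box every coordinate), so the maximum is
    attained at a vertex.  Returns integer-scaled vertices and the common
    denominator.
    """
    key = (units.seqs, tuple(hcosts), hs, hi, hd)
    cached = _DUAL_CACHE.get(key)
    if cached is not None:
        return cached
    idx = {c: k for k, c in enumerate("ACGT")}
    cons: list[tuple[tuple, int]] = []  # (coefficients, bound)
    for d in range(4):
        e = [0, 0, 0, 0]
        e[d] = 1
        cons.append((tuple(e), hi))
        e2 = [0, 0, 0, 0]
        e2[d] = -1
        cons.append((tuple(e2), hd))
    for i in range(4):
        for j in range(4):
            if i != j:
                v = [0, 0, 0, 0]
                v[i], v[j] = -1, 1
                cons.append((tuple(v), hs))
    for u, hu in zip(units, hcosts):
        vec = [0, 0, 0, 0]
        for c in u.seq:
            vec[idx[c]] += 1
        cons.append((tuple(vec), hu))
        cons.append((tuple(-x for x in vec), hu))
    vertices: set[tuple] = set()
    ncon = len(cons)
    for combo in itertools.combinations(range(ncon), 4):
        y = _solve4([cons[k][0] for k in combo], [cons[k][1] for k in combo])
        if y is None:
            continue
        if all(
            sum(ci * yi for ci, yi in zip(cvec, y)) <= cb
            for cvec, cb in cons
        ):
            vertices.add(tuple(y))
    denom = 1
    for v in vertices:
        for x in v:
            denom = denom * x.denominator // math.gcd(denom, x.denominator)
    scaled = tuple(
        tuple(int(x * denom) for x in v) for v in sorted(vertices)
    )
    _DUAL_CACHE[key] = (scaled, denom)
    return scaled, denom


def exact_eddc(
    s: str,
    t: str,
    units: UnitSet,
    params: CostParams | None = None,
    limits: SearchLimits | None = None,
    return_script: bool = True,
) -> tuple[Fraction, list[EditOp]]:
    """Exact EDDC between ``s`` and ``t`` and one optimal edit script.

    Best-first search over string states; raises :class:`OracleLimitError`
    when the node budget is exhausted rather than returning an
    approximation.  ``return_script=False`` skips parent bookkeeping (the
    script comes back empty), roughly halving memory on large searches.
    """
    units = UnitSet.coerce(units)
    params = params or CostParams()
    limits = limits or SearchLimits()
    if s == t:
        return Fraction(0), []
    useqs = units.seqs
    hcosts = [params.half_unit(u) for u in units]
    hs, hi, hd = params.half_sub(), params.half_ins(), params.half_del()
    max_len = limits.max_len
    if max_len is None:
        max_len = len(s) + len(t) + 2 * units.max_unit_len
    if max_len < max(len(s), len(t)):
        raise ValueError("max_len must be at least max(|s|, |t|)")

    ub = _as_half(weighted_levenshtein(s, t, params), "upper bound")
    if limits.upper_bound is not None:
        ub = min(ub, _as_half(limits.upper_bound, "upper bound"))

    r_w = _heuristic_factor(units, params)
    if r_w is not None:
        # integer ceil-division constants: ceil(x / (p/q)) == -((-x * q) // p)
        rp, rq = r_w.numerator, r_w.denominator

    # all-even half-costs force every path cost to be even, so odd lower
    # bounds round up by one
    all_even = not any(c & 1 for c in (hs, hi, hd, *hcosts))

    # The move set is closed under inversion (sub<->sub, ins<->del,
    # dup<->contract), so the search runs from both ends and meets in the
    # middle; the backward side charges each generated move at its
    # inverse's cost.  Per-side goal data for the heuristics:
    goals = (t, s)
    goal_masks = []
    goal_counts = []
    for goal in goals:
        masks = {c: 0 for c in "ACGT"}
        for i, c in enumerate(goal):
            masks[c] |= 1 << i
        goal_masks.append(masks)
        goal_counts.append(tuple(goal.count(c) for c in "ACGT"))
    move_costs = ((hs, hi, hd), (hs, hd, hi))  # backward swaps ins/del
    dual = []
    for mc in move_costs:
        verts, denom = _dual_vertices(units, hcosts, *mc)
        dual.append((verts, denom))

    h_caches: tuple[dict[str, int], ...] = ({}, {})

    def H(side: int, w: str) -> int:
        cache = h_caches[side]
        h = cache.get(w)
        if h is not None:
            return h
        h = 0
        if r_w is not None:
            masks = goal_masks[side]
            L = 0
            for c in w:
                y = masks[c] | L
                L = y & ~(y - ((L << 1) | 1))
            bound = len(w) + len(goals[side]) - 2 * bin(L).count("1")
            h = -((-bound * rq) // rp)
        gc = goal_counts[side]
        da = w.count("A") - gc[0]
        dc = w.count("C") - gc[1]
        dg = w.count("G") - gc[2]
        dt = w.count("T") - gc[3]
        verts, denom = dual[side]
        best = 0
        for ya, yc, yg, yt in verts:
            dot = ya * da + yc * dc + yg * dg + yt * dt
            if dot > best:
                best = dot
        hc = best // denom  # floor keeps the LP value a valid lower bound
        if hc > h:
            h = hc
        if all_even and h & 1:
            h += 1
        cache[w] = h
        return h

    best_g: tuple[dict[str, int], ...] = ({s: 0}, {t: 0})
    parents: tuple[dict[str, tuple[str, tuple]], ...] = ({}, {})
    h0 = H(0, s)
    if h0 > ub:  # heuristic is a true lower bound; ub is achievable
        raise AssertionError("admissible heuristic exceeded upper bound")
    # heap entries: (f, -g, w, h_is_exact)
    heaps: tuple[list, ...] = ([(h0, 0, s, True)], [(H(1, t), 0, t, True)])

    mu = _INF  # best known full-path cost and its meeting state
    meet: Optional[str] = None
    expansions = 0
    while heaps[0] or heaps[1]:
        fmin0 = heaps[0][0][0] if heaps[0] else _INF
        fmin1 = heaps[1][0][0] if heaps[1] else _INF
        if mu < _INF and mu <= max(fmin0, fmin1):
            break  # no remaining node can improve on the meeting path
        # expand the side likelier to exhaust first: termination fires as
        # soon as either frontier clears everything cheaper than mu
        if fmin0 >= mu or not heaps[0]:
            side = 1
        elif fmin1 >= mu or not heaps[1]:
            side = 0
        else:
            side = 0 if len(heaps[0]) <= len(heaps[1]) else 1
        my_g, other_g = best_g[side], best_g[1 - side]
        heap = heaps[side]
        f, negg, w, exact_h = heapq.heappop(heap)
        g = -negg
        if g != my_g.get(w, _INF):
            continue
        if not exact_h:
            he = H(side, w)
            if g + he > f:
                heapq.heappush(heap, (g + he, negg, w, True))
                continue
        if f >= mu:
            continue
        expansions += 1
        if expansions > limits.max_expansions:
            raise OracleLimitError(
                f"exact EDDC search exceeded {limits.max_expansions} node "
                f"expansions for |s|={len(s)}, |t|={len(t)}"
            )
        hw = f - g  # admissible lower bound at w (exact when exact_h)
        h_cache = h_caches[side]
        bound = min(ub, mu)
        for kind, pos, payload, hc, w2 in _moves(
            w, useqs, hcosts, move_costs[side]
        ):
            if len(w2) > max_len:
                continue
            g2 = g + hc
            if g2 >= my_g.get(w2, _INF):
                continue
            hb = h_cache.get(w2)
            if hb is None:
                hb = max(0, hw - hc)  # consistency-derived bound
                is_exact = False
            else:
                is_exact = True
            if g2 + hb > bound:
                continue
            if w2 not in my_g and (
                len(best_g[0]) + len(best_g[1]) >= limits.max_states
            ):
                raise OracleLimitError(
                    f"exact EDDC search exceeded {limits.max_states} stored "
                    f"states for |s|={len(s)}, |t|={len(t)}"
                )
            my_g[w2] = g2
            if return_script:
                parents[side][w2] = (w, (kind, pos, payload, hc))
            og = other_g.get(w2)
            if og is not None and g2 + og < mu:
                mu = g2 + og
                meet = w2
                bound = min(bound, mu)
            heapq.heappush(heap, (g2 + hb, -g2, w2, is_exact))
    if meet is None:
        raise OracleLimitError(
            "exact EDDC search exhausted its state space without reaching "
            "the target; max_len is too tight"
        )
    if not return_script:
        return Fraction(mu, 2), []
    return Fraction(mu, 2), _reconstruct_script(
        s, t, meet, parents, units, params
    )


def _reconstruct_script(
    s: str,
    t: str,
    meet: str,
    parents,
    units: UnitSet,
    params: CostParams,
) -> list[EditOp]:
    """Stitch the forward and inverted-backward parent chains into one
    s-to-t edit script through the meeting state."""

    def as_op(kind: str, pos: int, payload, hc: int) -> EditOp:
        if kind in ("duplicate_unit", "contract_unit"):
            payload = units[units.index(payload)]
        return EditOp(kind, pos, payload, Fraction(hc, 2))

    script: list[EditOp] = []
    cur = meet
    while cur != s:
        pw, (kind, pos, payload, hc) = parents[0][cur]
        script.append(as_op(kind, pos, payload, hc))
        cur = pw
    script.reverse()
    # backward chain: each recorded edge applied `kind` to the parent
    # (closer to t) producing the child; the forward script needs the
    # inverse op, whose cost was already charged on generation.
    cur = meet
    while cur != t:
        pw, (kind, pos, payload, hc) = parents[1][cur]
        if kind == "insert":
            inv = ("delete", pos, cur[pos])
        elif kind == "delete":
            inv = ("insert", pos, payload)
        elif kind == "substitute":
            inv = ("substitute", pos, pw[pos])
        elif kind == "duplicate_unit":
            inv = ("contract_unit", pos, payload)
        else:
            inv = ("duplicate_unit", pos, payload)
        script.append(as_op(inv[0], inv[1], inv[2], hc))
        cur = pw
    return script


@dataclass
class UnitCostTable:
    """Precomputed EDDC values between units (and pairs of units) of ``U``.

    ``cost1_half[x][z]`` is ``2 * EDDC(x, z)`` for unit sequences ``x`` and
    ``z`` in ``U`` (plus the empty string as ``z``); ``cost2_half[x][y][z]``
    is ``2 * EDDC(xy, z)``.  ``active_rules`` holds the ``(x, y, z)``
    conversion rules that survive redundancy pruning.
    """

    unit_seqs: tuple[str, ...]
    cost1_half: dict[str, dict[str, int]]
    cost2_half: dict[str, dict[str, dict[str, int]]]
    active_rules: set[tuple[str, str, str]] = field(default_factory=set)

    def cost1(self, x: str, z: str) -> Fraction:
        return Fraction(self.cost1_half[x][z], 2)

    def cost2(self, x: str, y: str, z: str) -> Fraction:
        return Fraction(self.cost2_half[x][y][z], 2)

    def all_rules(self) -> set[tuple[str, str, str]]:
        zs = list(self.unit_seqs) + [EPSILON]
        return {
            (x, y, z)
            for x in self.unit_seqs
            for y in self.unit_seqs
            for z in zs
        }


def build_cost_tables(
    units: UnitSet,
    params: CostParams | None = None,
    limits: SearchLimits | None = None,
) -> UnitCostTable:
    """Exact EDDC tables ``cost(x->z)`` and ``cost(xy->z)`` over ``units``.

    Every entry is computed with the search oracle; targets include the
    empty string.  Oracle budget errors are re-raised naming the offending
    conversion.
    """
    units = UnitSet.coerce(units)
    params = params or CostParams()
    seqs = units.seqs
    targets = list(seqs) + [EPSILON]
    cost1: dict[str, dict[str, int]] = {}
    cost2: dict[str, dict[str, dict[str, int]]] = {}
    for x in seqs:
        cost1[x] = {}
        for z in targets:
            try:
                c, _ = exact_eddc(x, z, units, params, limits)
            except OracleLimitError as e:
                raise OracleLimitError(
                    f"while computing cost({x} -> {z or 'eps'}): {e}"
                ) from e
            cost1[x][z] = _as_half(c, "table entry")
    for x in seqs:
        cost2[x] = {}
        for y in seqs:
            cost2[x][y] = {}
            for z in targets:
                try:
                    c, _ = exact_eddc(x + y, z, units, params, limits)
                except OracleLimitError as e:
                    raise OracleLimitError(
                        f"while computing cost({x}{y} -> {z or 'eps'}): {e}"
                    ) from e
                cost2[x][y][z] = _as_half(c, "table entry")
    table = UnitCostTable(seqs, cost1, cost2)
    table.active_rules = table.all_rules()
    return table


def prune_rules(table: UnitCostTable, units: UnitSet) -> UnitCostTable:
    """Drop conversion rules ``xy -> z`` realisable equally well indirectly.

    A rule is redundant when some other pair ``(p, q) != (x, y)`` satisfies
    ``cost(x->p) + cost(y->q) + cost(pq->z) <= cost(xy->z)``.  With exact
    tables the right-hand side is itself achievable, so equality (not just
    strict excess) marks redundancy; estimator results are unchanged by
    pruning.
    """
    units = UnitSet.coerce(units)
    seqs = table.unit_seqs
    active: set[tuple[str, str, str]] = set()
    c1, c2 = table.cost1_half, table.cost2_half
    for x in seqs:
        for y in seqs:
            for z in list(seqs) + [EPSILON]:
                focal = c2[x][y][z]
                redundant = False
                for p in seqs:
                    for q in seqs:
                        if (p, q) == (x, y):
                            continue
                        if c1[x][p] + c1[y][q] + c2[p][q][z] <= focal:
                            redundant = True
                            break
                    if redundant:
                        break
                if not redundant:
                    active.add((x, y, z))
    return UnitCostTable(seqs, c1, c2, active)


def write_cost_table_tsv(table: UnitCostTable, path) -> None:
    """Serialise a cost table to TSV (costs as numerators over 2)."""
    with open(path, "w") as fh:
        fh.write("# x\ty\tz\thalf_cost\tactive\n")
        for x in table.unit_seqs:
            for z in list(table.unit_seqs) + [EPSILON]:
                fh.write(f"{x}\t-\t{z or 'eps'}\t{table.cost1_half[x][z]}\t1\n")
        for x in table.unit_seqs:
            for y in table.unit_seqs:
                for z in list(table.unit_seqs) + [EPSILON]:
                    act = 1 if (x, y, z) in table.active_rules else 0
                    fh.write(
                        f"{x}\t{y}\t{z or 'eps'}\t"
                        f"{table.cost2_half[x][y][z]}\t{act}\n"
                    )


def read_cost_table_tsv(path) -> UnitCostTable:
    """Read a cost table written by :func:`write_cost_table_tsv`."""
    cost1: dict[str, dict[str, int]] = {}
    cost2: dict[str, dict[str, dict[str, int]]] = {}
    active: set[tuple[str, str, str]] = set()
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            x, y, z, half, act = line.split("\t")
            z = EPSILON if z == "eps" else z
            if x not in order:
                order.append(x)
            if y == "-":
                cost1.setdefault(x, {})[z] = int(half)
            else:
                cost2.setdefault(x, {}).setdefault(y, {})[z] = int(half)
                if act == "1":
                    active.add((x, y, z))
    return UnitCostTable(tuple(order), cost1, cost2, active)
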