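"""The heuristic EDDC estimator over compressed unit sequences.

Two strings are first compressed into optimal unit sequences (see
:mod:`heddc.decomposer`); the distance between the compressed forms is then
computed by a dynamic program that only ever converts unit intervals into
single units, using the precomputed unit cost tables:

``f(w, b, e, z)`` — minimum cost to convert the unit interval ``w[b, e)``
into the single unit ``z`` (or the empty string), built from single-unit
conversions ``cost(w[b] -> z)`` and merges ``cost(xy -> z)``.  The recursive
split point is restricted to the interior of the interval (``b < k < e``);
allowing ``k = e`` with a zero-cost empty right interval would inject a free
phantom unit and make ``f`` underestimate achievable cost.

``dp(i, j)`` — alignment score between prefixes of the two unit sequences:
each aligned block pair is routed through a common unit ``x``, paying
``f(u, p, i, x) + f(v, q, j, x)``.

Both complexity-reduction rewrites are used: an inner minimum over ``y`` is
precomputed per (split, interval, x, z), and the ``dp`` recursion is
evaluated through ``g(p, j, x) = min_q dp(p, q) + f(v, q, j, x)``.  The
result is an upper bound on (and in practice an excellent estimate of) the
true EDDC; distances are also reported normalised by ``|S| * |T|`` so that
alleles of very different lengths remain comparable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .decomposer import Decomposition, decompose
from .exact import CostParams, SearchLimits, UnitCostTable, build_cost_tables
from .units import TRRecord, UnitSet, is_primitive

logger = logging.getLogger(__name__)

_INF = 1 << 60


def _index_tables(units: UnitSet, table: UnitCostTable):
    """Convert string-keyed cost tables to dense index-based lists.

    z-index ``K`` (one past the last unit) denotes the empty string.
    """
    seqs = units.seqs
    if tuple(table.unit_seqs) != tuple(seqs):
        raise ValueError(
            "cost table was built for a different unit set: "
            f"{table.unit_seqs!r} vs {seqs!r}"
        )
    K = len(seqs)
    targets = list(seqs) + [units.epsilon_symbol]
    for x in seqs:
        if units.epsilon_symbol not in table.cost1_half[x]:
            raise ValueError("cost table lacks epsilon targets")
    c1 = [[table.cost1_half[x][z] for z in targets] for x in seqs]
    c2 = [
        [[table.cost2_half[x][y][z] for z in targets] for y in seqs]
        for x in seqs
    ]
    act = [
        [
            [(x, y, z) in table.active_rules for z in targets]
            for y in seqs
        ]
        for x in seqs
    ]
    return K, c1, c2, act


def compute_f(
    w: Sequence[int], units: UnitSet, table: UnitCostTable
) -> list[list[list[int]]]:
    """The interval-conversion table ``f`` for one unit sequence.

    Returns ``F`` with ``F[b][e][z]`` = half-integer cost of converting
    ``w[b, e)`` to target ``z`` (z-index ``len(units)`` is the empty
    string); entries are ``_INF`` where no conversion is derivable.
    """
    units = UnitSet.coerce(units)
    K, c1, c2, act = _index_tables(units, table)
    n = len(w)
    nz = K + 1
    F: list[list[list[int] | None]] = [[None] * (n + 1) for _ in range(n + 1)]
    # inner_min[(k, e)][x][z] = min_y f(w,k,e,y) + cost(xy->z), the first
    # complexity-reduction rewrite.
    inner: dict[tuple[int, int], list[list[int]]] = {}

    def make_inner(b: int, e: int) -> None:
        Fe = F[b][e]
        im = [[_INF] * nz for _ in range(K)]
        for x in range(K):
            c2x = c2[x]
            actx = act[x]
            imx = im[x]
            for y in range(K):
                fy = Fe[y]
                if fy >= _INF:
                    continue
                c2xy = c2x[y]
                actxy = actx[y]
                for z in range(nz):
                    if not actxy[z]:
                        continue
                    v = fy + c2xy[z]
                    if v < imx[z]:
                        imx[z] = v
        inner[(b, e)] = im

    for b in range(n + 1):
        empty = [_INF] * nz
        empty[K] = 0
        F[b][b] = empty
    for b in range(n):
        F[b][b + 1] = list(c1[w[b]])
        make_inner(b, b + 1)
    for L in range(2, n + 1):
        for b in range(n - L + 1):
            e = b + L
            out = [_INF] * nz
            for k in range(b + 1, e):
                Fl = F[b][k]
                im = inner[(k, e)]
                for x in range(K):
                    fx = Fl[x]
                    if fx >= _INF:
                        continue
                    imx = im[x]
                    for z in range(nz):
                        v = fx + imx[z]
                        if v < out[z]:
                            out[z] = v
            F[b][e] = out
            make_inner(b, e)
    return F  # type: ignore[return-value]


def compute_dp(
    u_seq: Sequence[int],
    v_seq: Sequence[int],
    f_u: list[list[list[int]]],
    f_v: list[list[list[int]]],
    units: UnitSet,
    table: UnitCostTable,
) -> list[list[int]]:
    """The prefix-alignment table ``dp`` over two unit sequences.

    ``dp[n][m]`` is the estimated EDDC (in half-units) between the decoded
    sequences.  Evaluated through the ``g``-table rewrite; identical to the
    naive triple-minimum evaluation.
    """
    units = UnitSet.coerce(units)
    K = len(units)
    n, m = len(u_seq), len(v_seq)
    dp = [[_INF] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = 0
    for i in range(1, n + 1):
        dp[i][0] = f_u[0][i][K]
    for j in range(1, m + 1):
        dp[0][j] = f_v[0][j][K]
        # g[p][x] = min_{q<j} dp(p,q) + f(v,q,j,x)
        g = [[_INF] * K for _ in range(n)]
        for p in range(n):
            dpp = dp[p]
            gp = g[p]
            for q in range(j):
                d = dpp[q]
                if d >= _INF:
                    continue
                Fvq = f_v[q][j]
                for x in range(K):
                    v2 = d + Fvq[x]
                    if v2 < gp[x]:
                        gp[x] = v2
        for i in range(1, n + 1):
            best = dp[i][j]
            for p in range(i):
                Fup = f_u[p][i]
                gp = g[p]
                for x in range(K):
                    if Fup[x] >= _INF or gp[x] >= _INF:
                        continue
                    v2 = Fup[x] + gp[x]
                    if v2 < best:
                        best = v2
            dp[i][j] = best
    return dp


@dataclass(frozen=True)
class DPState:
    """The filled dynamic-programming tables for one string pair."""

    f_u: list
    f_v: list
    dp: list


@dataclass(frozen=True)
class HeddcResult:
    """Estimated EDDC between two strings.

    ``raw`` is the distance between the compressed forms; ``normalized``
    divides by ``max(1,|S|) * max(1,|T|)`` (the guards keep degenerate empty
    alleles finite).  The decomposition residues are reported alongside but
    are *not* included in ``raw`` by default: the estimate is a distance
    between the optimal complex tandem repeats, not the raw strings.
    """

    raw: Fraction
    normalized: Fraction
    decomposition_s: Decomposition
    decomposition_t: Decomposition
    state: DPState


def heddc_distance(
    S: str,
    T: str,
    units: UnitSet,
    params: CostParams | None = None,
    table: UnitCostTable | None = None,
    add_residue: bool = False,
) -> HeddcResult:
    """Estimated EDDC between nucleotide strings ``S`` and ``T``.

    ``add_residue=True`` additionally charges both decomposition residues
    at cost 1 per edit (an extension, off by default).
    """
    units = UnitSet.coerce(units)
    params = params or CostParams()
    if table is None:
        table = build_cost_tables(units, params)
    ds = decompose(S, units)
    dt = decompose(T, units)
    f_u = compute_f(ds.unit_seq, units, table)
    f_v = compute_f(dt.unit_seq, units, table)
    dp = compute_dp(ds.unit_seq, dt.unit_seq, f_u, f_v, units, table)
    raw_half = dp[len(ds.unit_seq)][len(dt.unit_seq)]
    if raw_half >= _INF:
        raise RuntimeError("dp table incomplete; cost table may be invalid")
    if add_residue:
        raw_half += 2 * (ds.residue + dt.residue)
    raw = Fraction(raw_half, 2)
    denom = max(1, len(S)) * max(1, len(T))
    return HeddcResult(raw, raw / denom, ds, dt, DPState(f_u, f_v, dp))


def _pure_prefixes(v: str, seqs: Sequence[str]) -> list[bool]:
    """``ok[i]`` iff ``v[0:i)`` is an exact concatenation of units."""
    n = len(v)
    ok = [False] * (n + 1)
    ok[0] = True
    for i in range(1, n + 1):
        for u in seqs:
            L = len(u)
            if L <= i and ok[i - L] and v[i - L : i] == u:
                ok[i] = True
                break
    return ok


def _variant_core(v: str, unit_seq: str, seqs: Sequence[str]) -> str | None:
    """The unit variant hiding in a mismatching span substring.

    Flanks of ``v`` that are exact unit concatenations are already explained
    by the unit set; among all splits ``v = flank . core . flank`` the core
    closest to the assigned unit (then shortest, then lexicographically
    first) is the variant.  Returns None when ``v`` itself is pure over the
    units (no variant to learn).
    """
    from .exact import _lev

    pre = _pure_prefixes(v, seqs)
    suf = _pure_prefixes(v[::-1], [u[::-1] for u in seqs])
    best: tuple[int, int, str] | None = None
    n = len(v)
    for a in range(n + 1):
        if not pre[a]:
            continue
        for b in range(a + 1, n + 1):
            if not suf[n - b]:
                continue
            core = v[a:b]
            key = (_lev(core, unit_seq), len(core), core)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def augment_units(
    records: Sequence[TRRecord],
    units: UnitSet,
    min_count: int = 2,
    max_added: int = 10,
) -> UnitSet:
    """Extend ``units`` with recurrent unit variants observed in ``records``.

    Each record is decomposed; every span whose substring differs from its
    assigned unit contributes one candidate variant: the span's core after
    stripping flanks that are exact unit concatenations, chosen closest to
    the assigned unit (see :func:`_variant_core`).  Primitive candidates
    seen at least ``min_count`` times across records are appended (up to
    ``max_added``), ordered by count descending, then length descending,
    then lexicographically.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    units = UnitSet.coerce(units)
    if max_added <= 0:
        return units
    seqs = units.seqs
    counts: Counter[str] = Counter()
    for rec in records:
        d = decompose(rec.seq, units)
        for sym, (a, b) in zip(d.unit_seq, d.spans):
            segment = rec.seq[a:b]
            if not segment or segment == units[sym].seq:
                continue
            core = _variant_core(segment, units[sym].seq, seqs)
            if core is None or core in units or not is_primitive(core):
                continue
            counts[core] += 1
    ranked = sorted(
        (seg for seg, c in counts.items() if c >= min_count),
        key=lambda seg: (-counts[seg], -len(seg), seg),
    )
    added = ranked[:max_added]
    if not added:
        return units
    logger.info("augmenting unit set with variants: %s", added)
    return units.with_units(added)
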