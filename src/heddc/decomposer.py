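"""Compress a nucleotide string into its best-matching unit-symbol sequence.

Given a unit set ``U``, a string ``S`` is matched against the regular
language ``(u1|...|uk)*`` of all finite unit concatenations.  The optimal
*decomposition* is the concatenation ``V`` minimising the Levenshtein
distance ``Lev(S, V)``; that minimum is the decomposition's *residue* (zero
exactly when ``S`` is a pure complex tandem repeat of ``U``).  The search is
the classic approximate-regular-expression / wraparound dynamic program:
states are (position in S, unit, offset inside unit), with free jumps from
any unit's end to any unit's start, running in ``O(|S| * sum(|u|))``.

Ties between co-optimal decompositions are broken deterministically:

1. fewer unit symbols (or, with ``prefer="most"``, more unit symbols — used
   by unit-variant discovery, which wants discrepancies localised in the
   shortest possible spans);
2. lower unit index in the UnitSet;
3. match over substitution over deletion over insertion in the alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from .units import UnitSet

_INF = 1 << 60

# traceback op codes
_ENTER, _MATCH, _SUB, _DEL, _INS = range(5)


@dataclass(frozen=True)
class Decomposition:
    """An optimal unit-symbol rendering of one string.

    ``unit_seq`` holds unit indices into the UnitSet used; ``spans`` holds
    one half-open interval of the source string per symbol (consecutive,
    covering ``[0, source_len)`` whenever ``unit_seq`` is nonempty);
    ``residue`` is the minimum Levenshtein distance between the source and
    the decoded unit concatenation.
    """

    unit_seq: tuple[int, ...]
    residue: int
    spans: tuple[tuple[int, int], ...]
    source_len: int

    @property
    def is_pure(self) -> bool:
        return self.residue == 0


def decode(d: Decomposition, units: UnitSet) -> str:
    """Concatenate the decoded units of ``d`` in order."""
    units = UnitSet.coerce(units)
    for s in d.unit_seq:
        if not 0 <= s < len(units):
            raise IndexError(f"unit symbol {s} out of range for {units!r}")
    return "".join(units[s].seq for s in d.unit_seq)


def decompose(S: str, units: UnitSet, prefer: str = "fewest") -> Decomposition:
    """Optimal decomposition of ``S`` over ``units``.

    ``prefer`` selects the tie-break among co-optimal decompositions:
    ``"fewest"`` (default) or ``"most"`` unit symbols.
    """
    if prefer not in ("fewest", "most"):
        raise ValueError("prefer must be 'fewest' or 'most'")
    units = UnitSet.coerce(units)
    if len(units) == 0:  # unreachable via UnitSet, kept as a guard
        raise ValueError("unit set must be nonempty")
    useqs = [u.seq for u in units]
    sign = 1 if prefer == "fewest" else -1

    # flat state layout: for unit ui, offsets 0..len(u) map to base[ui]+j
    base: list[int] = []
    nstates = 0
    for u in useqs:
        base.append(nstates)
        nstates += len(u) + 1
    ends = [base[ui] + len(u) for ui, u in enumerate(useqs)]
    state_unit = [0] * nstates
    for ui, u in enumerate(useqs):
        for j in range(len(u) + 1):
            state_unit[base[ui] + j] = ui

    n = len(S)
    INFT = (_INF, _INF)
    # parent[i][sid] = (prev_i, prev_sid, op); prev_sid == -1 marks the
    # initial entry into the first unit.
    parent: list[list[tuple[int, int, int] | None]] = [
        [None] * nstates for _ in range(n + 1)
    ]

    def closure(cur: list[tuple[int, int]], par, i: int) -> None:
        # within-column edges: unit-char insertions (cost 1) and free jumps
        # from any unit end to any unit start.  Two insertion passes around
        # one jump pass reach the full fixpoint (traversing a whole extra
        # unit by insertions can never improve a start state).
        def ins_pass() -> None:
            for ui, u in enumerate(useqs):
                b = base[ui]
                for j in range(1, len(u) + 1):
                    prev_c = cur[b + j - 1]
                    if prev_c[0] >= _INF:
                        continue
                    cand = (prev_c[0] + 1, prev_c[1])
                    if cand < cur[b + j]:
                        cur[b + j] = cand
                        par[b + j] = (i, b + j - 1, _INS)

        ins_pass()
        ebest = INFT
        esid = -1
        for ui in range(len(useqs)):
            if cur[ends[ui]] < ebest:
                ebest = cur[ends[ui]]
                esid = ends[ui]
        if ebest[0] < _INF:
            for ui2 in range(len(useqs)):
                s0 = base[ui2]
                cand = (ebest[0], ebest[1] + sign)
                if cand < cur[s0]:
                    cur[s0] = cand
                    par[s0] = (i, esid, _ENTER)
        ins_pass()

    # column 0: free entry into any unit start
    cur = [INFT] * nstates
    for ui in range(len(useqs)):
        cand = (0, sign)
        if cand < cur[base[ui]]:
            cur[base[ui]] = cand
            parent[0][base[ui]] = (0, -1, _ENTER)
    closure(cur, parent[0], 0)
    prev = cur

    for i in range(1, n + 1):
        c = S[i - 1]
        cur = [INFT] * nstates
        par = parent[i]
        for ui, u in enumerate(useqs):
            b = base[ui]
            for j in range(len(u) + 1):
                sid = b + j
                if j >= 1 and prev[sid - 1][0] < _INF:
                    e0, n0 = prev[sid - 1]
                    if u[j - 1] == c:
                        cand = (e0, n0)
                        op = _MATCH
                    else:
                        cand = (e0 + 1, n0)
                        op = _SUB
                    if cand < cur[sid]:
                        cur[sid] = cand
                        par[sid] = (i - 1, sid - 1, op)
                if prev[sid][0] < _INF:
                    e0, n0 = prev[sid]
                    cand = (e0 + 1, n0)
                    if cand < cur[sid]:
                        cur[sid] = cand
                        par[sid] = (i - 1, sid, _DEL)
        closure(cur, par, i)
        prev = cur

    # accept: empty decomposition (delete all of S) or any unit end.
    best = (n, 0)
    best_sid = -1
    for ui in range(len(useqs)):
        if prev[ends[ui]] < best:
            best = prev[ends[ui]]
            best_sid = ends[ui]

    if best_sid == -1:
        return Decomposition((), n, (), n)

    unit_rev: list[int] = []
    spans_rev: list[tuple[int, int]] = []
    i, sid = n, best_sid
    exit_col = n
    while True:
        pi, psid, op = parent[i][sid]
        if op == _ENTER:
            unit_rev.append(state_unit[sid])
            spans_rev.append((i, exit_col))
            exit_col = i
            if psid == -1:
                break
            sid = psid
        else:
            i, sid = pi, psid
    return Decomposition(
        tuple(reversed(unit_rev)),
        best[0],
        tuple(reversed(spans_rev)),
        n,
    )


def decomposition_notation(d: Decomposition, units: UnitSet) -> str:
    """Repeat notation (e.g. ``(AAAG)2(AG)2``) for a decomposition."""
    from .units import format_repeat_notation

    units = UnitSet.coerce(units)
    return format_repeat_notation([units[s].seq for s in d.unit_seq])
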