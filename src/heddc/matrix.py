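"""Pairwise distance matrices over tandem-repeat allele collections."""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .decomposer import decompose
from .estimator import compute_dp, compute_f
from .exact import CostParams, UnitCostTable, build_cost_tables
from .units import TRRecord, UnitSet


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric raw and normalized distances with a zero diagonal.

    ``normalized[i][j] == raw[i][j] / (max(1, len_i) * max(1, len_j))``.
    """

    ids: tuple[str, ...]
    raw: tuple[tuple[Fraction, ...], ...]
    normalized: tuple[tuple[Fraction, ...], ...]
    lengths: tuple[int, ...]
    residues: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("record ids must be unique")
        for name in ("raw", "normalized"):
            mat = getattr(self, name)
            if len(mat) != n or any(len(row) != n for row in mat):
                raise ValueError(f"{name} matrix must be {n}x{n}")


def pairwise_matrix(
    records: Sequence[TRRecord],
    units: UnitSet,
    params: CostParams | None = None,
    table: UnitCostTable | None = None,
) -> DistanceMatrix:
    """Estimated EDDC between every unordered pair of records.

    Each record is decomposed (and its interval table filled) once; both
    matrix triangles are filled from one computation per pair.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    units = UnitSet.coerce(units)
    params = params or CostParams()
    if table is None:
        table = build_cost_tables(units, params)
    n = len(records)
    decs = []
    fs = []
    for r in records:
        try:
            d = decompose(r.seq, units)
            decs.append(d)
            fs.append(compute_f(d.unit_seq, units, table))
        except Exception as e:  # annotate with the offending record
            raise RuntimeError(f"while decomposing record {r.id!r}: {e}") from e
    raw = [[Fraction(0)] * n for _ in range(n)]
    norm = [[Fraction(0)] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dp = compute_dp(
                    decs[i].unit_seq, decs[j].unit_seq, fs[i], fs[j], units, table
                )
                val = Fraction(dp[len(decs[i].unit_seq)][len(decs[j].unit_seq)], 2)
            except Exception as e:
                raise RuntimeError(
                    f"while computing distance {records[i].id!r} vs "
                    f"{records[j].id!r}: {e}"
                ) from e
            denom = max(1, len(records[i].seq)) * max(1, len(records[j].seq))
            raw[i][j] = raw[j][i] = val
            norm[i][j] = norm[j][i] = val / denom
    return DistanceMatrix(
        tuple(r.id for r in records),
        tuple(tuple(row) for row in raw),
        tuple(tuple(row) for row in norm),
        tuple(len(r.seq) for r in records),
        tuple(d.residue for d in decs),
    )


def _fmt_norm(x: Fraction) -> str:
    return format(float(x), ".10g")


def write_distances_tsv(dm: DistanceMatrix, path, header: Sequence[str] = ()) -> None:
    """TSV with both matrices: raw as exact rationals, normalized to 10 s.f."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# raw\n")
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, rid in enumerate(dm.ids):
            fh.write(rid + "\t" + "\t".join(str(x) for x in dm.raw[i]) + "\n")
        fh.write("# normalized\n")
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for i, rid in enumerate(dm.ids):
            fh.write(
                rid + "\t" + "\t".join(_fmt_norm(x) for x in dm.normalized[i]) + "\n"
            )


def write_phylip(
    dm: DistanceMatrix, path, which: str = "normalized", relaxed: bool = False
) -> None:
    """Square PHYLIP distance matrix (normalized values by default).

    Strict mode truncates names to 10 characters and errors on collisions;
    ``relaxed=True`` keeps full names.
    """
    mat = getattr(dm, which)
    names = list(dm.ids)
    if not relaxed:
        short = [n[:10] for n in names]
        if len(set(short)) != len(short):
            raise ValueError(
                "taxon names collide after truncation to 10 characters; "
                "use relaxed mode"
            )
        names = [n.ljust(10) for n in short]
    with open(path, "w") as fh:
        fh.write(f"{len(names)}\n")
        for name, row in zip(names, mat):
            fh.write(name + "  " + "  ".join(_fmt_norm(x) for x in row) + "\n")


def read_phylip(path) -> tuple[list[str], list[list[float]]]:
    """Read a square PHYLIP distance matrix written by :func:`write_phylip`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    ids: list[str] = []
    mat: list[list[float]] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        ids.append(parts[0])
        mat.append([float(x) for x in parts[1:]])
    if len(mat) != n or any(len(row) != n for row in mat):
        raise ValueError("malformed PHYLIP square matrix")
    return ids, mat
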