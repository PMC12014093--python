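"""Domain types for tandem-repeat units and alleles, plus text-format I/O.

A *unit* (motif) is the building block of a tandem repeat: a short nucleotide
string that is *primitive*, i.e. not itself a whole number (>1) of copies of a
shorter string.  A *complex* tandem repeat concatenates runs of several
different units drawn from a unit set ``U``.  This module provides the unit
predicates used when assembling unit sets (primitivity, bifix-freeness,
rotations), the parenthesised repeat notation ``(AAAG)3(AG)2`` used to write
such repeats compactly, and FASTA readers/writers for collections of alleles.

Coordinates everywhere in this package are 0-based, half-open.  The alphabet
is fixed to ``{A, C, G, T}``; IUPAC ambiguity codes are rejected so that the
edit-operation move set stays finite.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGT")

#: Sentinel for the empty string, the "epsilon" target of unit conversions.
EPSILON = ""


class RepeatNotationError(ValueError):
    """Malformed parenthesised repeat notation."""


class FastaFormatError(ValueError):
    """A FASTA record violates this package's input contract."""


def _check_nucleotides(s: str, what: str) -> None:
    for i, ch in enumerate(s):
        if ch not in ALPHABET:
            raise ValueError(
                f"{what} contains non-ACGT symbol {ch!r} at position {i}"
            )


def is_primitive(u: str) -> bool:
    """True iff ``u`` is not k>1 concatenated copies of a shorter string.

    ``AGAG`` is not primitive (two copies of ``AG``); ``AG`` and every
    single letter are.
    """
    if not u:
        raise ValueError("unit must be nonempty")
    _check_nucleotides(u, "unit")
    n = len(u)
    for d in range(1, n):
        if n % d == 0 and u[:d] * (n // d) == u:
            return False
    return True


def is_bifix_free(u: str) -> bool:
    """True iff no proper prefix of ``u`` equals the same-length suffix.

    Bifix-free units (e.g. ``AAAG``, ``GAAA``) reduce the ambiguity of
    repeat decompositions; ``AAGA`` and ``AGAA`` are not bifix-free.
    """
    if not u:
        raise ValueError("unit must be nonempty")
    _check_nucleotides(u, "unit")
    return all(u[:k] != u[-k:] for k in range(1, len(u)))


def rotations(u: str) -> set[str]:
    """All cyclic shifts of ``u`` (including ``u`` itself)."""
    if not u:
        raise ValueError("unit must be nonempty")
    _check_nucleotides(u, "unit")
    return {u[k:] + u[:k] for k in range(len(u))}


def canonical_rotation(u: str) -> str:
    """Lexicographically smallest rotation; a normalisation helper.

    Never applied implicitly anywhere in this package.
    """
    return min(rotations(u))


@dataclass(frozen=True)
class Unit:
    """A primitive nucleotide motif."""

    seq: str

    def __post_init__(self) -> None:
        if not is_primitive(self.seq):
            raise ValueError(
                f"unit {self.seq!r} is not primitive (it is a tandem repeat "
                "of a shorter string)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq


class UnitSet:
    """An ordered set of distinct units; symbol index = list position.

    Construction rejects non-primitive motifs (they make decompositions
    ambiguous) and warns about motifs that are not bifix-free, which is a
    recommendation rather than a requirement.
    """

    #: distinguished sentinel for the empty string.
    epsilon_symbol = EPSILON

    def __init__(self, units: Iterable[Unit | str]):
        resolved: list[Unit] = []
        seen: set[str] = set()
        for u in units:
            unit = u if isinstance(u, Unit) else Unit(str(u))
            if unit.seq in seen:
                raise ValueError(f"duplicate unit {unit.seq!r} in unit set")
            seen.add(unit.seq)
            if not is_bifix_free(unit.seq):
                warnings.warn(
                    f"unit {unit.seq!r} is not bifix-free; decompositions "
                    "may be more ambiguous",
                    stacklevel=2,
                )
            resolved.append(unit)
        if not resolved:
            raise ValueError("unit set must contain at least one unit")
        self._units: tuple[Unit, ...] = tuple(resolved)
        self._index = {u.seq: i for i, u in enumerate(self._units)}

    @classmethod
    def coerce(cls, units: "UnitSet | Iterable[Unit | str]") -> "UnitSet":
        return units if isinstance(units, UnitSet) else cls(units)

    @property
    def units(self) -> tuple[Unit, ...]:
        return self._units

    @property
    def seqs(self) -> tuple[str, ...]:
        return tuple(u.seq for u in self._units)

    @property
    def max_unit_len(self) -> int:
        return max(len(u) for u in self._units)

    def index(self, seq: str) -> int:
        return self._index[seq]

    def __contains__(self, seq: object) -> bool:
        return seq in self._index

    def __iter__(self) -> Iterator[Unit]:
        return iter(self._units)

    def __len__(self) -> int:
        return len(self._units)

    def __getitem__(self, i: int) -> Unit:
        return self._units[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, UnitSet) and self.seqs == other.seqs

    def __repr__(self) -> str:
        return f"UnitSet({list(self.seqs)!r})"

    def with_units(self, extra: Iterable[Unit | str]) -> "UnitSet":
        """A new UnitSet with ``extra`` appended after the current units."""
        return UnitSet(list(self._units) + list(extra))


@dataclass(frozen=True)
class TRRecord:
    """One tandem-repeat allele: an identifier and its nucleotide sequence.

    The sequence may be empty (a degenerate allele in which every repeat
    block has count zero).
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        _check_nucleotides(self.seq, f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


_GROUP_RE = re.compile(r"\(([A-Za-z]+)\)(\d+)")
_RUN_RE = re.compile(r"[A-Za-z]+")


def parse_repeat_notation(expr: str) -> str:
    """Expand ``(MOTIF)COUNT`` groups and bare runs into a nucleotide string.

    ``"(AAAG)3(AG)2"`` -> ``"AAAGAAAGAAAGAGAG"``.  Whitespace is ignored.
    Counts may be zero.  Malformed input raises :class:`RepeatNotationError`
    naming the offending position.
    """
    out: list[str] = []
    pos = 0
    n = len(expr)
    while pos < n:
        ch = expr[pos]
        if ch.isspace():
            pos += 1
            continue
        if ch == "(":
            m = _GROUP_RE.match(expr, pos)
            if not m:
                raise RepeatNotationError(
                    f"malformed group at position {pos} in {expr!r}"
                )
            motif, count = m.group(1).upper(), int(m.group(2))
            _check_nucleotides(motif, f"motif at position {pos}")
            out.append(motif * count)
            pos = m.end()
        else:
            m = _RUN_RE.match(expr, pos)
            if not m:
                raise RepeatNotationError(
                    f"unexpected character {ch!r} at position {pos} in {expr!r}"
                )
            run = m.group(0).upper()
            _check_nucleotides(run, f"run at position {pos}")
            out.append(run)
            pos = m.end()
    return "".join(out)


def format_repeat_notation(unit_seqs: Sequence[str]) -> str:
    """Run-length encode consecutive equal motifs as ``(MOTIF)COUNT`` groups.

    Inverse of :func:`parse_repeat_notation` on its output.
    """
    parts: list[str] = []
    i = 0
    while i < len(unit_seqs):
        j = i
        while j < len(unit_seqs) and unit_seqs[j] == unit_seqs[i]:
            j += 1
        parts.append(f"({unit_seqs[i]}){j - i}")
        i = j
    return "".join(parts)


def read_fasta(path) -> list[TRRecord]:
    """Read a multi-record FASTA file into :class:`TRRecord` objects.

    Lowercase residues are normalised to uppercase.  Duplicate ids and
    non-ACGT residues are rejected with the record named in the message.
    """
    records: list[TRRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in ALPHABET:
                raise FastaFormatError(
                    f"record {rec.id!r} has non-ACGT residue {ch!r} at "
                    f"position {i}"
                )
        records.append(TRRecord(rec.id, seq))
    return records


def write_fasta(records: Sequence[TRRecord], path) -> None:
    """Write records as FASTA, preserving order; round-trips with read_fasta."""
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def parse_unit_spec(text: str) -> UnitSet:
    """Build a UnitSet from a comma-separated motif list, e.g. ``AAAG,AG``."""
    motifs = [m.strip().upper() for m in text.split(",") if m.strip()]
    return UnitSet(motifs)


def read_unit_file(path) -> UnitSet:
    """Build a UnitSet from a one-motif-per-line text file."""
    with open(path) as fh:
        motifs = [line.strip().upper() for line in fh if line.strip()]
    return UnitSet(motifs)
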