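"""Run configuration shared by the command-line subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from fractions import Fraction
from typing import Optional

import yaml

from .exact import CostParams, SearchLimits
from .units import UnitSet


@dataclass
class RunConfig:
    """Serializable settings driving a pipeline run.

    Costs are written as strings parsed by :class:`fractions.Fraction`
    (``"1"``, ``"1/2"``) so the YAML round trip is exact.
    """

    units: list[str] = field(default_factory=list)
    c_sub: str = "1"
    c_ins: str = "1"
    c_del: str = "1"
    add_residue: bool = False
    augment: bool = False
    augment_min_count: int = 2
    augment_max_added: int = 10
    oracle_max_expansions: int = 2_000_000
    oracle_max_len: Optional[int] = None
    seed: int = 0
    tree_method: str = "nj"
    log_level: str = "INFO"

    def cost_params(self) -> CostParams:
        return CostParams(
            c_sub=Fraction(self.c_sub),
            c_ins=Fraction(self.c_ins),
            c_del=Fraction(self.c_del),
        )

    def search_limits(self) -> SearchLimits:
        return SearchLimits(
            max_len=self.oracle_max_len,
            max_expansions=self.oracle_max_expansions,
        )

    def unit_set(self) -> UnitSet:
        return UnitSet(self.units)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def echo_lines(self) -> list[str]:
        """Header lines recording the parameters of a run."""
        d = asdict(self)
        return [f"{k}={d[k]}" for k in d]
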