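"""Run configuration: detection criteria, alignment parameters, provenance.

Every report embeds the exact configuration used, because downstream
comparison of interaction counts is meaningless without the thresholds.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .interactions import HBondCriteria, SaltBridgeCriteria


@dataclass
class RunConfig:
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    saltbridge: SaltBridgeCriteria = field(default_factory=SaltBridgeCriteria)
    gap_open: float = -10.0
    gap_extend: float = -0.5
    matrix: str = "BLOSUM62"
    identity_denominator: str = "alignment_length"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "hbond": asdict(self.hbond),
            "saltbridge": asdict(self.saltbridge),
            "alignment": {"gap_open": self.gap_open, "gap_extend": self.gap_extend,
                          "matrix": self.matrix,
                          "identity_denominator": self.identity_denominator},
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        aln = data.get("alignment", {})
        return cls(
            hbond=HBondCriteria(**data.get("hbond", {})),
            saltbridge=SaltBridgeCriteria(**data.get("saltbridge", {})),
            gap_open=aln.get("gap_open", -10.0),
            gap_extend=aln.get("gap_extend", -0.5),
            matrix=aln.get("matrix", "BLOSUM62"),
            identity_denominator=aln.get("identity_denominator", "alignment_length"),
            seed=data.get("seed", 0),
            log_level=data.get("log_level", "INFO"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
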