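"""Design configuration: every tunable default, loadable from flat TOML.

The defaults encode the published working values where the protocol
states them (100 bp HR1/HR2, 30-50 bp HR3, ~200 bp mutation fragments,
two terminators, 20 bp assembly overlaps) and conventional values where
it does not (primer melting targets, the recoding window cap, the
pairing-window and probability threshold of the integration model).  A
snapshot of the active configuration is embedded in every design report
for provenance.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields


@dataclass
class DesignConfig:
    # homology geometry
    hr_len: int = 100          # HR1/HR2 length, bp; 50 allowed with a warning
    hr3_len: int = 40          # preferred HR3 length, bp
    hr3_min: int = 30
    hr3_max: int = 50
    fragment_len: int = 200    # target sequence per mutation fragment, bp
    # selection cassette
    n_terminators: int = 2
    marker: str = "cat_syn"
    junction_gap: int = 0      # nt between marker stop and a restored ORF start
    rbs_boost_codons: int = 8  # marker tail length offered to silent_rbs_boost
    # recoding
    w_max: int = 14
    # integration-outcome model
    pairing_window: int = 20   # minimal perfect-identity window for a crossover, bp
    p_threshold: float = 0.9   # warn when P(desired integration) falls below this
    # RBS model
    rbs_consensus: str = "AGGAGG"
    rbs_spacer_min: int = 4
    rbs_spacer_max: int = 13
    # hairpin screen (spacer regions)
    hairpin_min_stem: int = 8
    hairpin_loop_min: int = 3
    hairpin_loop_max: int = 10
    # primers / assembly
    overlap_len: int = 20
    tm_target: float = 60.0
    tm_delta: float = 3.0
    tm_method: str = "auto"    # wallace below 14 nt, nearest-neighbor above
    primer_min_len: int = 18
    primer_max_len: int = 35
    # misc
    codon_table_id: int = 11
    severity: str = "warn"     # warn | error: how validate treats soft failures

    def __post_init__(self) -> None:
        if not (self.hr3_min <= self.hr3_len <= self.hr3_max):
            raise ValueError("need hr3_min <= hr3_len <= hr3_max")
        if self.hr_len < 50:
            raise ValueError("homology regions shorter than 50 bp are not supported")
        if self.n_terminators not in (0, 1, 2):
            raise ValueError("n_terminators must be 0, 1 or 2")
        if self.severity not in ("warn", "error"):
            raise ValueError("severity must be 'warn' or 'error'")

    @classmethod
    def from_file(cls, path) -> "DesignConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_toml(self) -> str:
        lines = []
        for key, value in self.to_dict().items():
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            else:
                lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
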