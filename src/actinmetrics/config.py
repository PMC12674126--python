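"""Analysis configuration: every threshold in one place.

Defaults are calibrated against published measurements of actin
conformational states (see docs/methods.md):

* W-loop gate: the Tyr143 OH to Gly168 O hydrogen-bond distance sits near
  3-4 A when the gate is shut and 8-12 A when open. Closed <= 5 A leaves
  margin above the largest printed closed values (~4.1 A); open >= 8 A.
* Flattening class: printed F-like dihedrals span -6.2..-10.9 deg and
  G-like ones -14.8..-23.6 deg; thresholds -12 (F) / -13.5 (G) separate
  both groups with >= 1 deg margin.
* Lateral-helix engagement: a Lys113 N to Glu195 O distance strictly below
  4 A marks an engaged (hydrogen-bonded) helix pair.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # W-loop gate state thresholds on d(Y143 OH, G168 O), Angstrom
    gate_closed_max: float = 5.0
    gate_open_min: float = 8.0
    # conformer classification thresholds on the SD dihedral, degrees
    phi_f_like_min: float = -12.0   # F_like if phi >= this
    phi_g_like_max: float = -13.5   # G_like if phi <= this
    # lateral helix engagement threshold, Angstrom (strict <)
    helix_engaged_max: float = 4.0
    # center-of-mass weighting: mass | geometric | ca
    com_weighting: str = "mass"
    # torsion ordering of subdomain centers
    com_order: tuple[str, str, str, str] = ("SD2", "SD1", "SD3", "SD4")
    # SASA sampling
    probe_radius: float = 1.4
    sasa_points: int = 960
    # superposition
    trim: str = "none"
    # trajectory open/closed calling threshold on d_gate, Angstrom
    open_threshold: float = 8.0
    # subdomain coverage below which a warning is emitted
    coverage_warning: float = 0.8

    def __post_init__(self) -> None:
        if self.gate_closed_max >= self.gate_open_min:
            raise ValueError("gate_closed_max must be below gate_open_min")
        if self.phi_g_like_max >= self.phi_f_like_min:
            raise ValueError("phi_g_like_max must be below phi_f_like_min")
        self.com_order = tuple(self.com_order)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["com_order"] = list(self.com_order)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


DEFAULT_CONFIG = AnalysisConfig()
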