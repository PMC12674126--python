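"""Per-frame metrics over multi-model coordinate files.

A trajectory here is simply a :class:`StructureModel` with several frames
(one MODEL block each in PDB). The module extracts W-loop gate distance
time series, the open-fraction counting statistic, and probe-displacement
series (distance of a probe atom from its reference position after
per-frame anchor superposition).

Frames with missing atoms fail loudly, naming the frame: silently skipping
frames would bias open fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .conformer import wloop_gate
from .errors import ActinMetricsError, DegenerateGeometryError, GateMetricError
from .geometry import kabsch, match_residues
from .model import StructureModel, require_atom, select_chain


@dataclass
class GateTimeSeries:
    """Per-frame W-loop gate distances for one chain."""

    frame_index: np.ndarray
    d_gate: np.ndarray      # Tyr143 OH - Gly168 O, Angstrom
    d_ca: np.ndarray        # Tyr143 CA - Tyr169 CA, Angstrom
    chain_id: str

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.d_gate = np.asarray(self.d_gate, dtype=float)
        self.d_ca = np.asarray(self.d_ca, dtype=float)
        if not (len(self.frame_index) == len(self.d_gate) == len(self.d_ca)):
            raise ValueError("series lengths differ")
        if np.any(self.d_gate < 0) or np.any(self.d_ca < 0):
            raise ValueError("distances must be >= 0")

    def __len__(self) -> int:
        return len(self.frame_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame_index, "d_gate": self.d_gate, "d_ca": self.d_ca}
        )


@dataclass(frozen=True)
class GateSeriesSummary:
    """Fraction of frames with the gate distance at/above a threshold."""

    open_fraction: float
    n_frames: int
    threshold: float


def gate_timeseries(
    traj: StructureModel,
    chain_id: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> GateTimeSeries:
    """W-loop gate distances for every frame, in frame order."""
    d_gate, d_ca = [], []
    for i in range(traj.n_frames):
        chain = select_chain(traj, chain_id, frame=i)
        try:
            g = wloop_gate(chain, config)
        except GateMetricError as exc:
            raise GateMetricError(f"frame {i}: {exc}") from exc
        d_gate.append(g.d_y143oh_g168o)
        d_ca.append(g.d_y143ca_y169ca)
    return GateTimeSeries(
        frame_index=np.arange(traj.n_frames),
        d_gate=np.array(d_gate),
        d_ca=np.array(d_ca),
        chain_id=chain_id,
    )


def open_fraction(series: GateTimeSeries, threshold: float = 8.0) -> GateSeriesSummary:
    """Counting statistic: (#frames with d_gate >= threshold) / n_frames."""
    n = len(series)
    if n == 0:
        raise DegenerateGeometryError("open_fraction of an empty series")
    frac = float(np.count_nonzero(series.d_gate >= threshold)) / n
    return GateSeriesSummary(open_fraction=frac, n_frames=n, threshold=threshold)


@dataclass
class DisplacementSeries:
    """Per-frame distance of a probe atom from its reference position
    after superposing an anchor chain on its reference counterpart."""

    frame_index: np.ndarray
    displacement: np.ndarray
    probe: tuple[str, int, str]

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if len(self.frame_index) != len(self.displacement):
            raise ValueError("series lengths differ")
        if np.any(self.displacement < 0):
            raise ValueError("displacements must be >= 0")

    def __len__(self) -> int:
        return len(self.frame_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame_index, "displacement": self.displacement}
        )


def displacement_timeseries(
    traj: StructureModel,
    anchor_chain: str,
    reference: StructureModel,
    probe: tuple[str, int, str],
    reference_anchor: str | None = None,
) -> DisplacementSeries:
    """For each frame: Kabsch-fit the anchor chain onto its reference
    counterpart, then measure |probe(frame, fitted) - probe(reference)|.

    ``probe`` is (chain id, residue number, atom name); the probe chain is
    looked up in the trajectory frame and in the reference structure under
    the same id. ``reference_anchor`` defaults to ``anchor_chain``.
    """
    ref_anchor = select_chain(reference, reference_anchor or anchor_chain)
    probe_chain_id, resnum, atom_name = probe
    ref_probe_atom = require_atom(
        select_chain(reference, probe_chain_id), resnum, atom_name, "probe"
    )
    disp = []
    for i in range(traj.n_frames):
        try:
            anchor = select_chain(traj, anchor_chain, frame=i)
            P, Q, _ = match_residues(anchor, ref_anchor)
            fit = kabsch(P, Q)
            probe_atom = require_atom(
                select_chain(traj, probe_chain_id, frame=i), resnum, atom_name, "probe"
            )
        except ActinMetricsError as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
        moved = fit.rotation @ probe_atom.coords + fit.translation
        disp.append(float(np.linalg.norm(moved - ref_probe_atom.coords)))
    return DisplacementSeries(
        frame_index=np.arange(traj.n_frames),
        displacement=np.array(disp),
        probe=probe,
    )
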