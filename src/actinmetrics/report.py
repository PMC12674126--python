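"""Assemble the per-subunit metrics table and pairwise RMSD matrix.

Column names mirror the conventional row labels used in actin
conformational comparisons: phi_sd1_sd4_deg, delta_sd2_<ref>_ang,
delta_sd1_<ref>_deg/_ang, d_y143ca_y169ca_ang, d_y143oh_g168o_ang. Every
populated cell is the direct output of a library operation; nothing is
computed report-side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, AnalysisConfig
from .conformer import DEFAULT_SCHEME, SubdomainScheme, assign_subdomains, conformer_metrics
from .geometry import rmsd_after_superposition
from .interface import buried_area
from .model import ChainModel

logger = logging.getLogger(__name__)


@dataclass
class MetricsTable:
    """Per-subunit conformer metrics plus a pairwise RMSD block."""

    metrics: pd.DataFrame
    rmsd: pd.DataFrame
    n_matched: pd.DataFrame
    interfaces: pd.DataFrame | None = None


def analyze_subunits(
    subunits: dict[str, ChainModel],
    references: dict[str, ChainModel] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    scheme: SubdomainScheme = DEFAULT_SCHEME,
    with_interfaces: bool = False,
) -> MetricsTable:
    """Compute conformer metrics for each named subunit, the all-pairs
    C-alpha RMSD matrix over subunits and references, and (optionally)
    pairwise interface buried areas between the subunits."""
    references = references or {}
    rows = []
    for role, chain in subunits.items():
        part = assign_subdomains(chain, scheme, config.coverage_warning)
        logger.info(
            "subunit %s: subdomain residue counts %s",
            role,
            {sd: len(part.realized[sd]) for sd in scheme.subdomains},
        )
        m = conformer_metrics(chain, references, config, scheme)
        row: dict[str, object] = {
            "subunit": role,
            "chain_id": chain.chain_id,
            "phi_sd1_sd4_deg": m.phi_sd1_sd4,
            "conformer_class": m.conformer_class,
            "d_y143ca_y169ca_ang": m.gate.d_y143ca_y169ca,
            "d_y143oh_g168o_ang": m.gate.d_y143oh_g168o,
            "gate_state": m.gate.gate_state,
        }
        for ref_name, off in m.delta_vs.items():
            row[f"delta_sd2_{ref_name}_ang"] = off.delta_sd2_ang
            row[f"delta_sd1_{ref_name}_deg"] = off.delta_sd1_deg
            row[f"delta_sd1_{ref_name}_ang"] = off.delta_sd1_ang
        rows.append(row)
    metrics = pd.DataFrame(rows).set_index("subunit")

    everything = {**subunits, **references}
    names = list(everything)
    rmsd = pd.DataFrame(np.nan, index=names, columns=names)
    nmat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(names):
        for b in names[i:]:
            fit = rmsd_after_superposition(everything[a], everything[b], trim=config.trim)
            rmsd.loc[a, b] = rmsd.loc[b, a] = fit.rmsd
            nmat.loc[a, b] = nmat.loc[b, a] = fit.n_matched

    interfaces = None
    if with_interfaces:
        irows = []
        roles = list(subunits)
        for i, a in enumerate(roles):
            for b in roles[i + 1:]:
                rep = buried_area(
                    subunits[a], subunits[b], config.probe_radius, config.sasa_points
                )
                top = sorted(rep.per_residue.items(), key=lambda kv: -kv[1])[:5]
                irows.append(
                    {
                        "pair": f"{a}/{b}",
                        "buried_area_ang2": rep.buried_area,
                        "top_residues": ";".join(
                            f"{cid}:{num}{ic}={area:.1f}" for (cid, num, ic), area in top
                        ),
                    }
                )
        interfaces = pd.DataFrame(irows)
    return MetricsTable(metrics=metrics, rmsd=rmsd, n_matched=nmat, interfaces=interfaces)
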