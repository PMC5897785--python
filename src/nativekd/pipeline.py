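"""End-to-end measurement pipeline: ladders -> windows -> integration -> fit.

Glue that the command line and the tests share.  Given scan sets per sample
(from files or from the simulator) it averages each acquisition, integrates
the free and bound +8 windows, assembles a :class:`~nativekd.model.TitrationModel`
and fits it.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .constants import DEFAULT_HALF_WIDTH, SCAN_RANGE
from .ladder import (
    IntegrationWindow,
    SpeciesDefinition,
    build_window,
    detect_window_overlap,
)
from .model import TitrationModel, TitrationResults
from .simulate import SyntheticTitration
from .spectra import SpectrumScan, average_scans, integrate_window

__all__ = ["standard_windows", "measure_sample", "analyze_scans", "analyze_titration"]


def standard_windows(
    protein_mass: float,
    ligand_mass: float,
    charge: int = 8,
    adducts: Sequence[int] = range(6),
    half_width: float = DEFAULT_HALF_WIDTH,
    scan_range: tuple[float, float] = SCAN_RANGE,
    check: bool = True,
) -> tuple[IntegrationWindow, IntegrationWindow]:
    """Free- and bound-species integration windows at one charge state.

    With ``check=True`` (default) the pair is screened for mutual overlap
    and scan-range escapes; conflicts raise with the offending windows named.
    """
    free = SpeciesDefinition("free", protein_mass)
    bound = free.with_ligand("bound", ligand_mass)
    w_free = build_window(free, charge, adducts, half_width)
    w_bound = build_window(bound, charge, adducts, half_width)
    if check:
        conflicts = detect_window_overlap([w_free, w_bound], *scan_range)
        if conflicts:
            raise ValueError(
                "integration windows conflict: "
                + "; ".join(c.detail for c in conflicts)
            )
    return w_free, w_bound


def measure_sample(
    scans: Sequence[SpectrumScan],
    w_free: IntegrationWindow,
    w_bound: IntegrationWindow,
    bin_width: float | None = None,
) -> tuple[float, float]:
    """Average an acquisition and return (ab_free, ab_bound)."""
    avg = average_scans(scans, bin_width=bin_width)
    return (
        integrate_window(avg, w_free).total_abundance,
        integrate_window(avg, w_bound).total_abundance,
    )


def analyze_scans(
    sample_scans: dict[str, Sequence[SpectrumScan]],
    design: pd.DataFrame,
    w_free: IntegrationWindow,
    w_bound: IntegrationWindow,
    bin_width: float | None = None,
) -> TitrationResults:
    """Integrate every sample's scans and fit the abundance-ratio model.

    ``design`` needs columns sample_id, ligand, P0, L0, replicate (mol/L).
    """
    rows = []
    for r in design.itertuples():
        sid = str(r.sample_id)
        if sid not in sample_scans:
            raise KeyError(f"design sample {sid!r} has no scans")
        ab_free, ab_bound = measure_sample(
            sample_scans[sid], w_free, w_bound, bin_width=bin_width
        )
        rows.append(
            {
                "sample_id": sid,
                "ligand": r.ligand,
                "P0": r.P0,
                "L0": r.L0,
                "replicate": r.replicate,
                "ab_free": ab_free,
                "ab_bound": ab_bound,
            }
        )
    return TitrationModel(pd.DataFrame(rows)).fit()


def analyze_titration(sim: SyntheticTitration, **window_kwargs) -> TitrationResults:
    """Run the full measurement chain on a simulated titration."""
    cfg = sim.config
    w_free, w_bound = standard_windows(
        cfg.protein_mass, cfg.ligand_mass, **window_kwargs
    )
    design = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "ligand": cfg.ligand_name,
                "P0": s.P0,
                "L0": s.L0,
                "replicate": s.replicate,
            }
            for s in sim.samples
        ]
    )
    scans = {s.sample_id: s.scans for s in sim.samples}
    return analyze_scans(scans, design, w_free, w_bound)
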