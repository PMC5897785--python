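"""Titration model and results objects.

:class:`TitrationModel` holds a tidy table of titration points (one row per
sample: initial concentrations plus measured free/bound total ion
abundances); :meth:`TitrationModel.fit` applies the abundance-ratio method
point-wise and returns a :class:`TitrationResults` carrying per-replicate
R/Ka/Kd estimates, per-concentration replicate statistics, a text
``summary()``, and plotting helpers.

No global fit across concentrations is attempted: the method yields one Kd
per sample, and replicates at one ligand concentration are summarised by the
mean and sample SD of their individual Kd values.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .binding import (
    BindingEstimate,
    TitrationPoint,
    estimate_binding,
    replicate_stats,
)

__all__ = ["TitrationModel", "TitrationResults", "assemble_titration_table"]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ["sample_id", "ligand", "P0", "L0", "replicate", "ab_free", "ab_bound"]


class TitrationModel:
    """Abundance-ratio binding model for a native-MS titration.

    Parameters
    ----------
    data
        Tidy DataFrame with columns ``sample_id, ligand, P0, L0, replicate,
        ab_free, ab_bound``. Concentrations in mol/L.

    Examples
    --------
    >>> model = TitrationModel.from_points(points)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"titration table is missing columns {missing}")
        self.data = data.reset_index(drop=True).copy()
        # validate rows eagerly through the domain type
        self._points = [
            TitrationPoint(
                sample_id=str(r.sample_id),
                P0=float(r.P0),
                L0=float(r.L0),
                ab_free=float(r.ab_free),
                ab_bound=float(r.ab_bound),
                replicate=int(r.replicate),
                ligand=str(r.ligand),
            )
            for r in self.data.itertuples()
        ]
        for (ligand, L0), grp in self.data.groupby(["ligand", "L0"]):
            if grp["P0"].nunique() > 1:
                raise ValueError(
                    f"inconsistent P0 within group ({ligand!r}, L0={L0:g}): "
                    f"{sorted(grp['P0'].unique())}"
                )

    @classmethod
    def from_points(cls, points: Sequence[TitrationPoint]) -> "TitrationModel":
        rows = [
            {
                "sample_id": p.sample_id,
                "ligand": p.ligand,
                "P0": p.P0,
                "L0": p.L0,
                "replicate": p.replicate,
                "ab_free": p.ab_free,
                "ab_bound": p.ab_bound,
            }
            for p in points
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, concentration_unit: str = "M"
    ) -> "TitrationModel":
        """Build from a tidy table; ``concentration_unit`` 'uM' converts
        P0/L0 columns from micromolar to molar."""
        df = data.copy()
        if concentration_unit == "uM":
            df["P0"] = df["P0"] * 1e-6
            df["L0"] = df["L0"] * 1e-6
        elif concentration_unit != "M":
            raise ValueError(f"unknown concentration unit {concentration_unit!r}")
        return cls(df)

    def fit(self) -> "TitrationResults":
        """Apply R -> Ka -> Kd to every titration point with L0 > 0.

        Zero-ligand samples (blanks) cannot enter the ratio equation; they
        are excluded from fitting, logged, and kept available for abundance
        statistics on the results object.
        """
        records = []
        for p in self._points:
            if p.L0 == 0:
                logger.info(
                    "sample %s has L0 = 0; excluded from Ka/Kd fitting", p.sample_id
                )
                continue
            est = estimate_binding(p)
            logger.debug(
                "sample %s: R=%.4f Ka=%.4g Kd=%.4g valid=%s",
                p.sample_id, est.R, est.Ka, est.Kd, est.valid,
            )
            records.append(
                {
                    "sample_id": p.sample_id,
                    "ligand": p.ligand,
                    "P0": p.P0,
                    "L0": p.L0,
                    "replicate": p.replicate,
                    "ab_free": p.ab_free,
                    "ab_bound": p.ab_bound,
                    "R": est.R,
                    "Ka": est.Ka,
                    "Kd": est.Kd,
                    "valid": est.valid,
                }
            )
        return TitrationResults(self, pd.DataFrame(records))


class TitrationResults:
    """Fit results: per-replicate estimates plus replicate summaries.

    Attributes
    ----------
    estimates
        One row per fitted sample with R, Ka (1/M), Kd (M) and the validity
        flag (False where Ka <= 0).
    """

    def __init__(self, model: TitrationModel, estimates: pd.DataFrame):
        self.model = model
        self.estimates = estimates

    # -- grouped summaries ----------------------------------------------------

    def by_concentration(self) -> pd.DataFrame:
        """Per (ligand, L0) group: mean/SD/%RSD of the replicate Kd values.

        Groups with a single replicate pass the value through with NaN
        spread columns.
        """
        rows = []
        for (ligand, L0), grp in self.estimates.groupby(["ligand", "L0"]):
            kds = grp["Kd"].to_numpy()
            if len(kds) >= 2:
                st = replicate_stats(list(kds))
                mean, sd, rsd = st.mean, st.sd, st.rsd_pct
            else:
                mean, sd, rsd = float(kds[0]), np.nan, np.nan
            rows.append(
                {
                    "ligand": ligand,
                    "L0": L0,
                    "n": len(kds),
                    "Kd_mean": mean,
                    "Kd_sd": sd,
                    "Kd_rsd_pct": rsd,
                    "all_valid": bool(grp["valid"].all()),
                }
            )
        return pd.DataFrame(rows).sort_values(["ligand", "L0"]).reset_index(drop=True)

    def abundance_stats(self) -> pd.DataFrame:
        """Replicate statistics of the measured abundances themselves,
        per (ligand, L0) group and species (free / bound), including blanks."""
        rows = []
        for (ligand, L0), grp in self.model.data.groupby(["ligand", "L0"]):
            for col, species in (("ab_free", "free"), ("ab_bound", "bound")):
                if L0 == 0 and species == "bound":
                    continue
                vals = grp[col].tolist()
                if len(vals) >= 2:
                    st = replicate_stats(vals)
                    rows.append(
                        {
                            "ligand": ligand,
                            "L0": L0,
                            "species": species,
                            "n": st.n,
                            "mean": st.mean,
                            "sd": st.sd,
                            "rsd_pct": st.rsd_pct,
                        }
                    )
        return pd.DataFrame(rows)

    # -- reporting ------------------------------------------------------------

    def report_table(self) -> pd.DataFrame:
        """Per-replicate R and Kd at reporting precision (R to 2 d.p.,
        Kd in uM to 1 d.p., half-up), one row per fitted sample."""
        df = self.estimates.copy()
        df["L0_uM"] = df["L0"] * 1e6
        df["R_2dp"] = df["R"].map(lambda x: round_half_up(x, 2))
        df["Kd_uM"] = df["Kd"].map(lambda x: round_half_up(x * 1e6, 1))
        return df[
            ["ligand", "L0_uM", "replicate", "R_2dp", "Kd_uM", "valid"]
        ].sort_values(["ligand", "L0_uM", "replicate"]).reset_index(drop=True)

    def average_kd(self, ligand: str, L0: float) -> float:
        """Mean of the per-replicate Kd values (M) at one concentration."""
        grp = self.estimates[
            (self.estimates["ligand"] == ligand)
            & np.isclose(self.estimates["L0"], L0)
        ]
        if grp.empty:
            raise KeyError(f"no fitted samples for ({ligand!r}, L0={L0:g})")
        return float(grp["Kd"].mean())

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        lines = [
            "Abundance-ratio titration fit",
            "=" * 64,
            f"{'samples fitted':<24}{len(self.estimates)}",
            f"{'ligands':<24}{', '.join(sorted(self.estimates['ligand'].unique()))}",
            "",
            f"{'ligand':<12}{'L0 (uM)':>8}{'n':>4}{'mean Kd (uM)':>14}"
            f"{'SD (uM)':>10}{'valid':>7}",
            "-" * 64,
        ]
        for r in self.by_concentration().itertuples():
            sd = f"{r.Kd_sd * 1e6:.1f}" if np.isfinite(r.Kd_sd) else "--"
            lines.append(
                f"{r.ligand:<12}{r.L0 * 1e6:>8.1f}{r.n:>4}"
                f"{r.Kd_mean * 1e6:>14.1f}{sd:>10}{str(r.all_valid):>7}"
            )
        lines += [
            "-" * 64,
            "Kd < 0 marks groups where apparent bound protein exceeds total",
            "ligand (Ka denominator negative); see the valid flag.",
        ]
        return "\n".join(lines)

    def plot_abundance(self, ax=None):
        """Mean total ion abundance (+/- SD) of free and bound species versus
        ligand concentration — the standard titration figure."""
        from . import plots

        return plots.plot_abundance_vs_concentration(self, ax=ax)


def assemble_titration_table(points: Sequence[TitrationPoint]) -> pd.DataFrame:
    """One-call convenience: fit all points and return the merged
    per-replicate report table plus per-concentration Kd statistics."""
    res = TitrationModel.from_points(points).fit()
    report = res.report_table()
    stats = res.by_concentration().assign(L0_uM=lambda d: d["L0"] * 1e6)
    return report.merge(
        stats[["ligand", "L0_uM", "Kd_mean", "Kd_sd", "Kd_rsd_pct", "n"]],
        on=["ligand", "L0_uM"],
        how="left",
    )
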