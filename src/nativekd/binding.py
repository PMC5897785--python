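"""The abundance-ratio method for 1:1 protein-ligand binding constants.

For a 1:1 complex P + L <=> PL sprayed under native conditions, the ratio of
total ion abundances of bound to free protein is taken as a proxy for the
solution concentration ratio at equilibrium:

    R = Ab(PL) / Ab(P) = [PL]_eq / [P]_eq

With initial (total) concentrations [P]0 and [L]0, mass balance closes the
system and the association constant follows directly:

    Ka = R / ([L]0 - (R / (1 + R)) * [P]0),        Kd = 1 / Ka

The denominator is the free-ligand concentration inferred from R. When the
apparent amount of bound protein, (R/(1+R))*[P]0, exceeds the total ligand,
the denominator — and hence Ka and Kd — go negative. That is not a numerical
bug but a diagnostic of biased abundances (response-factor differences,
charge states outside the acquired range, or nonspecific binding); negative
values are therefore reported verbatim and flagged invalid, never clamped.

All concentrations are mol/L internally; micromolar appears only in
reporting layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "TitrationPoint",
    "BindingEstimate",
    "ReplicateStats",
    "abundance_ratio",
    "association_constant",
    "dissociation_constant",
    "estimate_binding",
    "replicate_stats",
]


@dataclass(frozen=True)
class TitrationPoint:
    """One measured sample of the titration.

    Concentrations are initial (pre-equilibration) totals in mol/L;
    abundances are total ion abundances (summed window intensities).
    """

    sample_id: str
    P0: float
    L0: float
    ab_free: float
    ab_bound: float
    replicate: int = 1
    ligand: str = ""

    def __post_init__(self) -> None:
        if self.P0 <= 0:
            raise ValueError(f"{self.sample_id}: P0 must be > 0, got {self.P0}")
        if self.L0 < 0:
            raise ValueError(f"{self.sample_id}: L0 must be >= 0, got {self.L0}")
        if self.ab_free < 0 or self.ab_bound < 0:
            raise ValueError(f"{self.sample_id}: abundances must be >= 0")


@dataclass(frozen=True)
class BindingEstimate:
    """R, Ka and Kd for one titration point.

    ``valid`` is False when Ka <= 0 (apparent bound protein exceeds total
    ligand); Kd = 1/Ka with the sign preserved.
    """

    R: float
    Ka: float
    Kd: float
    valid: bool


@dataclass(frozen=True)
class ReplicateStats:
    """Mean, sample standard deviation (n-1) and percent RSD."""

    mean: float
    sd: float
    rsd_pct: float
    n: int


def abundance_ratio(ab_bound: float, ab_free: float, sample_id: str = "") -> float:
    """R = Ab(PL) / Ab(P)."""
    if ab_free <= 0:
        raise ZeroDivisionError(
            f"free-protein abundance is {ab_free} for sample {sample_id!r}; "
            "R is undefined"
        )
    if ab_bound < 0:
        raise ValueError(f"negative bound abundance for sample {sample_id!r}")
    return ab_bound / ab_free


def association_constant(R: float, L0: float, P0: float) -> float:
    """Ka = R / ([L]0 - (R/(1+R)) [P]0), in 1/M.

    May be negative; the caller decides how to flag it (see
    :func:`estimate_binding`). An exactly zero denominator raises.
    """
    if R < 0:
        raise ValueError(f"R must be >= 0, got {R}")
    if L0 <= 0:
        raise ValueError(f"L0 must be > 0 to estimate Ka, got {L0}")
    if P0 <= 0:
        raise ValueError(f"P0 must be > 0, got {P0}")
    denom = L0 - (R / (1.0 + R)) * P0
    if denom == 0.0:
        raise ZeroDivisionError(
            "apparent bound protein exactly equals total ligand; Ka is singular"
        )
    return R / denom


def dissociation_constant(Ka: float) -> float:
    """Kd = 1/Ka in M, sign preserved."""
    if Ka == 0.0:
        raise ZeroDivisionError("Ka = 0 has no finite Kd")
    return 1.0 / Ka


def estimate_binding(point: TitrationPoint) -> BindingEstimate:
    """Full chain R -> Ka -> Kd for one titration point, with validity flag."""
    R = abundance_ratio(point.ab_bound, point.ab_free, point.sample_id)
    Ka = association_constant(R, point.L0, point.P0)
    Kd = dissociation_constant(Ka)
    return BindingEstimate(R=R, Ka=Ka, Kd=Kd, valid=Ka > 0)


def replicate_stats(values: Sequence[float]) -> ReplicateStats:
    """Mean, sample SD (n-1 denominator) and %RSD = 100*SD/mean."""
    n = len(values)
    if n < 2:
        raise ValueError(f"need >= 2 replicates for a standard deviation, got {n}")
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    rsd = 100.0 * sd / mean if mean != 0 else math.nan
    return ReplicateStats(mean=mean, sd=sd, rsd_pct=rsd, n=n)
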