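"""Ground-truth synthetic titration spectra.

The generator produces profile spectra of a 1:1 protein-ligand titration the
way an ion trap would see it: species concentrations fixed by mass-action
equilibrium, each species fanned out over a +98 Da adduct series (truncated
geometric weights) and a charge-state envelope, each ion a Gaussian peak on
a regular m/z grid, plus optional baseline and noise.  Every sample carries
its ground truth (Kd, equilibrium state, response bias, seed) so end-to-end
parameter recovery can be asserted, and three failure modes reported for
abundance-ratio titrations can be switched on:

* ``response_bias`` (rho) — the bound complex ionizes rho times as
  efficiently as free protein, so measured R = rho * [PL]/[P];
* ``charge_weights_bound`` — the complex redistributes signal to charge
  states outside the acquired scan range;
* ``nonspecific_kd`` — a second, weaker ligand-binding site produces a PL2
  species whose ions fall outside the bound-species window (the hook
  effect at high ligand concentration).

Noise model: one log-normal spray-efficiency factor per replicate (shared
by all species and scans of that replicate — electrospray drift moves the
whole spectrum up or down together) plus independent log-normal shot noise
per grid point per scan, both with coefficient of variation ``noise_cv``.

Numerical note: the default grid step (0.0125 Th) is chosen commensurate
with the +8 charge-state mass shift of both ligands (172.9875 and 176.0 Th
are exact multiples), so the free and bound integration windows sample
their Gaussian ladders with identical phase and edge truncation cancels
exactly in the abundance ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .constants import DC5_MASS, P0_MOLAR, RNASE_A_MASS
from .ladder import SpeciesDefinition, predict_ion_mz
from .spectra import SpectrumScan

__all__ = [
    "EquilibriumState",
    "SimulationConfig",
    "SyntheticScan",
    "SyntheticSample",
    "SyntheticTitration",
    "solve_equilibrium",
    "solve_equilibrium_nonspecific",
    "adduct_weights",
    "simulate_spectrum",
    "simulate_titration",
]


@dataclass(frozen=True)
class EquilibriumState:
    """Solution composition at equilibrium, mol/L."""

    PL: float
    P_free: float
    L_free: float
    PL2: float = 0.0


def solve_equilibrium(P0: float, L0: float, Kd: float) -> EquilibriumState:
    """Exact 1:1 mass-action equilibrium.

    [PL] is the smaller root of the binding quadratic,

        PL = ((P0 + L0 + Kd) - sqrt((P0 + L0 + Kd)^2 - 4 P0 L0)) / 2,

    which satisfies PL <= min(P0, L0) and PL*Kd = P_free*L_free.
    """
    if P0 <= 0:
        raise ValueError(f"P0 must be > 0, got {P0}")
    if L0 < 0:
        raise ValueError(f"L0 must be >= 0, got {L0}")
    if Kd < 0:
        raise ValueError(f"Kd must be >= 0, got {Kd}")
    s = P0 + L0 + Kd
    disc = s * s - 4.0 * P0 * L0
    pl = (s - math.sqrt(max(disc, 0.0))) / 2.0
    pl = min(pl, P0, L0)  # guard float overshoot at the stoichiometric limit
    return EquilibriumState(PL=pl, P_free=P0 - pl, L_free=L0 - pl)


def solve_equilibrium_nonspecific(
    P0: float, L0: float, Kd1: float, Kd2: float
) -> EquilibriumState:
    """Sequential two-site equilibrium P + L <=> PL (Kd1), PL + L <=> PL2 (Kd2).

    Solved by root-finding on free ligand x in [0, L0]:
    P = P0 / (1 + x/Kd1 + x^2/(Kd1 Kd2)), with mass balance on L.
    """
    if min(P0, Kd1, Kd2) <= 0 or L0 < 0:
        raise ValueError("P0, Kd1, Kd2 must be > 0 and L0 >= 0")
    if L0 == 0:
        return EquilibriumState(PL=0.0, P_free=P0, L_free=0.0)

    def l_balance(x: float) -> float:
        q = 1.0 + x / Kd1 + x * x / (Kd1 * Kd2)
        p = P0 / q
        pl = p * x / Kd1
        pl2 = pl * x / Kd2
        return x + pl + 2.0 * pl2 - L0

    x = brentq(l_balance, 0.0, L0, xtol=1e-18, rtol=1e-14)
    q = 1.0 + x / Kd1 + x * x / (Kd1 * Kd2)
    p = P0 / q
    pl = p * x / Kd1
    return EquilibriumState(PL=pl, P_free=p, L_free=x, PL2=pl * x / Kd2)


def adduct_weights(decay: float, max_adducts: int) -> np.ndarray:
    """Truncated-geometric phosphate-adduct distribution over X = 0..max.

    weights[X] proportional to decay**X, normalized to sum to 1; monotone
    non-increasing, matching the declining adduct envelope seen on intact
    protein spectra.
    """
    if not 0.0 <= decay < 1.0:
        raise ValueError(f"decay must be in [0, 1), got {decay}")
    if max_adducts < 0:
        raise ValueError(f"max_adducts must be >= 0, got {max_adducts}")
    w = decay ** np.arange(max_adducts + 1, dtype=float)
    return w / w.sum()


@dataclass
class SimulationConfig:
    """Knobs of the synthetic titration.

    Defaults reproduce the study conditions: P0 = 40.9 uM throughout, ligand
    at 0/5/10/20/40 uM with 6 replicates of the blank and 3 of each titration
    point, Kd = 2.2 uM, +8 the only charge state inside the acquired
    m/z 1500-1950 window, up to 8 phosphate adducts, and replicate abundance
    scatter around 15 %.
    """

    Kd_true: float = 2.2e-6
    #: (P0, L0, n_replicates) rows; mol/L.
    design: Sequence[tuple[float, float, int]] = (
        (P0_MOLAR, 0.0, 6),
        (P0_MOLAR, 5e-6, 3),
        (P0_MOLAR, 10e-6, 3),
        (P0_MOLAR, 20e-6, 3),
        (P0_MOLAR, 40e-6, 3),
    )
    protein_mass: float = RNASE_A_MASS
    ligand_mass: float = DC5_MASS
    ligand_name: str = "dC5"
    adduct_decay: float = 0.45
    max_adducts: int = 8
    peak_sigma: float = 1.5
    response_bias: float = 1.0
    charge_weights: dict[int, float] = field(default_factory=lambda: {8: 1.0})
    charge_weights_bound: dict[int, float] | None = None
    noise_cv: float = 0.15
    baseline: float = 0.0
    grid: tuple[float, float, float] = (1500.0, 1950.0, 0.0125)
    n_scans: int = 5
    #: integrated counts per mol/L of a species (detector response scale).
    counts_per_molar: float = 1.8e12
    nonspecific_kd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Kd_true < 0 or self.peak_sigma <= 0 or self.counts_per_molar <= 0:
            raise ValueError("Kd_true, peak_sigma, counts_per_molar must be positive")
        if self.noise_cv < 0 or self.baseline < 0:
            raise ValueError("noise_cv and baseline must be >= 0")
        total = sum(self.charge_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            self.charge_weights = {z: w / total for z, w in self.charge_weights.items()}

    @property
    def grid_mz(self) -> np.ndarray:
        lo, hi, step = self.grid
        return lo + step * np.arange(int(round((hi - lo) / step)) + 1)

    def species(self) -> tuple[SpeciesDefinition, SpeciesDefinition]:
        free = SpeciesDefinition(
            "free", self.protein_mass, max_adducts=self.max_adducts
        )
        bound = free.with_ligand("bound", self.ligand_mass)
        return free, bound


@dataclass
class SyntheticScan(SpectrumScan):
    """A simulated profile scan plus its ground-truth parameters."""

    truth: dict = field(default_factory=dict)


@dataclass
class SyntheticSample:
    """All scans of one replicate, with the underlying equilibrium state."""

    sample_id: str
    P0: float
    L0: float
    replicate: int
    scans: list[SyntheticScan]
    state: EquilibriumState
    spray_factor: float


@dataclass
class SyntheticTitration:
    """Output of :func:`simulate_titration`: samples plus a manifest."""

    samples: list[SyntheticSample]
    config: SimulationConfig

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "P0": s.P0,
                "L0": s.L0,
                "replicate": s.replicate,
                "seed": self.config.seed,
                "Kd_true": self.config.Kd_true,
                "response_bias": self.config.response_bias,
                "PL_eq": s.state.PL,
                "P_free_eq": s.state.P_free,
                "L_free_eq": s.state.L_free,
                "PL2_eq": s.state.PL2,
                "spray_factor": s.spray_factor,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _add_species(
    intensity: np.ndarray,
    grid: np.ndarray,
    species: SpeciesDefinition,
    concentration: float,
    response: float,
    charge_weights: dict[int, float],
    config: SimulationConfig,
) -> None:
    """Accumulate one species' Gaussian ladder onto the profile."""
    if concentration <= 0:
        return
    step = config.grid[2]
    aw = adduct_weights(config.adduct_decay, species.max_adducts)
    for z, cw in charge_weights.items():
        for x, w in enumerate(aw):
            mu = predict_ion_mz(species.neutral_mass, x, species.adduct_mass, z)
            if mu < grid[0] - 10 * config.peak_sigma or mu > grid[-1] + 10 * config.peak_sigma:
                continue  # ion outside the acquired range: signal is simply lost
            area = concentration * response * cw * w * config.counts_per_molar * step
            intensity += area * norm.pdf(grid, loc=mu, scale=config.peak_sigma)


def simulate_spectrum(
    state: EquilibriumState,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    spray_factor: float = 1.0,
    scan_prefix: str = "scan",
) -> list[SyntheticScan]:
    """Simulate ``config.n_scans`` profile scans of one equilibrated sample.

    Peak areas are concentration x response x charge weight x adduct weight;
    the bound species (and PL2, if present) carry the ``response_bias``
    factor. With ``noise_cv = 0`` and unit spray factor the scans are
    deterministic and identical.
    """
    if config.grid[2] > config.peak_sigma:
        import warnings

        warnings.warn(
            f"grid step {config.grid[2]} exceeds peak sigma {config.peak_sigma}; "
            "peaks are under-sampled",
            stacklevel=2,
        )
    rng = rng or np.random.default_rng(config.seed)
    grid = config.grid_mz
    free, bound = config.species()
    cw_free = config.charge_weights
    cw_bound = config.charge_weights_bound or config.charge_weights
    if config.charge_weights_bound:
        total = sum(cw_bound.values())
        cw_bound = {z: w / total for z, w in cw_bound.items()}

    clean = np.zeros_like(grid)
    _add_species(clean, grid, free, state.P_free, 1.0, cw_free, config)
    _add_species(clean, grid, bound, state.PL, config.response_bias, cw_bound, config)
    if state.PL2 > 0:
        bound2 = bound.with_ligand("bound2", config.ligand_mass)
        _add_species(clean, grid, bound2, state.PL2, config.response_bias, cw_bound, config)
    clean += config.baseline

    truth = {
        "PL": state.PL,
        "P_free": state.P_free,
        "L_free": state.L_free,
        "PL2": state.PL2,
        "Kd_true": config.Kd_true,
        "response_bias": config.response_bias,
        "spray_factor": spray_factor,
    }
    scans = []
    for i in range(config.n_scans):
        shot = _lognormal_factors(rng, config.noise_cv, grid.shape)
        scans.append(
            SyntheticScan(
                mz=grid.copy(),
                intensity=clean * spray_factor * shot,
                mode="profile",
                scan_id=f"{scan_prefix}={i + 1}",
                truth=truth,
            )
        )
    return scans


def simulate_titration(config: SimulationConfig | None = None) -> SyntheticTitration:
    """Simulate the full titration design, one scan set per replicate.

    Reproducible: the same config (including seed) yields identical output.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    samples = []
    for P0, L0, n_rep in config.design:
        if config.nonspecific_kd is not None:
            state = solve_equilibrium_nonspecific(
                P0, L0, config.Kd_true, config.nonspecific_kd
            )
        else:
            state = solve_equilibrium(P0, L0, config.Kd_true)
        for rep in range(1, n_rep + 1):
            spray = float(_lognormal_factors(rng, config.noise_cv, ()))
            sample_id = f"{config.ligand_name}_L{L0 * 1e6:g}uM_r{rep}"
            scans = simulate_spectrum(
                state, config, rng=rng, spray_factor=spray,
                scan_prefix=f"{sample_id}.scan",
            )
            samples.append(
                SyntheticSample(
                    sample_id=sample_id,
                    P0=P0,
                    L0=L0,
                    replicate=rep,
                    scans=scans,
                    state=state,
                    spray_factor=spray,
                )
            )
    return SyntheticTitration(samples=samples, config=config)


def ideal_config(**overrides) -> SimulationConfig:
    """Noise-free, bias-free configuration for exactness checks."""
    base = SimulationConfig(noise_cv=0.0, response_bias=1.0, n_scans=1)
    return replace(base, **overrides)
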