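"""Predicted m/z ladders for multiply protonated, adducted protein ions.

An electrosprayed intact protein appears as a series of charge states, each
of which carries its own series of +98 Da phosphate (Pi) adducts.  The
observed m/z of a species with neutral mass ``M``, ``X`` adducts and charge
``z`` is

    m/z = (M + X * m_adduct + z * m_proton) / z

This module builds those ladders, turns a (charge, adduct-range) slice of a
ladder into a closed m/z integration window, and detects window collisions —
the situation that forces capping the usable adduct count when a ligand-bound
species at one charge state runs into the free protein at the next lower
charge state, or past the end of the acquired scan range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .constants import DEFAULT_HALF_WIDTH, PI_ADDUCT_MASS, PROTON_MASS

__all__ = [
    "SpeciesDefinition",
    "LadderEntry",
    "IntegrationWindow",
    "predict_ion_mz",
    "build_ladder",
    "build_window",
    "detect_window_overlap",
    "max_safe_adducts",
]


@dataclass(frozen=True)
class SpeciesDefinition:
    """A neutral species (protein, optionally with one bound ligand).

    Parameters
    ----------
    name
        Text label, e.g. ``"RNaseA"`` or ``"RNaseA+dC5"``.
    neutral_mass
        Average neutral mass in Da (M for the free protein, M+L for the
        ligand-bound form).
    adduct_mass
        Mass of one adduct in Da; default is the nominal +98 Da phosphate.
    max_adducts
        Largest adduct count the species is modelled with.
    """

    name: str
    neutral_mass: float
    adduct_mass: float = PI_ADDUCT_MASS
    max_adducts: int = 8

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"neutral_mass must be > 0, got {self.neutral_mass}")
        if self.adduct_mass <= 0:
            raise ValueError(f"adduct_mass must be > 0, got {self.adduct_mass}")
        if self.max_adducts < 0:
            raise ValueError(f"max_adducts must be >= 0, got {self.max_adducts}")

    def with_ligand(self, name: str, ligand_mass: float) -> "SpeciesDefinition":
        """Return the 1:1 ligand-bound counterpart of this species."""
        return SpeciesDefinition(
            name=name,
            neutral_mass=self.neutral_mass + ligand_mass,
            adduct_mass=self.adduct_mass,
            max_adducts=self.max_adducts,
        )


@dataclass(frozen=True)
class LadderEntry:
    """One predicted ion: a species at a given charge and adduct count."""

    species: SpeciesDefinition
    charge: int
    n_adducts: int
    mz: float


@dataclass(frozen=True)
class IntegrationWindow:
    """A closed m/z interval [lo, hi] assigned to one species at one charge."""

    species: str
    charge: int
    lo: float
    hi: float
    half_width: float = DEFAULT_HALF_WIDTH

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(
                f"window for {self.species!r} z={self.charge} is degenerate: "
                f"lo={self.lo} must be < hi={self.hi}"
            )

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def overlaps(self, other: "IntegrationWindow") -> bool:
        """True if the closed intervals intersect."""
        return self.lo <= other.hi and other.lo <= self.hi


def predict_ion_mz(
    neutral_mass: float,
    n_adducts: int,
    adduct_mass: float = PI_ADDUCT_MASS,
    charge: int = 1,
    proton_mass: float = PROTON_MASS,
) -> float:
    """m/z of [M + X·adduct + z·H]^z+ at full precision.

    Rounding to 1 decimal is a display concern and is never applied here.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral_mass must be > 0, got {neutral_mass}")
    if adduct_mass <= 0:
        raise ValueError(f"adduct_mass must be > 0, got {adduct_mass}")
    if n_adducts < 0:
        raise ValueError(f"n_adducts must be >= 0, got {n_adducts}")
    return (neutral_mass + n_adducts * adduct_mass + charge * proton_mass) / charge


def build_ladder(
    species: SpeciesDefinition,
    charges: Iterable[int],
    adducts: Iterable[int],
    proton_mass: float = PROTON_MASS,
) -> list[LadderEntry]:
    """All (charge, adduct-count) ions of a species, in grid order.

    Empty charge or adduct ranges yield an empty list.
    """
    entries = []
    adducts = list(adducts)
    for z in charges:
        for x in adducts:
            entries.append(
                LadderEntry(
                    species=species,
                    charge=z,
                    n_adducts=x,
                    mz=predict_ion_mz(
                        species.neutral_mass, x, species.adduct_mass, z, proton_mass
                    ),
                )
            )
    return entries


def build_window(
    species: SpeciesDefinition,
    charge: int,
    adducts: Iterable[int],
    half_width: float = DEFAULT_HALF_WIDTH,
    proton_mass: float = PROTON_MASS,
) -> IntegrationWindow:
    """Closed window spanning a species' adduct series at one charge state.

    lo = (smallest ladder m/z) - half_width, hi = (largest) + half_width.
    A degenerate window (single adduct count with zero padding) raises.
    """
    if half_width < 0:
        raise ValueError(f"half_width must be >= 0, got {half_width}")
    adducts = list(adducts)
    if not adducts:
        raise ValueError(f"empty adduct range: window for {species.name!r} undefined")
    mzs = [
        predict_ion_mz(species.neutral_mass, x, species.adduct_mass, charge, proton_mass)
        for x in adducts
    ]
    return IntegrationWindow(
        species=species.name,
        charge=charge,
        lo=min(mzs) - half_width,
        hi=max(mzs) + half_width,
        half_width=half_width,
    )


@dataclass(frozen=True)
class WindowConflict:
    """A detected window problem: a pairwise overlap or scan-range escape."""

    kind: str  # "overlap" | "out_of_scan"
    first: IntegrationWindow
    second: IntegrationWindow | None = None
    detail: str = ""


def detect_window_overlap(
    windows: Sequence[IntegrationWindow],
    scan_lo: float = float("-inf"),
    scan_hi: float = float("inf"),
) -> list[WindowConflict]:
    """Every pairwise window intersection plus every window not fully inside
    the acquired scan range ``[scan_lo, scan_hi]``."""
    conflicts: list[WindowConflict] = []
    for i, w in enumerate(windows):
        for other in windows[i + 1:]:
            if w.overlaps(other):
                conflicts.append(
                    WindowConflict(
                        kind="overlap",
                        first=w,
                        second=other,
                        detail=(
                            f"{w.species} z={w.charge} [{w.lo:.1f}, {w.hi:.1f}] "
                            f"intersects {other.species} z={other.charge} "
                            f"[{other.lo:.1f}, {other.hi:.1f}]"
                        ),
                    )
                )
        if w.lo < scan_lo or w.hi > scan_hi:
            conflicts.append(
                WindowConflict(
                    kind="out_of_scan",
                    first=w,
                    detail=(
                        f"{w.species} z={w.charge} [{w.lo:.1f}, {w.hi:.1f}] "
                        f"escapes scan range [{scan_lo:g}, {scan_hi:g}]"
                    ),
                )
            )
    return conflicts


def max_safe_adducts(
    target: SpeciesDefinition,
    charge: int,
    others: Sequence[IntegrationWindow] = (),
    scan_hi: float = float("inf"),
    scan_lo: float = float("-inf"),
    half_width: float = DEFAULT_HALF_WIDTH,
    proton_mass: float = PROTON_MASS,
) -> int:
    """Largest adduct count whose window stays inside the scan range and
    clear of every other window.

    This is the restraint that caps a usable adduct series: growing the
    window by one adduct at a time until it would either cross the end of
    the scan or collide with another species' window. Raises ``ValueError``
    if even the adduct-free window conflicts, naming the blocking window.
    """
    best: int | None = None
    for x_max in range(target.max_adducts + 1):
        window = build_window(
            target, charge, range(x_max + 1), half_width, proton_mass
        )
        conflicts = detect_window_overlap(
            [window, *others], scan_lo=scan_lo, scan_hi=scan_hi
        )
        # only conflicts involving the candidate window matter
        blocking = [c for c in conflicts if c.first is window or c.second is window]
        if blocking:
            if best is None:
                raise ValueError(
                    f"no adduct count fits for {target.name!r} z={charge}: "
                    + blocking[0].detail
                )
            break
        best = x_max
    assert best is not None
    return best
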