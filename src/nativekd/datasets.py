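"""Packaged reference data: the published titration design and abundance
tables, shipped so the full analysis is reproducible without any download.

The underlying instrument files (vendor .raw, ~30 acquisitions) are archived
in a public repository and are not needed here: the published abundance
tables are the measurement-path output and feed the ratio analysis directly.

Fixture integrity is verified by SHA-256 at load time.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .model import TitrationModel

__all__ = [
    "titration_design",
    "blank_abundances",
    "titration_abundances",
    "expected_report",
    "titration_model",
]

_CHECKSUMS = {
    "table1_design.csv": "c603d98fb21a2587f35388ef7bfbb13a7c3eeb1f31b264eed86c285895a2114d",
    "table4_blank_abundance.csv": "adda93365c125a144f482a4247c79e293e63d582cd2e82772e19a529e9ab608e",
    "table5_abundance.csv": "8da89c3880d15b2c4dbd97f00581dc6a5b25303792765cf7be7e1a7cf3ec1579",
    "table6_expected.csv": "9d5bfa0e2bca1a2d08eac0557691b03fcefe0c47eb4f41e74911581b17364b93",
}


class FixtureIntegrityError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("nativekd.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"packaged fixture {name} is corrupted: sha256 {digest} != {_CHECKSUMS[name]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def titration_design() -> pd.DataFrame:
    """Sample-preparation design: pipetted volumes and resulting overall
    concentrations (uM). Ligand stock is 200 uM into a 100 uL sample, so
    L0_uM = 2 * oligo_stock_uL."""
    return _load("table1_design.csv")


def blank_abundances() -> pd.DataFrame:
    """Free-protein +8 total ion abundances of the six no-ligand replicates."""
    return _load("table4_blank_abundance.csv")


def titration_abundances() -> pd.DataFrame:
    """Free/bound +8 total ion abundances for both ligands at 5-40 uM,
    three replicates each (long format, concentrations in uM)."""
    return _load("table5_abundance.csv")


def expected_report() -> pd.DataFrame:
    """The published per-replicate R (2 d.p.) and Kd in uM (1 d.p.),
    including the negative apparent Kd values below 40 uM ligand."""
    return _load("table6_expected.csv")


def titration_model(P0_uM: float = 40.9) -> TitrationModel:
    """The packaged abundance table as a ready-to-fit :class:`TitrationModel`."""
    df = titration_abundances().copy()
    df["sample_id"] = (
        df["ligand"] + "_" + df["L0_uM"].astype(str) + "uM_r" + df["replicate"].astype(str)
    )
    df["P0"] = P0_uM
    df = df.rename(columns={"L0_uM": "L0"})
    return TitrationModel.from_dataframe(
        df[["sample_id", "ligand", "P0", "L0", "replicate", "ab_free", "ab_bound"]],
        concentration_unit="uM",
    )
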