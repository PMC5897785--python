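"""Scan reading, averaging, and total-ion-abundance integration.

The measurement chain mirrors how ion-trap titration data are processed:
all full scans of an acquisition are averaged into one spectrum, and the
"total ion abundance" of a species is the plain sum of intensities at every
point falling inside its closed m/z integration window.

Input formats: plain mzML and long-format CSV peak lists with columns
``scan_id, mz, intensity``. Profile and centroided data are both accepted;
averaging requires identical m/z grids unless a bin width is given, in which
case centroids are pooled and binned.

The mzML support here is deliberately compact: an accession-driven reader
for MS1 spectra (32/64-bit float binary arrays, zlib or uncompressed) and a
matching writer, covering the subset of mzML 1.1 that direct-infusion
intact-protein acquisitions and this package's simulator produce.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .ladder import IntegrationWindow

__all__ = [
    "SpectrumScan",
    "AveragedSpectrum",
    "AbundanceMeasurement",
    "read_scans",
    "write_scans_csv",
    "write_scans_mzml",
    "average_scans",
    "integrate_window",
]


class SpectrumFormatError(ValueError):
    """A scan file violates the format contract (unsorted m/z, negative
    intensity, empty file, ...)."""


@dataclass
class SpectrumScan:
    """One acquired scan: parallel m/z and intensity arrays.

    ``mz`` must be strictly increasing and intensities non-negative;
    violations raise at construction, naming the scan.
    """

    mz: np.ndarray
    intensity: np.ndarray
    mode: str = "profile"  # "profile" | "centroid"
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise SpectrumFormatError(
                f"scan {self.scan_id!r}: mz and intensity must be equal-length 1-d arrays"
            )
        if self.mz.size == 0:
            raise SpectrumFormatError(f"scan {self.scan_id!r}: empty scan")
        if np.any(np.diff(self.mz) <= 0):
            bad = int(np.argmax(np.diff(self.mz) <= 0))
            raise SpectrumFormatError(
                f"scan {self.scan_id!r}: m/z not strictly increasing near index {bad} "
                f"(m/z {self.mz[bad]:g})"
            )
        if np.any(self.intensity < 0):
            bad = int(np.argmax(self.intensity < 0))
            raise SpectrumFormatError(
                f"scan {self.scan_id!r}: negative intensity at m/z {self.mz[bad]:g}"
            )
        if self.mode not in ("profile", "centroid"):
            raise SpectrumFormatError(f"scan {self.scan_id!r}: unknown mode {self.mode!r}")


@dataclass
class AveragedSpectrum:
    """Mean spectrum over an acquisition's scans."""

    mz: np.ndarray
    intensity: np.ndarray
    n_scans: int

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")


@dataclass
class AbundanceMeasurement:
    """Total ion abundance of one species inside its integration window."""

    species: str
    window: IntegrationWindow
    total_abundance: float


def read_scans(source: str | Path) -> list[SpectrumScan]:
    """Read scans from an mzML file or a long-format CSV peak list.

    The CSV dialect is ``scan_id, mz, intensity`` with one row per point;
    scans are returned in first-appearance (acquisition) order.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise SpectrumFormatError(f"{path}: empty file")
    if path.suffix.lower() == ".mzml":
        return _read_mzml(path)
    return _read_csv(path)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values).

    Kind is 'mz' (MS:1000514), 'intensity' (MS:1000515) or None for other
    array types. Handles 64-bit (MS:1000523) and 32-bit (MS:1000521) floats,
    zlib-compressed (MS:1000574) or uncompressed (MS:1000576) payloads.
    """
    kind = None
    dtype = "<f8"
    compressed = False
    payload = b""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
            elif acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
        elif tag == "binary":
            payload = base64.b64decode(child.text or "")
    if compressed:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[SpectrumScan]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SpectrumFormatError(f"{path}: not well-formed mzML ({exc})") from exc
    scans = []
    for spec in root.iter():
        if _local(spec.tag) != "spectrum":
            continue
        mode = "profile"
        arrays: dict[str, np.ndarray] = {}
        for child in spec.iter():
            tag = _local(child.tag)
            if tag == "cvParam" and child.get("accession") == "MS:1000127":
                mode = "centroid"
            elif tag == "binaryDataArray":
                kind, values = _decode_binary_array(child)
                if kind:
                    arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumFormatError(
                f"{path}: spectrum {spec.get('id')!r} lacks m/z or intensity array"
            )
        scans.append(
            SpectrumScan(
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                mode=mode,
                scan_id=spec.get("id", ""),
            )
        )
    if not scans:
        raise SpectrumFormatError(f"{path}: no spectra found")
    return scans


def _read_csv(path: Path) -> list[SpectrumScan]:
    df = pd.read_csv(path)
    required = {"scan_id", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise SpectrumFormatError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    if df.empty:
        raise SpectrumFormatError(f"{path}: no data rows")
    scans = []
    for scan_id in df["scan_id"].unique():  # first-appearance order
        sub = df[df["scan_id"] == scan_id]
        scans.append(
            SpectrumScan(
                mz=sub["mz"].to_numpy(),
                intensity=sub["intensity"].to_numpy(),
                scan_id=str(scan_id),
            )
        )
    return scans


def write_scans_csv(scans: Sequence[SpectrumScan], path: str | Path) -> None:
    """Write scans as a long-format CSV peak list (scan_id, mz, intensity)."""
    frames = [
        pd.DataFrame({"scan_id": s.scan_id or str(i), "mz": s.mz, "intensity": s.intensity})
        for i, s in enumerate(scans)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --- minimal mzML writer -----------------------------------------------------
# Plain (unindexed) mzML 1.1 with 64-bit little-endian zlib-compressed binary
# arrays; enough structure for standard readers to recover id, m/z and
# intensity arrays and the profile/centroid flag.

def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *np.asarray(values, dtype=float))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="nativekd" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="nativekd"/>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="{id}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_scans_mzml(scans: Sequence[SpectrumScan], path: str | Path) -> None:
    """Write scans as plain mzML 1.1 (64-bit float, zlib-compressed arrays)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MZML_HEADER.format(count=len(scans)))
        for i, scan in enumerate(scans):
            mz_b64 = _encode_array(scan.mz)
            int_b64 = _encode_array(scan.intensity)
            if scan.mode == "centroid":
                mode_acc, mode_name = "MS:1000127", "centroid spectrum"
            else:
                mode_acc, mode_name = "MS:1000128", "profile spectrum"
            fh.write(
                _MZML_SPECTRUM.format(
                    index=i,
                    id=escape(scan.scan_id or f"scan={i + 1}"),
                    npts=scan.mz.size,
                    mode_acc=mode_acc,
                    mode_name=mode_name,
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_MZML_FOOTER)
    # cheap well-formedness check so a truncated write fails loudly
    ET.parse(path)


# --- averaging and integration ----------------------------------------------

def average_scans(
    scans: Sequence[SpectrumScan],
    bin_width: float | None = None,
) -> AveragedSpectrum:
    """Arithmetic-mean spectrum across scans.

    Profile scans on one shared m/z grid are averaged point-wise. Scans on
    differing grids (or centroided peak lists) require ``bin_width``: all
    points are pooled, assigned to bins of that width, and per-bin summed
    intensities are averaged over the number of scans.
    """
    if not scans:
        raise ValueError("need at least one scan to average")
    grids_match = all(
        s.mz.shape == scans[0].mz.shape and np.array_equal(s.mz, scans[0].mz)
        for s in scans[1:]
    )
    if grids_match and bin_width is None:
        mean = np.mean([s.intensity for s in scans], axis=0)
        return AveragedSpectrum(mz=scans[0].mz.copy(), intensity=mean, n_scans=len(scans))
    if bin_width is None:
        raise ValueError(
            "scans are not on a shared m/z grid; pass bin_width to pool and bin them"
        )
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    all_mz = np.concatenate([s.mz for s in scans])
    all_int = np.concatenate([s.intensity for s in scans])
    lo = np.floor(all_mz.min() / bin_width) * bin_width
    idx = np.floor((all_mz - lo) / bin_width).astype(int)
    n_bins = idx.max() + 1
    sums = np.bincount(idx, weights=all_int, minlength=n_bins)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width
    occupied = np.bincount(idx, minlength=n_bins) > 0
    return AveragedSpectrum(
        mz=centers[occupied],
        intensity=sums[occupied] / len(scans),
        n_scans=len(scans),
    )


def integrate_window(
    spectrum: AveragedSpectrum, window: IntegrationWindow
) -> AbundanceMeasurement:
    """Total ion abundance: sum of intensities at all points with
    ``window.lo <= mz <= window.hi`` (boundaries inclusive).

    A window with no overlap with the spectrum yields abundance 0 with a
    warning rather than an error.
    """
    mask = (spectrum.mz >= window.lo) & (spectrum.mz <= window.hi)
    if not mask.any():
        warnings.warn(
            f"window {window.species!r} [{window.lo:.1f}, {window.hi:.1f}] contains "
            f"no spectrum points (spectrum spans {spectrum.mz[0]:.1f}-{spectrum.mz[-1]:.1f})",
            stacklevel=2,
        )
    return AbundanceMeasurement(
        species=window.species,
        window=window,
        total_abundance=float(spectrum.intensity[mask].sum()),
    )


def measure_abundances(
    spectrum: AveragedSpectrum, windows: Iterable[IntegrationWindow]
) -> dict[str, AbundanceMeasurement]:
    """Integrate several windows against one averaged spectrum."""
    return {w.species: integrate_window(spectrum, w) for w in windows}
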