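"""Feature tables, MS2 spectra and in-source artifact detection.

A *feature* is one detected ionic species extracted from the
four-dimensional LC-TIMS-MS data space (m/z, retention time, ion
mobility/CCS, intensity).  Feature tables travel as per-sample UTF-8 CSV
with a mandatory header; MS2 spectra travel as MGF (via pyteomics).

In-source fragmentation produces MS1 peaks (typically ``[M-H2O+H]+``)
that mimic distinct compounds at the same retention time as their
precursor; :func:`detect_insource_artifacts` links such child features to
their parents so the classifier never assigns them a chemical class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from .chem_core import WATER_MASS

__all__ = [
    "Feature4D",
    "MS2Spectrum",
    "ArtifactLink",
    "FormatError",
    "FEATURE_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "read_ms2_mgf",
    "write_ms2_mgf",
    "detect_insource_artifacts",
    "DEFAULT_NEUTRAL_LOSSES",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


# --------------------------------------------------------------------------
# Data model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature4D:
    """One detected species in a sample.

    ``ccs`` (collisional cross section, A^2) and ``mobility`` (1/k0,
    V s/cm^2) are optional: not every feature gets a mobility assignment.
    ``ms2_ref`` names the linked MS2 spectrum, if any.
    """

    feature_id: str
    sample_id: str
    mz: float
    rt: float  # minutes
    intensity: float
    snr: float | None = None
    ccs: float | None = None
    mobility: float | None = None
    ms2_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: mz must be positive")
        if self.rt < 0:
            raise ValueError(f"{self.feature_id}: rt must be >= 0")
        if self.intensity < 0:
            raise ValueError(f"{self.feature_id}: intensity must be >= 0")
        if self.snr is not None and self.snr < 0:
            raise ValueError(f"{self.feature_id}: snr must be >= 0")
        if self.ccs is not None and self.ccs <= 0:
            raise ValueError(f"{self.feature_id}: ccs must be positive when present")


@dataclass(frozen=True)
class MS2Spectrum:
    """A product-ion spectrum: precursor m/z plus (m/z, intensity) peaks,
    sorted ascending by m/z."""

    spectrum_id: str
    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    collision_energy: str | None = None  # metadata, e.g. "25-50 eV"

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor_mz must be positive")
        if not self.peaks:
            raise ValueError("spectrum must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be >= 0")

    def intensity_at(self, mz: float, tol: float) -> float:
        """Summed intensity of peaks within ``tol`` Da of ``mz``."""
        return sum(i for m, i in self.peaks if abs(m - mz) <= tol)


@dataclass(frozen=True)
class ArtifactLink:
    """Child feature attributed to in-source fragmentation of a parent."""

    child_id: str
    parent_id: str
    neutral_loss: float  # Da, parent.mz - child.mz
    rt_delta: float  # minutes, child.rt - parent.rt
    loss_name: str = "H2O"


# --------------------------------------------------------------------------
# Feature-table CSV
# --------------------------------------------------------------------------

FEATURE_COLUMNS = (
    "feature_id",
    "sample_id",
    "mz",
    "rt_min",
    "ccs_A2",
    "mobility_1k0",
    "intensity",
    "snr",
    "ms2_ref",
)

_OPTIONAL_FLOAT = {"ccs_A2", "mobility_1k0", "snr"}


def write_feature_table(features: Sequence[Feature4D], path: str | Path) -> None:
    """Write features to the documented CSV dialect (UTF-8, '.' decimal,
    empty string for absent optionals).  Lossless at repr precision."""
    rows = []
    for f in features:
        rows.append(
            {
                "feature_id": f.feature_id,
                "sample_id": f.sample_id,
                "mz": repr(f.mz),
                "rt_min": repr(f.rt),
                "ccs_A2": "" if f.ccs is None else repr(f.ccs),
                "mobility_1k0": "" if f.mobility is None else repr(f.mobility),
                "intensity": repr(f.intensity),
                "snr": "" if f.snr is None else repr(f.snr),
                "ms2_ref": f.ms2_ref or "",
            }
        )
    pd.DataFrame(rows, columns=list(FEATURE_COLUMNS)).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> list[Feature4D]:
    """Read the CSV dialect written by :func:`write_feature_table`.

    Raises :class:`FormatError` naming the first missing mandatory column,
    or the row number of the first non-numeric mandatory value.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected a header") from None
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    features: list[Feature4D] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        def fval(col: str, *, optional: bool = False) -> float | None:
            raw = getattr(row, col)
            if raw == "":
                if optional:
                    return None
                raise FormatError(f"{path}: row {idx}: empty value in column {col!r}")
            try:
                return float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}: row {idx}: non-numeric value {raw!r} in column {col!r}"
                ) from None

        features.append(
            Feature4D(
                feature_id=row.feature_id,
                sample_id=row.sample_id,
                mz=fval("mz"),
                rt=fval("rt_min"),
                ccs=fval("ccs_A2", optional=True),
                mobility=fval("mobility_1k0", optional=True),
                intensity=fval("intensity"),
                snr=fval("snr", optional=True),
                ms2_ref=row.ms2_ref or None,
            )
        )
    return features


# --------------------------------------------------------------------------
# MGF
# --------------------------------------------------------------------------


def write_ms2_mgf(spectra: Sequence[MS2Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; TITLE carries the spectrum id, PEPMASS the
    precursor m/z (6 dp). Round trips losslessly at that precision."""
    entries = []
    for s in spectra:
        params: dict = {"title": s.spectrum_id, "pepmass": round(s.precursor_mz, 6)}
        if s.collision_energy:
            params["collision_energy"] = s.collision_energy
        entries.append(
            {
                "params": params,
                "m/z array": [round(m, 6) for m, _ in s.peaks],
                "intensity array": [i for _, i in s.peaks],
            }
        )
    _mgf.write(entries, str(path), write_charges=False, file_mode="w")


def read_ms2_mgf(path: str | Path) -> list[MS2Spectrum]:
    """Read an MGF file into :class:`MS2Spectrum` records.

    Each BEGIN IONS block must carry TITLE and PEPMASS; violations raise
    :class:`FormatError`.
    """
    text = Path(path).read_text(encoding="utf-8")
    if text.count("BEGIN IONS") != text.count("END IONS"):
        raise FormatError(f"{path}: unterminated BEGIN IONS block")
    spectra: list[MS2Spectrum] = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for entry in reader:
                params = entry.get("params", {})
                title = params.get("title")
                if not title:
                    raise FormatError(f"{path}: spectrum block without TITLE")
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise FormatError(f"{path}: spectrum {title!r} lacks PEPMASS")
                precursor = pepmass[0] if isinstance(pepmass, (tuple, list)) else float(pepmass)
                if precursor is None or (isinstance(precursor, float) and math.isnan(precursor)):
                    raise FormatError(f"{path}: spectrum {title!r} lacks PEPMASS")
                peaks = tuple(
                    zip(
                        (float(m) for m in entry["m/z array"]),
                        (float(i) for i in entry["intensity array"]),
                    )
                )
                if not peaks:
                    raise FormatError(f"{path}: spectrum {title!r} has no peaks")
                spectra.append(
                    MS2Spectrum(
                        spectrum_id=str(title),
                        precursor_mz=float(precursor),
                        peaks=peaks,
                        collision_energy=params.get("collision_energy"),
                    )
                )
    except _mgf.aux.PyteomicsError as exc:  # malformed numeric lines etc.
        raise FormatError(f"{path}: {exc}") from exc
    return spectra


# --------------------------------------------------------------------------
# In-source artifact detection
# --------------------------------------------------------------------------

DEFAULT_NEUTRAL_LOSSES: tuple[tuple[str, float], ...] = (("H2O", WATER_MASS),)


def detect_insource_artifacts(
    features: Sequence[Feature4D],
    losses: Sequence[tuple[str, float]] = DEFAULT_NEUTRAL_LOSSES,
    mz_tol_ppm: float = 5.0,
    rt_tol_min: float = 0.05,
) -> list[ArtifactLink]:
    """Link co-eluting feature pairs whose m/z difference matches a neutral loss.

    Every (child, parent) pair with ``parent.mz - child.mz`` within
    ``mz_tol_ppm`` (relative to the parent m/z) of a listed loss and
    \\|rt difference\\| <= ``rt_tol_min`` is linked; a child may link to
    several parents (downstream code flags such children as ambiguous).
    Links are returned sorted by \\|rt_delta\\| then ids, so the result is
    independent of input order.
    """
    if not losses:
        raise ValueError("losses must be non-empty")
    links: list[ArtifactLink] = []
    for child in features:
        for parent in features:
            if parent.feature_id == child.feature_id or parent.mz <= child.mz:
                continue
            rt_delta = child.rt - parent.rt
            if abs(rt_delta) > rt_tol_min:
                continue
            diff = parent.mz - child.mz
            for name, loss in losses:
                if abs(diff - loss) <= parent.mz * mz_tol_ppm * 1e-6:
                    links.append(
                        ArtifactLink(
                            child_id=child.feature_id,
                            parent_id=parent.feature_id,
                            neutral_loss=diff,
                            rt_delta=rt_delta,
                            loss_name=name,
                        )
                    )
                    break
    links.sort(key=lambda l: (abs(l.rt_delta), l.child_id, l.parent_id))
    return links
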