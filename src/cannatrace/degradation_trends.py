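"""Storage-stability trend analysis across conditions and time points.

The study design: two e-liquid sources (plant-derived isolate vs
synthetic CBD), four storage conditions (light/ambient 25 C 60 % RH,
dark/ambient, stressed 40 C 75 % RH, refrigerated 4 C dark), five
replicates each, sampled on days 1, 8, 15, 22 and 29.

Abundances are normalised per sample to the deuterated internal standard
(D3-Delta9-THC, 40 ng/mL in the dilution solvent), gated at the limit of
quantification (signal-to-noise >= 10), summarised into a compound x
condition x day trend table, and tested for monotone trends with an
ordinary-least-squares slope plus an internally implemented Mann-Kendall
test (exact S-statistic null for n <= 10 time points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import ElementalFormula, PROTONATED, ion_mz
from .feature_io import Feature4D

__all__ = [
    "CONDITIONS",
    "STUDY_DAYS",
    "StudySample",
    "CalibrationCurve",
    "TrendStat",
    "SourceReport",
    "internal_standard_mz",
    "normalize_to_is",
    "InternalStandardError",
    "loq_gate",
    "build_trend_table",
    "trend_stat",
    "mann_kendall",
    "fit_calibration",
    "quantify",
    "source_markers",
    "PLANT_MARKERS",
    "SYNTHETIC_MARKERS",
    "SHARED_COMPOUNDS",
]

CONDITIONS = (
    "light_ambient_25C_60RH",
    "dark_ambient_25C_60RH",
    "stressed_40C_75RH",
    "refrigerated_4C",
)
STUDY_DAYS = (1, 8, 15, 22, 29)
N_REPLICATES = 5
LOQ_SNR = 10.0

#: Composition of the internal standard, D3-Delta9-THC.
IS_FORMULA = ElementalFormula.parse("C21H27D3O2")


def internal_standard_mz() -> float:
    """[M+H]+ m/z of D3-Delta9-THC, computed from its composition."""
    return ion_mz(IS_FORMULA, PROTONATED)


@dataclass(frozen=True)
class StudySample:
    sample_id: str
    condition: str
    day: int
    replicate: int
    source: str  # plant | synthetic

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.day not in STUDY_DAYS:
            raise ValueError(f"day must be one of {STUDY_DAYS}, got {self.day}")
        if not 1 <= self.replicate <= N_REPLICATES:
            raise ValueError(f"replicate must be 1..{N_REPLICATES}")
        if self.source not in ("plant", "synthetic"):
            raise ValueError(f"source must be plant or synthetic, got {self.source!r}")


# --------------------------------------------------------------------------
# Internal-standard normalisation and LOQ gating
# --------------------------------------------------------------------------


class InternalStandardError(ValueError):
    """Zero or multiple internal-standard candidates in a sample."""


def normalize_to_is(
    features: Sequence[Feature4D],
    is_mz: float | None = None,
    is_rt: float = 11.20,
    mz_tol_ppm: float = 5.0,
    rt_tol_min: float = 0.1,
) -> dict[str, float]:
    """Divide every analyte intensity by the internal-standard intensity.

    Exactly one feature must match the IS within the m/z and RT
    tolerances; zero or several raise :class:`InternalStandardError` so
    the caller can exclude and log the sample.  Returns
    feature_id -> normalised abundance for the non-IS features.
    """
    target = internal_standard_mz() if is_mz is None else is_mz
    hits = [
        f
        for f in features
        if abs(f.mz - target) <= target * mz_tol_ppm * 1e-6 and abs(f.rt - is_rt) <= rt_tol_min
    ]
    if len(hits) != 1:
        raise InternalStandardError(
            f"expected exactly 1 internal-standard feature, found {len(hits)}"
        )
    is_feature = hits[0]
    if is_feature.intensity <= 0:
        raise InternalStandardError("internal-standard intensity is zero")
    return {
        f.feature_id: f.intensity / is_feature.intensity
        for f in features
        if f.feature_id != is_feature.feature_id
    }


def loq_gate(feature: Feature4D, snr_threshold: float = LOQ_SNR) -> str:
    """``quantifiable`` iff snr >= threshold (boundary inclusive);
    a missing snr is conservatively ``below_loq``."""
    if feature.snr is None:
        import warnings

        warnings.warn(f"{feature.feature_id}: no snr recorded, treating as below LOQ")
        return "below_loq"
    return "quantifiable" if feature.snr >= snr_threshold else "below_loq"


# --------------------------------------------------------------------------
# Trend table
# --------------------------------------------------------------------------


def build_trend_table(
    observations: pd.DataFrame,
    snr_threshold: float = LOQ_SNR,
) -> pd.DataFrame:
    """Summarise per-replicate observations into the trend table.

    ``observations`` columns: compound, condition, day, replicate,
    norm_abundance, snr.  Returns one row per (compound, condition, day)
    with mean and sd over the *quantifiable* replicates only (below-LOQ
    replicates are counted, not imputed), deterministically sorted.
    """
    required = {"compound", "condition", "day", "replicate", "norm_abundance", "snr"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    df = observations.copy()
    df["quant"] = df["snr"] >= snr_threshold
    rows = []
    for (compound, condition, day), cell in df.groupby(
        ["compound", "condition", "day"], sort=True
    ):
        quant = cell.loc[cell["quant"], "norm_abundance"]
        rows.append(
            {
                "compound": compound,
                "condition": condition,
                "day": day,
                "mean_norm_abundance": float(quant.mean()) if len(quant) else float("nan"),
                "sd": float(quant.std(ddof=1)) if len(quant) > 1 else 0.0,
                "n": int(len(cell)),
                "below_loq_count": int((~cell["quant"]).sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "condition",
            "day",
            "mean_norm_abundance",
            "sd",
            "n",
            "below_loq_count",
        ],
    )


# --------------------------------------------------------------------------
# Trend statistics
# --------------------------------------------------------------------------


def _mk_exact_sf(n: int, s: int) -> float:
    """Pr(S >= s) under the Mann-Kendall null for n untied observations.

    S = (concordant - discordant) pairs = n(n-1)/2 - 2 * inversions, and
    the inversion count of a uniform random permutation has generating
    polynomial prod_{i=1..n} (1 + x + ... + x^(i-1)); the tail follows by
    direct summation.
    """
    coeffs = np.array([1.0])
    for i in range(1, n + 1):
        coeffs = np.convolve(coeffs, np.ones(i))
    total = coeffs.sum()  # n!
    max_pairs = n * (n - 1) // 2
    # S = max_pairs - 2k for inversion count k
    prob = 0.0
    for k in range(len(coeffs)):
        if max_pairs - 2 * k >= s:
            prob += coeffs[k]
    return prob / total


def mann_kendall(values: Sequence[float], alpha: float = 0.05) -> tuple[int, float, str]:
    """Mann-Kendall monotonic-trend test.

    Returns ``(S, p_two_sided, verdict)`` with verdict one of
    ``increasing`` / ``decreasing`` / ``none``.  For n <= 10 without ties
    the exact null distribution of S is used; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    x = [float(v) for v in values]
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 observations")
    s = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            s += (x[j] > x[i]) - (x[j] < x[i])
    has_ties = len(set(x)) != n
    if s == 0:
        return 0, 1.0, "none"
    if n <= 10 and not has_ties:
        p = 2.0 * _mk_exact_sf(n, abs(s))
    else:
        counts = pd.Series(x).value_counts().to_numpy()
        var = (n * (n - 1) * (2 * n + 5) - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
        z = (abs(s) - 1) / math.sqrt(var) if var > 0 else 0.0
        p = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2.0))))
    p = min(p, 1.0)
    if p <= alpha:
        return s, p, "increasing" if s > 0 else "decreasing"
    return s, p, "none"


@dataclass(frozen=True)
class TrendStat:
    slope: float  # per day, ordinary least squares
    intercept: float
    s_statistic: int
    p_value: float
    verdict: str  # increasing | decreasing | none


def trend_stat(series: Sequence[tuple[float, float]], alpha: float = 0.05) -> TrendStat:
    """OLS slope plus Mann-Kendall monotonicity verdict for a
    (day, mean abundance) series; requires >= 3 time points."""
    if len(series) < 3:
        raise ValueError("trend needs at least 3 time points")
    days = np.array([d for d, _ in series], dtype=float)
    vals = np.array([v for _, v in series], dtype=float)
    slope, intercept = np.polyfit(days, vals, 1)
    s, p, verdict = mann_kendall(list(vals), alpha=alpha)
    return TrendStat(float(slope), float(intercept), s, p, verdict)


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    points: tuple[tuple[float, float], ...]  # (concentration, response)
    slope: float
    intercept: float
    r_squared: float


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary-least-squares line through (concentration, response) points."""
    if len({c for c, _ in points}) < 2:
        raise ValueError("calibration needs >= 2 distinct concentrations")
    x = np.array([c for c, _ in points], dtype=float)
    y = np.array([r for _, r in points], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(tuple((float(c), float(r)) for c, r in points), float(slope), float(intercept), r2)


def quantify(curve: CalibrationCurve, response: float) -> tuple[float, bool]:
    """Invert the calibration line: ``(response - intercept) / slope``.

    Returns ``(concentration, below_range)``; a negative inversion is
    reported as (0-clipped value, True) rather than a negative amount.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (response - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return conc, False


# --------------------------------------------------------------------------
# Source markers
# --------------------------------------------------------------------------

#: Compounds observed only in the plant-derived (isolate) formulation.
PLANT_MARKERS = frozenset({"CBDV", "CBDP", "CBDH", "6a-OH-CBD", "7-OH-CBD"})
#: Observed only in the synthetic formulation.
SYNTHETIC_MARKERS = frozenset({"CBDH-isomer"})
#: Present in both sources — never discriminative (CBDB in particular was
#: found in synthetic material despite earlier reports).
SHARED_COMPOUNDS = frozenset({"CBDB", "OH-CBE", "HU-331", "HU-331-like"})


@dataclass(frozen=True)
class SourceReport:
    verdict: str  # plant | synthetic | indeterminate
    plant_markers_detected: tuple[str, ...]
    synthetic_markers_detected: tuple[str, ...]
    shared_detected: tuple[str, ...]


def source_markers(detected_compounds: Sequence[str]) -> SourceReport:
    """Call the CBD source (plant vs synthetic) from marker compounds.

    Shared compounds (notably CBDB) are reported but never used as
    discriminators; detecting markers of both classes, or of neither,
    yields ``indeterminate``.
    """
    detected = set(detected_compounds)
    plant = tuple(sorted(detected & PLANT_MARKERS))
    synth = tuple(sorted(detected & SYNTHETIC_MARKERS))
    shared = tuple(sorted(detected & SHARED_COMPOUNDS))
    if plant and not synth:
        verdict = "plant"
    elif synth and not plant:
        verdict = "synthetic"
    else:
        verdict = "indeterminate"
    return SourceReport(verdict, plant, synth, shared)
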