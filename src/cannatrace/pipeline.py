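"""End-to-end orchestration: isotope grouping -> artifact detection ->
library matching -> unknown classification -> trend assembly.

This layer glues the pure modules into the analysis flow and owns the
tabular output schema; the command-line interface in :mod:`cannatrace.cli`
is a thin wrapper around these functions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import IsotopePattern
from .degradation_trends import (
    CONDITIONS,
    InternalStandardError,
    LOQ_SNR,
    build_trend_table,
    normalize_to_is,
    source_markers,
    trend_stat,
)
from .feature_io import (
    ArtifactLink,
    Feature4D,
    MS2Spectrum,
    detect_insource_artifacts,
    read_feature_table,
    read_ms2_mgf,
)
from .spectral_library import (
    LibraryEntry,
    MatchTolerances,
    load_default_library,
    match_feature,
)
from .unknown_classifier import ClassifierConfig, classify_unknown, load_default_rules

logger = logging.getLogger("cannatrace")

__all__ = [
    "IS_ABBREV",
    "group_isotope_companions",
    "annotate_features",
    "annotate_sample_files",
    "trend_analysis",
    "parse_sample_id",
]

IS_ABBREV = "IS-D3-THC"

#: m/z spacing of an M+1 isotopologue and matching tolerances.
_M1_DELTA = 1.00336
_M1_MZ_TOL = 0.01
_M1_RT_TOL = 0.05


def group_isotope_companions(
    features: Sequence[Feature4D],
) -> tuple[list[Feature4D], dict[str, IsotopePattern], set[str]]:
    """Split features into primaries and their M+1 isotope companions.

    A companion is a smaller co-eluting feature one isotope spacing above
    a primary.  Returns (primaries, observed isotope pattern per primary
    id, companion ids).  A primary without a companion gets no observed
    pattern (the isotope criterion then fails rather than being skipped).
    """
    companion_of: dict[str, str] = {}
    by_id = {f.feature_id: f for f in features}
    for f in features:
        best: tuple[float, str] | None = None
        for g in features:
            if g.feature_id == f.feature_id or g.intensity >= f.intensity:
                continue
            if abs(g.rt - f.rt) > _M1_RT_TOL:
                continue
            d = abs(g.mz - (f.mz + _M1_DELTA))
            if d <= _M1_MZ_TOL and (best is None or d < best[0]):
                best = (d, g.feature_id)
        if best is not None:
            companion_of[f.feature_id] = best[1]
    companion_ids = set(companion_of.values())
    primaries = [f for f in features if f.feature_id not in companion_ids]
    patterns: dict[str, IsotopePattern] = {}
    for fid, cid in companion_of.items():
        if fid in companion_ids:
            continue  # chains (M+2 of something) never seed a pattern
        f, c = by_id[fid], by_id[cid]
        if f.intensity <= 0:
            continue
        rel = min(c.intensity / f.intensity, 1.0)
        if rel < 1.0 and rel > 0:
            patterns[fid] = IsotopePattern(((f.mz, 1.0), (c.mz, rel)))
    return primaries, patterns, companion_ids


_ANNOTATION_COLUMNS = [
    "feature_id",
    "sample_id",
    "mz",
    "rt_min",
    "intensity",
    "snr",
    "role",
    "match_abbrev",
    "match_level",
    "delta_ppm",
    "delta_rt",
    "delta_ccs_pct",
    "isotope_score",
    "ms2_score",
    "class_label",
    "class_parent",
    "class_confidence",
    "class_evidence",
]


def annotate_features(
    features: Sequence[Feature4D],
    spectra: Mapping[str, MS2Spectrum],
    library: Sequence[LibraryEntry] | None = None,
    tolerances: MatchTolerances = MatchTolerances(),
    classifier: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Annotate one sample's features: one output row per feature.

    Isotope companions are set aside; primaries are matched against the
    library on the five criteria; features without a *validated* match go
    to artifact detection and rule-based classification.
    """
    library = library if library is not None else load_default_library()
    classifier = classifier or load_default_rules()
    parents = {e.abbreviation: e for e in library}

    primaries, patterns, companion_ids = group_isotope_companions(features)
    artifacts: list[ArtifactLink] = detect_insource_artifacts(primaries)

    rows = []
    for f in features:
        row: dict = {
            "feature_id": f.feature_id,
            "sample_id": f.sample_id,
            "mz": f.mz,
            "rt_min": f.rt,
            "intensity": f.intensity,
            "snr": f.snr,
            "role": "isotope" if f.feature_id in companion_ids else "primary",
            "match_abbrev": "",
            "match_level": "",
            "delta_ppm": np.nan,
            "delta_rt": np.nan,
            "delta_ccs_pct": np.nan,
            "isotope_score": np.nan,
            "ms2_score": np.nan,
            "class_label": "",
            "class_parent": "",
            "class_confidence": "",
            "class_evidence": "",
        }
        if f.feature_id in companion_ids:
            rows.append(row)
            continue
        ms2 = spectra.get(f.ms2_ref) if f.ms2_ref else None
        results = match_feature(
            f, ms2, library, tolerances, isotope=patterns.get(f.feature_id)
        )
        best = results[0] if results else None
        if best is not None:
            row.update(
                match_abbrev=best.entry.abbreviation,
                match_level=best.level,
                delta_ppm=best.delta_ppm,
                delta_rt=best.delta_rt,
                delta_ccs_pct=np.nan if best.delta_ccs_pct is None else best.delta_ccs_pct,
                isotope_score=np.nan if best.isotope_score is None else best.isotope_score,
                ms2_score=np.nan if best.ms2_score is None else best.ms2_score,
            )
        if best is None or best.level != "validated":
            call = classify_unknown(f, ms2, artifacts, parents, classifier)
            row.update(
                class_label=call.label if call.label != "unclassified" else "",
                class_parent=call.parent_compound,
                class_confidence=call.confidence if call.label != "unclassified" else "",
                class_evidence="; ".join(call.evidence),
            )
        rows.append(row)
    df = pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS)
    n_val = int((df["match_level"] == "validated").sum())
    n_class = int((df["class_label"] != "").sum())
    logger.info(
        "annotated %d features: %d validated, %d classified, %d isotope companions",
        len(df),
        n_val,
        n_class,
        len(companion_ids),
    )
    return df


def annotate_sample_files(
    features_csv: str | Path,
    mgf_path: str | Path | None = None,
    library: Sequence[LibraryEntry] | None = None,
    tolerances: MatchTolerances = MatchTolerances(),
    classifier: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Annotate one sample from its feature CSV (and sibling MGF, if any)."""
    features = read_feature_table(features_csv)
    spectra: dict[str, MS2Spectrum] = {}
    if mgf_path is not None and Path(mgf_path).exists():
        spectra = {s.spectrum_id: s for s in read_ms2_mgf(mgf_path)}
    return annotate_features(features, spectra, library, tolerances, classifier)


def compound_identity(row: pd.Series) -> str:
    """The reported identity of an annotated feature: validated library
    abbreviation, else the degradation-class label, else empty."""
    if row["match_level"] == "validated":
        return row["match_abbrev"]
    return row["class_label"]


_SAMPLE_ID_RE = re.compile(
    r"^(?P<source>plant|synthetic)-(?P<condition>[A-Za-z0-9_]+)-d(?P<day>\d+)-r(?P<rep>\d+)$"
)


def parse_sample_id(sample_id: str) -> dict:
    """Decode source/condition/day/replicate from a study sample id."""
    m = _SAMPLE_ID_RE.match(sample_id)
    if not m:
        raise ValueError(f"sample id {sample_id!r} does not encode the study design")
    d = m.groupdict()
    return {
        "source": d["source"],
        "condition": d["condition"],
        "day": int(d["day"]),
        "replicate": int(d["rep"]),
    }


@dataclass(frozen=True)
class TrendAnalysis:
    trend_table: pd.DataFrame  # compound x condition x day summaries + slope/verdict
    slopes: pd.DataFrame  # compound x condition slopes and Mann-Kendall verdicts
    source_verdict: str
    excluded_samples: tuple[str, ...]


def trend_analysis(
    annotated: Mapping[str, pd.DataFrame],
    features_by_sample: Mapping[str, Sequence[Feature4D]],
    loq_snr: float = LOQ_SNR,
) -> TrendAnalysis:
    """Assemble the study trend table from per-sample annotations.

    ``annotated`` maps sample ids (encoding condition/day/replicate) to
    annotation frames; ``features_by_sample`` supplies the raw features
    for internal-standard normalisation.  Samples without exactly one IS
    feature are excluded and reported.  Cells where no replicate is
    quantifiable contribute a mean of zero to the slope fit (absence of
    quantifiable signal is treated as zero abundance for trends).
    """
    obs_rows = []
    excluded: list[str] = []
    detected: set[str] = set()
    for sample_id, df in sorted(annotated.items()):
        meta = parse_sample_id(sample_id)
        try:
            norm = normalize_to_is(list(features_by_sample[sample_id]))
        except InternalStandardError as exc:
            logger.warning("sample %s excluded: %s", sample_id, exc)
            excluded.append(sample_id)
            continue
        primary = df[df["role"] == "primary"]
        for _, row in primary.iterrows():
            identity = compound_identity(row)
            if not identity or identity == IS_ABBREV or identity == "in-source-artifact":
                continue
            detected.add(identity)
            obs_rows.append(
                {
                    "compound": identity,
                    "condition": meta["condition"],
                    "day": meta["day"],
                    "replicate": meta["replicate"],
                    "norm_abundance": norm.get(row["feature_id"], 0.0),
                    "snr": row["snr"] if pd.notna(row["snr"]) else 0.0,
                }
            )
    if not obs_rows:
        raise ValueError("no usable observations: cannot build trends")
    obs = (
        pd.DataFrame(obs_rows)
        .groupby(["compound", "condition", "day", "replicate"], as_index=False)
        .agg({"norm_abundance": "sum", "snr": "max"})
    )
    # A compound not detected in a sample is a real observation of zero
    # abundance (below LOQ), not a missing cell: complete the grid so the
    # day-1 absence of late-forming degradants anchors their trends.
    seen = set(zip(obs["compound"], obs["condition"], obs["day"], obs["replicate"]))
    fill = []
    included = [sid for sid in sorted(annotated) if sid not in set(excluded)]
    metas = [parse_sample_id(sid) for sid in included]
    for compound in obs["compound"].unique():
        for meta in metas:
            key = (compound, meta["condition"], meta["day"], meta["replicate"])
            if key not in seen:
                fill.append(
                    {
                        "compound": compound,
                        "condition": meta["condition"],
                        "day": meta["day"],
                        "replicate": meta["replicate"],
                        "norm_abundance": 0.0,
                        "snr": 0.0,
                    }
                )
    if fill:
        obs = pd.concat([obs, pd.DataFrame(fill)], ignore_index=True)
    table = build_trend_table(obs, snr_threshold=loq_snr)

    slope_rows = []
    for (compound, condition), sub in table.groupby(["compound", "condition"]):
        series = [
            (float(day), 0.0 if pd.isna(mean) else float(mean))
            for day, mean in zip(sub["day"], sub["mean_norm_abundance"])
        ]
        if len(series) < 3:
            raise ValueError(
                f"{compound}/{condition}: {len(series)} time points, need >= 3 for a trend"
            )
        stat = trend_stat(series)
        slope_rows.append(
            {
                "compound": compound,
                "condition": condition,
                "slope_per_day": stat.slope,
                "mk_s": stat.s_statistic,
                "mk_p": stat.p_value,
                "verdict": stat.verdict,
            }
        )
    slopes = pd.DataFrame(slope_rows)
    table = table.merge(slopes[["compound", "condition", "slope_per_day", "verdict"]],
                        on=["compound", "condition"], how="left")
    report = source_markers(sorted(detected))
    return TrendAnalysis(
        trend_table=table,
        slopes=slopes,
        source_verdict=report.verdict,
        excluded_samples=tuple(excluded),
    )
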