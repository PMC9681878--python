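"""Seeded generator emulating the UHPLC-TIMS-TOF feature data of the study.

The generator is the package's stand-in for the (undeposited) raw data:
it emits day-1 profiling fixtures whose compound presence/absence matches
the published day-1 table, full four-condition stability studies
(4 conditions x 5 days x 5 replicates) with planted linear degradation
kinetics, Gaussian m/z and RT noise, lognormal intensity noise, M+1
isotope companion peaks, in-source water-loss artifact children, and the
deuterated internal standard in every sample.  Planted-truth records are
emitted alongside every sample so recall/precision are computable.

All randomness flows from a single integer seed; identical (seed, config)
produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem_core import (
    ElementalFormula,
    PROTONATED,
    WATER_MASS,
    ion_mz,
    isotope_pattern,
)
from .degradation_trends import CONDITIONS, STUDY_DAYS, N_REPLICATES, internal_standard_mz
from .feature_io import Feature4D, MS2Spectrum, write_feature_table, write_ms2_mgf
from .spectral_library import LibraryEntry, build_default_roster, write_library

__all__ = [
    "GeneratorConfig",
    "GeneratedSample",
    "StabilityStudy",
    "generate_day1",
    "generate_stability_study",
    "generate_library_fixture",
    "generate_pseudo_ms3",
    "write_sample",
    "write_study",
    "PEAKS",
    "KINETICS_DEFAULTS",
    "IS_BASE_INTENSITY",
]

# --------------------------------------------------------------------------
# Study-condition constants
# --------------------------------------------------------------------------

IS_BASE_INTENSITY = 2.0e5
CBD_BASE_INTENSITY = 1.0e6
TRACE_INTENSITY = 2.0e3  # day-1 impurities sit just above the LOQ gate
NOISE_FLOOR = 100.0  # snr = intensity / noise_floor
ARTIFACT_FRACTION = 0.3  # in-source child intensity relative to its parent

#: MS2 fragment templates (m/z, relative intensity) for degradation-product
#: classes; library compounds use their library spectra.
_CLASS_MS2: Mapping[str, tuple[tuple[float, float], ...]] = {
    "OH-CBD": ((193.1228, 100.0),),
    "diOH-CBD": ((193.1228, 100.0),),
    "OH-CBE": ((135.0448, 60.0), (205.1227, 100.0)),
    "CBE-isomer": ((109.1042, 30.0), (135.0442, 60.0), (205.1224, 100.0)),
    "CBDH-isomer": ((193.1223, 25.0), (207.1380, 100.0)),
    # deliberately free of every diagnostic core fragment: this class is
    # called on composition + retention time only
    "HU-331-like": ((203.1067, 100.0), (311.2006, 40.0)),
}

#: Per-class condition -> slope (raw intensity units per day) defaults.
#: Orderings encode the study's qualitative findings: CBE-type products
#: grow fastest under stress/light, slowest refrigerated; HU-331 is
#: thermo- and photo-labile, so it accumulates most when refrigerated in
#: the dark; OH-CBE peaks highest at dark/ambient.  Magnitudes are
#: documented defaults, not literature values.
KINETICS_DEFAULTS: Mapping[str, Mapping[str, float]] = {
    "CBE": {
        "stressed_40C_75RH": 400.0,
        "light_ambient_25C_60RH": 380.0,
        "dark_ambient_25C_60RH": 120.0,
        "refrigerated_4C": 2.0,
    },
    "OH-CBD": {
        "stressed_40C_75RH": 100.0,
        "light_ambient_25C_60RH": 80.0,
        "dark_ambient_25C_60RH": 40.0,
        "refrigerated_4C": 1.0,
    },
    "OH-CBE": {
        "dark_ambient_25C_60RH": 150.0,
        "stressed_40C_75RH": 80.0,
        "light_ambient_25C_60RH": 70.0,
        "refrigerated_4C": 5.0,
    },
    "HU-331": {
        "refrigerated_4C": 60.0,
        "dark_ambient_25C_60RH": 30.0,
        "stressed_40C_75RH": 10.0,
        "light_ambient_25C_60RH": 2.0,
    },
    "HU-331-like": {
        "stressed_40C_75RH": 50.0,
        "light_ambient_25C_60RH": 20.0,
        "dark_ambient_25C_60RH": 15.0,
        "refrigerated_4C": 2.0,
    },
}


@dataclass(frozen=True)
class PeakSpec:
    """One chromatographic peak the generator can plant.

    ``day1`` / ``stability`` are (synthetic, plant) presence flags
    transcribed from the published day-1 and stressed-storage compound
    tables.  ``kinetics_key`` selects the slope family (None = constant
    abundance); ``base_intensity`` is the day-1 amplitude A0.
    """

    key: str  # unique, e.g. "OH-CBE@2.76"
    label: str  # compound name or degradation class
    formula: str  # neutral elemental composition
    rt: float
    day1: tuple[bool, bool]
    stability: tuple[bool, bool]
    kind: str  # library | class
    base_intensity: float
    kinetics_key: str | None = None
    ccs_override: float | None = None


def _p(key, label, formula, rt, day1, stab, kind, base, kin=None, ccs=None) -> PeakSpec:
    return PeakSpec(key, label, formula, rt, day1, stab, kind, base, kin, ccs)


Y, N = True, False

#: The planted peak roster.  Presence flags: (synthetic CBD, plant/isolate CBD).
PEAKS: tuple[PeakSpec, ...] = (
    _p("6a-OH-CBD", "6a-OH-CBD", "C21H30O3", 1.84, (N, Y), (N, Y), "library", TRACE_INTENSITY),
    _p("7-OH-CBD", "7-OH-CBD", "C21H30O3", 2.03, (N, Y), (N, Y), "library", TRACE_INTENSITY),
    _p("diOH-CBD@2.13", "diOH-CBD", "C21H30O4", 2.13, (N, N), (Y, Y), "class", 0.0, "OH-CBD"),
    _p("HU-331-like@2.42", "HU-331-like", "C21H28O3", 2.42, (Y, Y), (Y, N), "class", TRACE_INTENSITY, "HU-331-like"),
    _p("diOH-CBD@2.52", "diOH-CBD", "C21H30O4", 2.52, (N, N), (Y, Y), "class", 0.0, "OH-CBD"),
    _p("OH-CBE@2.76", "OH-CBE", "C21H30O4", 2.76, (Y, Y), (Y, Y), "class", TRACE_INTENSITY, "OH-CBE"),
    _p("CBE-isomer@2.85", "CBE-isomer", "C21H30O3", 2.85, (N, N), (Y, Y), "class", 0.0, "CBE", ccs=184.9),
    _p("CBDV", "CBDV", "C19H26O2", 3.20, (N, Y), (N, Y), "library", TRACE_INTENSITY),
    _p("OH-CBD@3.22", "OH-CBD", "C21H30O3", 3.22, (N, N), (Y, Y), "class", 0.0, "OH-CBD"),
    _p("OH-CBE@3.61", "OH-CBE", "C21H30O4", 3.61, (N, N), (Y, Y), "class", 0.0, "OH-CBE"),
    _p("OH-CBD@3.67", "OH-CBD", "C21H30O3", 3.67, (N, N), (Y, N), "class", 0.0, "OH-CBD"),
    _p("CBDB", "CBDB", "C20H28O2", 3.92, (Y, Y), (Y, Y), "library", TRACE_INTENSITY),
    _p("CBE", "CBE", "C21H30O3", 4.17, (N, N), (Y, Y), "library", 0.0, "CBE"),
    _p("OH-CBE@4.21", "OH-CBE", "C21H30O4", 4.21, (N, N), (Y, Y), "class", 0.0, "OH-CBE"),
    _p("OH-CBE@4.75", "OH-CBE", "C21H30O4", 4.75, (Y, Y), (Y, Y), "class", TRACE_INTENSITY, "OH-CBE"),
    _p("CBD", "CBD", "C21H30O2", 4.99, (Y, Y), (Y, Y), "library", CBD_BASE_INTENSITY),
    _p("CBDH", "CBDH", "C22H32O2", 6.56, (N, Y), (N, Y), "library", TRACE_INTENSITY),
    _p("CBDP", "CBDP", "C23H34O2", 8.95, (N, Y), (N, Y), "library", TRACE_INTENSITY),
    _p("CBDH-isomer@9.65", "CBDH-isomer", "C22H32O2", 9.65, (Y, N), (Y, N), "class", TRACE_INTENSITY),
    _p("HU-331", "HU-331", "C21H28O3", 9.92, (Y, Y), (Y, Y), "library", TRACE_INTENSITY, "HU-331"),
    _p("IS", "IS-D3-THC", "C21H27D3O2", 11.20, (Y, Y), (Y, Y), "library", IS_BASE_INTENSITY),
)

#: Peaks that shed an in-source water-loss child ion (the m/z 347.22 ->
#: 329.21 pathway): the dihydroxy-CBD and first hydroxy-CBE peaks.
DEFAULT_ARTIFACT_PARENTS: tuple[str, ...] = ("diOH-CBD@2.13", "OH-CBE@2.76")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    mass_noise_ppm_sd: float = 0.5
    rt_jitter_sd: float = 0.02  # minutes
    intensity_cv: float = 0.10
    ccs_noise_pct_sd: float = 0.2
    noise_floor: float = NOISE_FLOOR
    kinetics: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: KINETICS_DEFAULTS
    )
    artifact_parents: tuple[str, ...] = DEFAULT_ARTIFACT_PARENTS
    include_isotopes: bool = True

    def zero_noise(self) -> "GeneratorConfig":
        return replace(
            self, mass_noise_ppm_sd=0.0, rt_jitter_sd=0.0, intensity_cv=0.0, ccs_noise_pct_sd=0.0
        )


@dataclass(frozen=True)
class GeneratedSample:
    sample_id: str
    source: str
    condition: str | None
    day: int
    replicate: int
    features: tuple[Feature4D, ...]
    spectra: tuple[MS2Spectrum, ...]
    truth: Mapping[str, Mapping[str, object]]  # feature_id -> truth record


@dataclass(frozen=True)
class StabilityStudy:
    source: str
    samples: tuple[GeneratedSample, ...]
    planted_kinetics_norm: Mapping[str, Mapping[str, float]]  # key -> condition -> slope (IS-normalised)


# --------------------------------------------------------------------------
# Internals
# --------------------------------------------------------------------------

_ROSTER_BY_ABBREV = {e.abbreviation: e for e in build_default_roster()}


def _peak_mz(spec: PeakSpec) -> float:
    return ion_mz(ElementalFormula.parse(spec.formula), PROTONATED)


def _peak_ccs(spec: PeakSpec) -> float:
    if spec.ccs_override is not None:
        return spec.ccs_override
    if spec.kind == "library" and spec.label in _ROSTER_BY_ABBREV:
        return _ROSTER_BY_ABBREV[spec.label].ccs
    return round(60.0 + 0.38 * _peak_mz(spec), 1)


def _peak_ms2_template(spec: PeakSpec) -> tuple[tuple[float, float], ...]:
    if spec.kind == "library" and spec.label in _ROSTER_BY_ABBREV:
        entry = _ROSTER_BY_ABBREV[spec.label]
        return entry.ms2.peaks if entry.ms2 else ()
    return _CLASS_MS2.get(spec.label, ())


def _m1_delta_and_ratio(formula: ElementalFormula) -> tuple[float, float]:
    pat = isotope_pattern(formula)
    base_idx = max(range(len(pat.peaks)), key=lambda i: pat.peaks[i][1])
    for mz, rel in pat.peaks[base_idx + 1 :]:
        return mz - pat.peaks[base_idx][0], rel
    return 1.0033548, 0.0  # mononuclidic edge case


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _expected_intensity(spec: PeakSpec, condition: str | None, day: int, cfg: GeneratorConfig) -> float:
    slope = 0.0
    if spec.kinetics_key is not None and condition is not None:
        slope = cfg.kinetics.get(spec.kinetics_key, {}).get(condition, 0.0)
    return max(0.0, spec.base_intensity + slope * (day - 1))


def _generate_sample(
    sample_id: str,
    source: str,
    condition: str | None,
    day: int,
    replicate: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    presence_field: str,
) -> GeneratedSample:
    src_idx = 0 if source == "synthetic" else 1
    features: list[Feature4D] = []
    spectra: list[MS2Spectrum] = []
    truth: dict[str, dict[str, object]] = {}

    for spec in PEAKS:
        present = getattr(spec, presence_field)[src_idx]
        if not present:
            continue
        expected = _expected_intensity(spec, condition, day, cfg)
        if expected <= 0.0:
            continue
        intensity = expected * _lognormal_factor(rng, cfg.intensity_cv)
        theo_mz = _peak_mz(spec)
        mz = theo_mz * (1.0 + rng.normal(0.0, cfg.mass_noise_ppm_sd) * 1e-6)
        rt = max(0.0, spec.rt + rng.normal(0.0, cfg.rt_jitter_sd))
        ccs = _peak_ccs(spec) * (1.0 + rng.normal(0.0, cfg.ccs_noise_pct_sd) / 100.0)
        fid = f"{sample_id}:{spec.key}"
        template = _peak_ms2_template(spec)
        ms2_ref = None
        if template:
            frag_peaks = tuple(
                sorted(
                    (
                        fm * (1.0 + rng.normal(0.0, cfg.mass_noise_ppm_sd) * 1e-6),
                        fi * _lognormal_factor(rng, cfg.intensity_cv),
                    )
                    for fm, fi in template
                )
            )
            ms2_ref = fid
            spectra.append(
                MS2Spectrum(spectrum_id=fid, precursor_mz=mz, peaks=frag_peaks)
            )
        feature = Feature4D(
            feature_id=fid,
            sample_id=sample_id,
            mz=mz,
            rt=rt,
            intensity=intensity,
            snr=intensity / cfg.noise_floor,
            ccs=ccs,
            ms2_ref=ms2_ref,
        )
        features.append(feature)
        truth[fid] = {
            "compound": spec.label,
            "peak_key": spec.key,
            "kind": spec.kind,
            "theoretical_mz": theo_mz,
            "rt": spec.rt,
        }

        # M+1 isotope companion
        formula = ElementalFormula.parse(spec.formula)
        if cfg.include_isotopes:
            delta, ratio = _m1_delta_and_ratio(formula)
            if ratio > 0:
                m1_id = f"{fid}::M1"
                features.append(
                    Feature4D(
                        feature_id=m1_id,
                        sample_id=sample_id,
                        mz=mz + delta,
                        rt=rt,
                        intensity=intensity * ratio,
                        snr=intensity * ratio / cfg.noise_floor,
                        ccs=ccs,
                    )
                )
                truth[m1_id] = {"compound": spec.label, "peak_key": spec.key, "kind": "isotope"}

        # in-source water-loss child (stability samples only)
        if condition is not None and spec.key in cfg.artifact_parents:
            child_int = intensity * ARTIFACT_FRACTION
            child_id = f"{fid}>H2O"
            features.append(
                Feature4D(
                    feature_id=child_id,
                    sample_id=sample_id,
                    mz=mz - WATER_MASS,
                    rt=rt,
                    intensity=child_int,
                    snr=child_int / cfg.noise_floor,
                    ccs=ccs,
                )
            )
            truth[child_id] = {
                "compound": spec.label,
                "peak_key": spec.key,
                "kind": "artifact",
                "parent_feature": fid,
            }

    return GeneratedSample(
        sample_id=sample_id,
        source=source,
        condition=condition,
        day=day,
        replicate=replicate,
        features=tuple(features),
        spectra=tuple(spectra),
        truth=truth,
    )


# --------------------------------------------------------------------------
# Public generators
# --------------------------------------------------------------------------


def generate_day1(source: str, cfg: GeneratorConfig) -> GeneratedSample:
    """Day-1 profiling fixture for one source (plant | synthetic):
    one feature per published day-1 peak present for that source, plus the
    CBD and internal-standard features, with configurable noise."""
    if source not in ("plant", "synthetic"):
        raise ValueError(f"source must be plant or synthetic, got {source!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0 if source == "plant" else 1]))
    return _generate_sample(
        sample_id=f"day1-{source}",
        source=source,
        condition=None,
        day=1,
        replicate=1,
        cfg=cfg,
        rng=rng,
        presence_field="day1",
    )


def generate_stability_study(source: str, cfg: GeneratorConfig) -> StabilityStudy:
    """Full stability design for one source: 4 conditions x 5 days x 5
    replicates = 100 samples with planted linear-with-floor kinetics."""
    if source not in ("plant", "synthetic"):
        raise ValueError(f"source must be plant or synthetic, got {source!r}")
    samples: list[GeneratedSample] = []
    seq = np.random.SeedSequence([cfg.seed, 100 if source == "plant" else 101])
    children = seq.spawn(len(CONDITIONS) * len(STUDY_DAYS) * N_REPLICATES)
    i = 0
    for condition in CONDITIONS:
        for day in STUDY_DAYS:
            for rep in range(1, N_REPLICATES + 1):
                sample_id = f"{source}-{condition}-d{day:02d}-r{rep}"
                rng = np.random.default_rng(children[i])
                i += 1
                samples.append(
                    _generate_sample(
                        sample_id, source, condition, day, rep, cfg, rng, "stability"
                    )
                )
    planted: dict[str, dict[str, float]] = {}
    src_idx = 0 if source == "synthetic" else 1
    for spec in PEAKS:
        if spec.kinetics_key is None or not spec.stability[src_idx]:
            continue
        planted[spec.key] = {
            cond: cfg.kinetics.get(spec.kinetics_key, {}).get(cond, 0.0) / IS_BASE_INTENSITY
            for cond in CONDITIONS
        }
    return StabilityStudy(source=source, samples=tuple(samples), planted_kinetics_norm=planted)


def generate_library_fixture(path: str | Path | None = None) -> list[LibraryEntry]:
    """The 39-entry reference library (theoretical m/z from the mass core,
    synthetic placeholder spectra flagged in provenance); optionally
    written to ``path`` in the MSP-like dialect."""
    entries = build_default_roster()
    if path is not None:
        write_library(entries, path)
    return entries


def generate_pseudo_ms3(
    ratio: float, cfg: GeneratorConfig, spectrum_id: str = "pseudo-ms3"
) -> MS2Spectrum:
    """Pseudo-MS3 spectrum of the CBE water-loss ion with a planted
    245.1540/231.1378 intensity ratio."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    base = 100.0
    peaks = [
        (231.1378, base * _lognormal_factor(rng, cfg.intensity_cv)),
        (245.1540, base * ratio * _lognormal_factor(rng, cfg.intensity_cv)),
        (175.1481, 20.0 * _lognormal_factor(rng, cfg.intensity_cv)),
    ]
    peaks = [(m, i) for m, i in peaks if i > 0]
    return MS2Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=313.2162,
        peaks=tuple(sorted(peaks)),
    )


# --------------------------------------------------------------------------
# File emission
# --------------------------------------------------------------------------


def write_sample(sample: GeneratedSample, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_feature_table(sample.features, outdir / f"{sample.sample_id}.features.csv")
    if sample.spectra:
        write_ms2_mgf(sample.spectra, outdir / f"{sample.sample_id}.ms2.mgf")
    meta = {
        "sample_id": sample.sample_id,
        "source": sample.source,
        "condition": sample.condition,
        "day": sample.day,
        "replicate": sample.replicate,
        "features": sample.truth,
    }
    (outdir / f"{sample.sample_id}.truth.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8"
    )


def write_study(study: StabilityStudy, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in study.samples:
        write_sample(sample, outdir)
    (outdir / f"{study.source}-planted-kinetics.json").write_text(
        json.dumps(
            {"source": study.source, "kinetics_norm": study.planted_kinetics_norm},
            indent=1,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
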