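"""Rule-based classification of unannotated degradation products.

Features that no library entry validates are classified into oxidative
degradation classes of the parent cannabinoids using, in fixed order:

1. in-source artifact links (an artifact-linked feature is never given a
   chemical class),
2. a *core* assignment from diagnostic MS2 fragments (the olivetol ion
   m/z 193.1228 marks a CBD-type core; the 205.12 / 135.04 pair marks a
   CBE-type core; the hexyl-resorcinol ion 207.1380 marks a CBDH-type
   core),
3. the oxidation level from the elemental-composition delta between the
   feature ion and the core parent (+O -> hydroxy, +2O -> dihydroxy,
   +O-2H -> quinone), and
4. a retention-time plausibility check: hydroxylation increases polarity,
   so a hydroxy label whose feature does not elute earlier than its
   parent is kept but demoted to low confidence.

A pseudo-MS3 spectrum of the water-loss ion separates the CBE
stereoisomers by the intensity ratio of the m/z 245.1540 and 231.1378
ions; which stereoisomer sits on the high-ratio side is configurable
metadata, not an assertion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .chem_core import (
    ElementalFormula,
    PROTONATED,
    enumerate_formulas,
    ion_mz,
    ppm_error,
)
from .feature_io import ArtifactLink, Feature4D, MS2Spectrum
from .spectral_library import LibraryEntry

__all__ = [
    "DiagnosticRule",
    "ClassifiedUnknown",
    "ClassifierConfig",
    "load_default_rules",
    "fragment_tolerance",
    "classify_unknown",
    "distinguish_cbe_stereoisomer",
    "StereoisomerCall",
    "oxidation_series",
    "SeriesReport",
    "LABELS",
]

LABELS = (
    "OH-CBD",
    "diOH-CBD",
    "OH-CBE",
    "CBE-isomer",
    "HU-331-like",
    "CBDH-isomer",
    "in-source-artifact",
    "unclassified",
)

#: Composition deltas relative to the core parent, in rule order.
_OXIDATION_DELTAS: tuple[tuple[str, Mapping[str, int]], ...] = (
    ("", {}),  # same composition: positional/stereo isomer of the parent
    ("OH-", {"O": 1}),
    ("diOH-", {"O": 2}),
    ("quinone", {"O": 1, "H": -2}),
)


@dataclass(frozen=True)
class DiagnosticRule:
    """Fragments whose joint presence assigns a core structure."""

    core_name: str
    required_fragments: tuple[tuple[float, float], ...]  # (mz, tol Da)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.required_fragments:
            raise ValueError("rule needs at least one required fragment")
        if any(tol <= 0 for _, tol in self.required_fragments):
            raise ValueError("fragment tolerances must be positive")

    def matches(self, ms2: MS2Spectrum) -> bool:
        return all(ms2.intensity_at(mz, tol) > 0 for mz, tol in self.required_fragments)


@dataclass(frozen=True)
class ClassifiedUnknown:
    feature_id: str
    label: str
    parent_compound: str = ""
    evidence: tuple[str, ...] = ()
    confidence: str = "high"  # high | low
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "unclassified" and not self.evidence:
            raise ValueError("a classified feature must carry evidence")


@dataclass(frozen=True)
class ClassifierConfig:
    rules: tuple[DiagnosticRule, ...]
    mass_tol_ppm: float = 5.0
    rt_margin: float = 0.3  # minutes; hydroxy product must elute this much earlier
    stereo_threshold: float = 2.0
    stereo_high_ratio_class: str = "CBE"  # orientation of the 245/231 ratio; metadata
    stereo_fragment_tol: float = 0.005


def fragment_tolerance(mz: float, da: float = 0.005, ppm: float = 10.0) -> float:
    """max(0.005 Da, 10 ppm): wide enough to absorb the spread between
    independently quoted diagnostic masses (e.g. 135.0442 vs 135.0448)."""
    return max(da, mz * ppm * 1e-6)


def load_default_rules(path: str | Path | None = None) -> ClassifierConfig:
    """Load the diagnostic-fragment rules (packaged JSON unless ``path`` given)."""
    if path is None:
        text = resources.files("cannatrace.data").joinpath("diagnostic_rules.json").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = json.loads(text)
    rules = tuple(
        DiagnosticRule(
            core_name=r["core_name"],
            required_fragments=tuple(
                (float(mz), fragment_tolerance(float(mz), doc.get("tol_da", 0.005), doc.get("tol_ppm", 10.0)))
                for mz in r["required_fragments"]
            ),
            description=r.get("description", ""),
        )
        for r in doc["rules"]
    )
    return ClassifierConfig(
        rules=rules,
        mass_tol_ppm=float(doc.get("mass_tol_ppm", 5.0)),
        rt_margin=float(doc.get("rt_margin_min", 0.3)),
        stereo_threshold=float(doc.get("stereo_threshold", 2.0)),
        stereo_high_ratio_class=doc.get("stereo_high_ratio_class", "CBE"),
    )


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------


def _composition_consistent(
    feature_mz: float, candidate: ElementalFormula, tol_ppm: float
) -> bool:
    """The implied ion composition must survive independent formula
    enumeration at the same tolerance (guards against rule-order luck)."""
    hits = enumerate_formulas(feature_mz, tol_ppm, PROTONATED)
    return candidate in {f for f, _ in hits}


def classify_unknown(
    feature: Feature4D,
    ms2: MS2Spectrum | None,
    artifacts: Sequence[ArtifactLink],
    parents: Mapping[str, LibraryEntry],
    config: ClassifierConfig | None = None,
) -> ClassifiedUnknown:
    """Assign a degradation-product class to one unannotated feature.

    ``parents`` maps core names (and auxiliary references such as HU-331,
    CBDH, CBDM) to library entries supplying formulas and retention
    times; a rule that needs an absent parent raises ``KeyError`` naming it.
    Features with neither an MS2 spectrum nor an artifact link return
    ``unclassified``.
    """
    config = config or load_default_rules()

    # (1) in-source artifacts take absolute precedence
    my_links = [l for l in artifacts if l.child_id == feature.feature_id]
    if my_links:
        parent_ids = sorted({l.parent_id for l in my_links})
        evidence = [
            f"neutral loss {l.loss_name} ({l.neutral_loss:.4f} Da) from {l.parent_id}"
            for l in my_links
        ]
        confidence = "high" if len(parent_ids) == 1 else "low"
        if len(parent_ids) > 1:
            evidence.append("ambiguous artifact: multiple co-eluting parents")
        return ClassifiedUnknown(
            feature_id=feature.feature_id,
            label="in-source-artifact",
            parent_compound=parent_ids[0],
            evidence=tuple(evidence),
            confidence=confidence,
            rt=feature.rt,
        )

    if ms2 is None:
        return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)

    # (2) core assignment from diagnostic fragments, first matching rule wins
    core_rule = next((r for r in config.rules if r.matches(ms2)), None)
    if core_rule is None:
        # Composition-only fallback: the CBD quinone (HU-331-like) has no
        # diagnostic-fragment rule — its fragmentation is not established —
        # so it is called on ion composition and retention time alone.
        return _quinone_fallback(feature, parents, config)
    core = core_rule.core_name
    if core not in parents:
        raise KeyError(f"parent compound {core!r} absent from reference set")
    parent = parents[core]
    evidence = [
        f"diagnostic fragments for {core} core: "
        + ", ".join(f"{mz:.4f}" for mz, _ in core_rule.required_fragments)
    ]

    # (3) oxidation level from the composition delta vs the core parent
    for prefix, delta in _OXIDATION_DELTAS:
        try:
            candidate = parent.neutral_formula.add(delta)
        except ValueError:
            continue
        theo = ion_mz(candidate, PROTONATED)
        dppm = ppm_error(feature.mz, theo)
        if abs(dppm) > config.mass_tol_ppm:
            continue
        if not _composition_consistent(feature.mz, candidate, config.mass_tol_ppm):
            continue
        evidence.append(
            f"ion composition {candidate.add({'H': 1}).hill()} "
            f"({'+'.join(f'{v:+d}{k}' for k, v in delta.items()) or 'parent composition'}, "
            f"{dppm:+.2f} ppm)"
        )
        return _finish_label(feature, prefix, core, parent, parents, evidence, config)

    return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)


def _quinone_fallback(
    feature: Feature4D,
    parents: Mapping[str, LibraryEntry],
    config: ClassifierConfig,
) -> ClassifiedUnknown:
    """HU-331-like: CBD + O - 2H ion composition at a retention time far
    from the HU-331 reference entry."""
    cbd = parents.get("CBD")
    hu331 = parents.get("HU-331")
    if cbd is None or hu331 is None:
        return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)
    try:
        quinone = cbd.neutral_formula.add({"O": 1, "H": -2})
    except ValueError:
        return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)
    dppm = ppm_error(feature.mz, ion_mz(quinone, PROTONATED))
    if (
        abs(dppm) <= config.mass_tol_ppm
        and abs(feature.rt - hu331.rt) > config.rt_margin
        and _composition_consistent(feature.mz, quinone, config.mass_tol_ppm)
    ):
        evidence = (
            f"ion composition {quinone.add({'H': 1}).hill()} = CBD +O -2H ({dppm:+.2f} ppm)",
            f"rt {feature.rt:.2f} min far from HU-331 reference ({hu331.rt:.2f} min)",
        )
        return ClassifiedUnknown(
            feature.feature_id, "HU-331-like", "CBD", evidence, "high", rt=feature.rt
        )
    return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)


def _finish_label(
    feature: Feature4D,
    prefix: str,
    core: str,
    parent: LibraryEntry,
    parents: Mapping[str, LibraryEntry],
    evidence: list[str],
    config: ClassifierConfig,
) -> ClassifiedUnknown:
    confidence = "high"

    if prefix == "":  # same composition as the parent: an isomer
        label = f"{core}-isomer"
        if label not in LABELS:
            return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)
        others = [parents[a] for a in parents if parents[a].neutral_formula == parent.neutral_formula]
        near = [e.abbreviation for e in others if abs(feature.rt - e.rt) <= config.rt_margin]
        if near:
            # co-elutes with a known reference: not an unknown isomer
            return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)
        evidence.append(
            f"rt {feature.rt:.2f} min differs from all same-composition references"
        )
        return ClassifiedUnknown(
            feature.feature_id, label, core, tuple(evidence), confidence, rt=feature.rt
        )

    if prefix == "quinone":
        if core != "CBD":
            return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)
        hu331 = parents.get("HU-331")
        if hu331 is None:
            raise KeyError("parent compound 'HU-331' absent from reference set")
        if abs(feature.rt - hu331.rt) <= config.rt_margin:
            # this is HU-331 itself; the library matcher owns it
            return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)
        evidence.append(
            f"quinone composition at rt {feature.rt:.2f} min, far from HU-331 ({hu331.rt:.2f} min)"
        )
        return ClassifiedUnknown(
            feature.feature_id, "HU-331-like", core, tuple(evidence), confidence, rt=feature.rt
        )

    label = f"{prefix}{core}"
    if label not in LABELS:
        return ClassifiedUnknown(feature.feature_id, "unclassified", rt=feature.rt)
    # (4) hydroxylation increases polarity -> earlier elution than the parent
    if feature.rt < parent.rt - config.rt_margin:
        evidence.append(
            f"rt {feature.rt:.2f} min elutes earlier than {core} ({parent.rt:.2f} min)"
        )
    else:
        confidence = "low"
        evidence.append(
            f"rt {feature.rt:.2f} min not earlier than {core} ({parent.rt:.2f} min): "
            "inconsistent with added polarity"
        )
    return ClassifiedUnknown(
        feature.feature_id, label, core, tuple(evidence), confidence, rt=feature.rt
    )


# --------------------------------------------------------------------------
# CBE stereoisomer differentiation (pseudo-MS3 of the water-loss ion)
# --------------------------------------------------------------------------

_STEREO_NUMERATOR = 245.1540
_STEREO_DENOMINATOR = 231.1378


@dataclass(frozen=True)
class StereoisomerCall:
    call: str  # CBE | CBE-isomer | indeterminate
    ratio: float | None  # I(245.1540) / I(231.1378); None when neither ion present


def distinguish_cbe_stereoisomer(
    pseudo_ms3: MS2Spectrum, config: ClassifierConfig | None = None
) -> StereoisomerCall:
    """Separate CBE from its stereoisomer by the 245.1540/231.1378 ratio.

    The spectrum should be the fragmentation of the in-source
    ``[M-H2O+H]+`` ion near m/z 313.216.  ``ratio > threshold`` calls the
    configured high-ratio class, ``ratio < 1/threshold`` the other;
    anything between — or a tie — is indeterminate.
    """
    config = config or load_default_rules()
    tol = config.stereo_fragment_tol
    num = pseudo_ms3.intensity_at(_STEREO_NUMERATOR, tol)
    den = pseudo_ms3.intensity_at(_STEREO_DENOMINATOR, tol)
    if num == 0 and den == 0:
        return StereoisomerCall("indeterminate", None)
    high = config.stereo_high_ratio_class
    low = "CBE-isomer" if high == "CBE" else "CBE"
    if den == 0:
        return StereoisomerCall(high, float("inf"))
    ratio = num / den
    if ratio > config.stereo_threshold:
        return StereoisomerCall(high, ratio)
    if ratio < 1.0 / config.stereo_threshold:
        return StereoisomerCall(low, ratio)
    return StereoisomerCall("indeterminate", ratio)


# --------------------------------------------------------------------------
# Oxidation series report
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SeriesReport:
    parent: str
    members: Mapping[str, tuple[str, ...]]  # label -> feature ids
    counts: Mapping[str, int]
    rt_ordering_ok: bool  # diOH < OH < parent retention times


def oxidation_series(
    classified: Sequence[ClassifiedUnknown], parent: LibraryEntry
) -> SeriesReport:
    """Group classified unknowns of one parent by oxidation level and check
    that retention times follow polarity (diOH < OH < parent)."""
    core = parent.abbreviation
    members: dict[str, list[str]] = {}
    rts: dict[str, list[float]] = {}
    for c in classified:
        if c.parent_compound != core or c.label == "in-source-artifact":
            continue
        members.setdefault(c.label, []).append(c.feature_id)
        if c.rt is not None:
            rts.setdefault(c.label, []).append(c.rt)

    oh, dioh = f"OH-{core}", f"diOH-{core}"
    ordering_ok = True
    if dioh in rts and oh in rts:
        ordering_ok &= max(rts[dioh]) < min(rts[oh])
    if oh in rts:
        ordering_ok &= max(rts[oh]) < parent.rt
    if dioh in rts:
        ordering_ok &= max(rts[dioh]) < parent.rt
    return SeriesReport(
        parent=core,
        members={k: tuple(v) for k, v in sorted(members.items())},
        counts={k: len(v) for k, v in sorted(members.items())},
        rt_ordering_ok=bool(ordering_ok),
    )
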