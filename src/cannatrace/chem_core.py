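"""Exact-mass arithmetic for small-molecule (cannabinoid) annotation.

Everything downstream of feature detection — adduct m/z computation, ppm
scoring, CHO formula enumeration and isotope-envelope simulation — lives
here as pure functions on :class:`ElementalFormula`.

Atomic masses and isotope abundances are pinned in-source (CODATA/NIST
monoisotopic values, >= 7 decimal places) so results are reproducible
without any external lookup.  Supported elements: C, H, O, N, S and D
(deuterium, treated as its own symbol so labelled internal standards can
be expressed exactly).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ElementalFormula",
    "AdductSpec",
    "IsotopePattern",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "rdbe",
    "ElementBounds",
    "enumerate_formulas",
    "isotope_pattern",
    "isotope_similarity",
]

# --------------------------------------------------------------------------
# Pinned physical constants
# --------------------------------------------------------------------------

#: Monoisotopic (most abundant isotope) atomic masses, Da.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "S": 31.97207100,
    "D": 2.0141017778,  # deuterium as an explicit symbol
}

ELECTRON_MASS: float = 0.00054858
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

#: Per-element isotope distributions as (mass, abundance) tuples,
#: abundance-normalised.  D is mononuclidic by construction (a labelled
#: position stays labelled).
ISOTOPES: Mapping[str, Sequence[tuple[float, float]]] = {
    "C": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "H": ((1.00782503207, 0.999885), (2.0141017778, 0.000115)),
    "O": ((15.9949146196, 0.99757), (16.9991317, 0.00038), (17.9991610, 0.00205)),
    "N": ((14.0030740048, 0.99636), (15.0001088982, 0.00364)),
    "S": (
        (31.97207100, 0.9499),
        (32.97145876, 0.0075),
        (33.96786690, 0.0425),
        (35.96708076, 0.0001),
    ),
    "D": ((2.0141017778, 1.0),),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


# --------------------------------------------------------------------------
# Elemental formulas
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, e.g. ``ElementalFormula({"C": 21, "H": 30, "O": 2})``.

    Only the whitelisted elements (C, H, O, N, S, D) are accepted; counts
    must be non-negative integers and at least one atom must be present.
    Instances are immutable and hashable.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for elem, n in self.counts.items():
            if elem not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {elem!r}")
            if not isinstance(n, int) or isinstance(n, bool) or n < 0:
                raise ValueError(f"count for {elem} must be a non-negative integer, got {n!r}")
            if n:
                clean[elem] = n
        if not clean:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    # -- constructors ------------------------------------------------------

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-notation text such as ``"C21H30O2"`` or ``"C21H27D3O2"``."""
        if not text or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
            raise ValueError(f"cannot parse formula {text!r}")
        counts: dict[str, int] = {}
        for elem, digits in _FORMULA_TOKEN.findall(text):
            if not elem:
                continue
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        return cls(counts)

    # -- protocol ----------------------------------------------------------

    def __getitem__(self, elem: str) -> int:
        return self.counts.get(elem, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __str__(self) -> str:
        return self.hill()

    def hill(self) -> str:
        """Hill notation: C first, H second, remaining elements alphabetical."""
        order = [e for e in ("C", "H") if e in self.counts]
        order += sorted(e for e in self.counts if e not in ("C", "H"))
        return "".join(f"{e}{self.counts[e] if self.counts[e] != 1 else ''}" for e in order)

    def add(self, other: "ElementalFormula | Mapping[str, int]", scale: int = 1) -> "ElementalFormula":
        """Return self + scale * other; negative results raise ``ValueError``."""
        other_counts = other.counts if isinstance(other, ElementalFormula) else other
        merged = dict(self.counts)
        for elem, n in other_counts.items():
            merged[elem] = merged.get(elem, 0) + scale * n
            if merged[elem] < 0:
                raise ValueError(
                    f"composition would need {merged[elem]} atoms of {elem}"
                )
        return ElementalFormula(merged)

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())


WATER = ElementalFormula({"H": 2, "O": 1})
WATER_MASS = 2 * MONOISOTOPIC_MASS["H"] + MONOISOTOPIC_MASS["O"]


# --------------------------------------------------------------------------
# Adducts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AdductSpec:
    """An ionisation adduct: label, signed mass delta (Da, relative to the
    neutral monoisotopic mass, electron not included) and integer charge.

    ``composition_delta`` records the atoms gained/lost so chemical
    feasibility of losses (e.g. water loss from an oxygen-free formula)
    can be checked.
    """

    label: str
    mass_delta: float
    charge: int
    composition_delta: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")

    @classmethod
    def from_label(cls, label: str) -> "AdductSpec":
        try:
            return cls(**_KNOWN_ADDUCTS[_normalise_adduct_label(label)])
        except KeyError:
            raise ValueError(f"unknown adduct label {label!r}") from None


def _normalise_adduct_label(label: str) -> str:
    return label.replace(" ", "")


_KNOWN_ADDUCTS: dict[str, dict] = {
    "[M+H]+": dict(
        label="[M+H]+",
        mass_delta=MONOISOTOPIC_MASS["H"],
        charge=1,
        composition_delta={"H": 1},
    ),
    "[M-H2O+H]+": dict(
        label="[M-H2O+H]+",
        mass_delta=MONOISOTOPIC_MASS["H"] - WATER_MASS,
        charge=1,
        composition_delta={"H": -1, "O": -1},
    ),
    "[M+Na]+": dict(
        label="[M+Na]+",
        mass_delta=22.9897692809,
        charge=1,
        composition_delta={},
    ),
    "[M-H]-": dict(
        label="[M-H]-",
        mass_delta=-MONOISOTOPIC_MASS["H"],
        charge=-1,
        composition_delta={"H": -1},
    ),
}

PROTONATED = AdductSpec.from_label("[M+H]+")
WATER_LOSS_PROTONATED = AdductSpec.from_label("[M-H2O+H]+")


# --------------------------------------------------------------------------
# Scalar operations
# --------------------------------------------------------------------------


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Sum of most-abundant-isotope masses, Da."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula)


def ion_mz(neutral: ElementalFormula, adduct: AdductSpec) -> float:
    """m/z of ``neutral`` ionised as ``adduct``, electron-mass corrected.

    ``(M + delta - z * m_e) / |z|`` — for a singly protonated ion this is
    the neutral mass plus the proton mass.  Raises ``ValueError`` when the
    adduct's losses exceed the atoms available (e.g. ``[M-H2O+H]+`` of an
    oxygen-free formula).
    """
    if adduct.composition_delta:
        neutral.add(adduct.composition_delta)  # feasibility check only
    m = monoisotopic_mass(neutral) + adduct.mass_delta - adduct.charge * ELECTRON_MASS
    return m / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million: (obs - theo)/theo * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def rdbe(formula: ElementalFormula) -> float:
    """Rings-plus-double-bond equivalents: C - H/2 + N/2 + 1 (D counts as H).

    Half-integer values flag even-electron ion compositions rather than
    neutral molecules.
    """
    h_like = formula["H"] + formula["D"]
    return formula["C"] - h_like / 2.0 + formula["N"] / 2.0 + 1.0


# --------------------------------------------------------------------------
# Formula enumeration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementBounds:
    """Per-element (min, max) count ranges for formula enumeration.

    Defaults cover the phytocannabinoid space: C 0-40, H 0-80, O 0-10,
    N and S disabled.
    """

    ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"C": (0, 40), "H": (0, 80), "O": (0, 10)}
    )

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("bounds must name at least one element")
        for elem, (lo, hi) in self.ranges.items():
            if elem not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element {elem!r} in bounds")
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range {lo}..{hi} for {elem}")


DEFAULT_BOUNDS = ElementBounds()
DEFAULT_RDBE_RANGE = (0.0, 25.0)


def enumerate_formulas(
    mz: float,
    tol_ppm: float,
    adduct: AdductSpec = PROTONATED,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    rdbe_range: tuple[float, float] = DEFAULT_RDBE_RANGE,
) -> list[tuple[ElementalFormula, float]]:
    """All neutral formulas within ``bounds`` whose ``ion_mz`` lies within
    ``tol_ppm`` of ``mz`` and whose RDBE lies in ``rdbe_range``.

    Exhaustive within the bounds; returned sorted by \\|ppm error\\|
    ascending (ties by Hill string for determinism).  An empty list is a
    valid result.
    """
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    lo_mz = mz * (1 - tol_ppm * 1e-6)
    hi_mz = mz * (1 + tol_ppm * 1e-6)
    # Neutral-mass window implied by the ion-mass window.
    z = abs(adduct.charge)
    lo_m = lo_mz * z - adduct.mass_delta + adduct.charge * ELECTRON_MASS
    hi_m = hi_mz * z - adduct.mass_delta + adduct.charge * ELECTRON_MASS

    elems = list(bounds.ranges)
    heavy = [e for e in elems if e != "H"]
    h_range = bounds.ranges.get("H", (0, 0))
    m_h = MONOISOTOPIC_MASS["H"]

    out: list[tuple[ElementalFormula, float]] = []

    def recurse(idx: int, counts: dict[str, int], mass: float) -> None:
        if mass > hi_m + 1e-9:
            return
        if idx == len(heavy):
            # Solve the hydrogen count range directly from the mass window.
            h_lo = max(h_range[0], int(-(-(lo_m - mass) // m_h) - 2))
            h_hi = min(h_range[1], int((hi_m - mass) / m_h) + 2)
            for h in range(max(h_lo, 0), h_hi + 1):
                total = mass + h * m_h
                if not (lo_m - 1e-9 <= total <= hi_m + 1e-9):
                    continue
                cand = dict(counts)
                if h:
                    cand["H"] = h
                if not cand:
                    continue
                formula = ElementalFormula(cand)
                if not (rdbe_range[0] <= rdbe(formula) <= rdbe_range[1]):
                    continue
                try:
                    err = ppm_error(mz, ion_mz(formula, adduct))
                except ValueError:
                    continue  # adduct loss infeasible for this composition
                if abs(err) <= tol_ppm + 1e-12:
                    out.append((formula, err))
            return
        elem = heavy[idx]
        lo, hi = bounds.ranges[elem]
        m_e = MONOISOTOPIC_MASS[elem]
        for n in range(lo, hi + 1):
            new_mass = mass + n * m_e
            if new_mass > hi_m + 1e-9:
                break
            nxt = dict(counts)
            if n:
                nxt[elem] = n
            recurse(idx + 1, nxt, new_mass)

    recurse(0, {}, 0.0)
    out.sort(key=lambda pair: (abs(pair[1]), pair[0].hill()))
    return out


# --------------------------------------------------------------------------
# Isotope patterns
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopePattern:
    """Ordered (m/z, relative abundance) peaks, base peak normalised to 1."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("isotope pattern must contain at least one peak")
        mzs = [p[0] for p in self.peaks]
        if mzs != sorted(mzs):
            raise ValueError("peaks must be sorted ascending by m/z")
        abundances = [p[1] for p in self.peaks]
        if max(abundances) != 1.0:
            raise ValueError("base peak abundance must be exactly 1")
        if any(a <= 0 or a > 1 for a in abundances):
            raise ValueError("abundances must lie in (0, 1]")

    def base_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]


def _merge_bins(peaks: list[tuple[float, float]], bin_width: float) -> list[tuple[float, float]]:
    """Greedy left-to-right merge of peaks closer than ``bin_width``;
    merged m/z is the abundance-weighted centroid."""
    peaks = sorted(peaks)
    merged: list[tuple[float, float]] = []
    for m, a in peaks:
        if merged and m - merged[-1][0] < bin_width:
            pm, pa = merged[-1]
            tot = pa + a
            merged[-1] = ((pm * pa + m * a) / tot, tot)
        else:
            merged.append((m, a))
    return merged


def _raw_isotope_distribution(
    formula: ElementalFormula, bin_width: float, floor: float = 1e-12
) -> list[tuple[float, float]]:
    """Un-normalised isotopologue distribution (sums to 1 up to the tiny
    ``floor`` used to bound intermediate list sizes)."""
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    for elem, n in formula:
        atom = list(ISOTOPES[elem])
        # exponentiation by squaring on distributions
        power = atom
        remaining = n
        acc: list[tuple[float, float]] | None = None
        while remaining:
            if remaining & 1:
                acc = _convolve(acc, power, bin_width, floor) if acc else power
            remaining >>= 1
            if remaining:
                power = _convolve(power, power, bin_width, floor)
        if acc:
            dist = _convolve(dist, acc, bin_width, floor)
    return sorted(dist)


def _convolve(
    d1: Sequence[tuple[float, float]],
    d2: Sequence[tuple[float, float]],
    bin_width: float,
    floor: float,
) -> list[tuple[float, float]]:
    out: dict[float, float] = {}
    for m1, a1 in d1:
        for m2, a2 in d2:
            a = a1 * a2
            if a < floor:
                continue
            key = m1 + m2
            out[key] = out.get(key, 0.0) + a
    return _merge_bins(list(out.items()), bin_width)


def isotope_pattern(
    formula: ElementalFormula, bin_width: float = 0.01, prune: float = 1e-4
) -> IsotopePattern:
    """Theoretical isotope envelope of ``formula`` (neutral masses).

    Per-element isotope distributions are convolved exactly, peaks closer
    than ``bin_width`` merged into abundance-weighted centroids, peaks
    below ``prune`` x base removed and the base peak normalised to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dist = _raw_isotope_distribution(formula, bin_width)
    base = max(a for _, a in dist)
    kept = [(m, a / base) for m, a in dist if a / base >= prune]
    # renormalise in case pruning removed the old base's siblings
    top = max(a for _, a in kept)
    kept = [(m, min(a / top, 1.0)) for m, a in kept]
    return IsotopePattern(tuple(sorted(kept)))


def isotope_similarity(
    observed: IsotopePattern, theoretical: IsotopePattern, tol: float = 0.01
) -> float:
    """Symmetric envelope-agreement score in [0, 1].

    Both patterns are first re-expressed relative to their base peak
    (mass offsets from the most abundant peak), so an observed *ion*
    envelope can be scored against a theoretical *neutral* envelope — the
    criterion tests the shape of the isotope distribution, not absolute
    mass.  Offset peaks are then greedily matched within ``tol`` Da; the
    score is ``1 - D / A`` where ``D`` sums \\|abundance differences\\|
    over matched pairs plus the full abundance of every unmatched peak on
    either side, and ``A`` is the total abundance of both patterns.
    Identical patterns score exactly 1; every unmatched or deviating peak
    lowers the score; the result is clamped at 0.
    """
    obs_base = observed.base_mz()
    theo_base = theoretical.base_mz()
    obs = [(m - obs_base, a) for m, a in observed.peaks]
    theo = [(m - theo_base, a) for m, a in theoretical.peaks]
    used: set[int] = set()
    deviation = 0.0
    for mo, ao in obs:
        best_j, best_d = -1, tol
        for j, (mt, _at) in enumerate(theo):
            if j in used:
                continue
            d = abs(mo - mt)
            if d <= best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            used.add(best_j)
            deviation += abs(ao - theo[best_j][1])
        else:
            deviation += ao
    for j, (_mt, at) in enumerate(theo):
        if j not in used:
            deviation += at
    total = sum(a for _, a in obs) + sum(a for _, a in theo)
    return max(0.0, 1.0 - deviation / total)
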