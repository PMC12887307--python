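"""Molecular characterization of dissolved organic matter (DOM) from
ultrahigh-resolution mass spectra.

Peak lists (m/z, intensity) from negative-mode ESI FT-ICR-MS are assigned
CHNOS molecular formulas by exact-mass matching of the deprotonated ion
[M-H]-, constrained by standard DOM plausibility rules (element ranges,
H/C and O/C windows, integer double-bond equivalents, bounded carbon
oxidation state). Assigned formulas are characterized by van Krevelen
position (H/C vs O/C), classified into seven biochemical compound classes,
and summarized as class abundances, heteroatom series (CHO/CHNO/CHOS/CHNOS)
and a Shannon chemodiversity index over peak intensities.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import MASS_C, MASS_H, MASS_N, MASS_O, MASS_S, PROTON_MASS
from .errors import AnalysisError
from ._util import shannon_nats

__all__ = [
    "Peak",
    "MolecularFormula",
    "FormulaDescriptors",
    "AssignmentConfig",
    "AssignedPeak",
    "AssignmentResult",
    "ClassBox",
    "ClassScheme",
    "default_class_scheme",
    "CLASS_LABELS",
    "descriptors",
    "classify",
    "candidate_formulas",
    "assign_peaklist",
    "class_abundance",
    "chemodiversity",
    "compare_formula_sets",
    "FormulaSetComparison",
    "formula_to_string",
    "parse_formula",
]


class Peak(NamedTuple):
    """One singly charged, negative-mode mass spectral peak."""

    mz: float
    intensity: float


class MolecularFormula(NamedTuple):
    """Element counts of a neutral CHNOS formula."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0


def formula_to_string(f: MolecularFormula) -> str:
    """Hill-ish compact notation, zero counts omitted: C6H12O6, C10H15NO4S."""
    parts = []
    for sym, cnt in zip("CHNOS", f):
        if cnt == 0:
            continue
        parts.append(sym if cnt == 1 else f"{sym}{cnt}")
    return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Inverse of :func:`formula_to_string` (CHNOS elements only)."""
    counts = dict.fromkeys("CHNOS", 0)
    i = 0
    while i < len(text):
        sym = text[i]
        if sym not in counts:
            raise ValueError(f"unsupported element {sym!r} in formula {text!r}")
        i += 1
        j = i
        while j < len(text) and text[j].isdigit():
            j += 1
        counts[sym] = int(text[i:j]) if j > i else 1
        i = j
    return MolecularFormula(counts["C"], counts["H"], counts["N"], counts["O"], counts["S"])


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormulaDescriptors:
    """Derived molecular descriptors of a neutral formula.

    nosc is the nominal oxidation state of carbon,
    4 - (4c + h - 3n - 2o - 2s)/c; dbe the double-bond equivalents,
    c - h/2 + n/2 + 1 (integer for valid even-electron neutrals).
    """

    neutral_monoisotopic_mass: float
    theoretical_mz: float
    hc_ratio: float
    oc_ratio: float
    dbe: float
    nosc: float
    series: str


def _series(n: int, s: int) -> str:
    if n > 0 and s > 0:
        return "CHNOS"
    if n > 0:
        return "CHNO"
    if s > 0:
        return "CHOS"
    return "CHO"


def descriptors(f: MolecularFormula) -> FormulaDescriptors:
    """Compute all descriptors; requires c >= 1 (h = 0 is permitted here even
    though assignment itself demands h >= 4, so limiting cases like CO2 work)."""
    c, h, n, o, s = f
    if c < 1:
        raise ValueError("descriptors require at least one carbon")
    mass = c * MASS_C + h * MASS_H + n * MASS_N + o * MASS_O + s * MASS_S
    return FormulaDescriptors(
        neutral_monoisotopic_mass=mass,
        theoretical_mz=mass - PROTON_MASS,
        hc_ratio=h / c,
        oc_ratio=o / c,
        dbe=c - h / 2 + n / 2 + 1,
        nosc=4 - (4 * c + h - 3 * n - 2 * o - 2 * s) / c,
        series=_series(n, s),
    )


# ---------------------------------------------------------------------------
# van Krevelen compound classes
# ---------------------------------------------------------------------------

CLASS_LABELS = (
    "lipids",
    "aliphatic/peptides",
    "carbohydrates",
    "unsaturated hydrocarbons",
    "lignin/CRAM-like",
    "tannins",
    "aromatic structures",
)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassBox:
    """One H/C x O/C rectangle; half-open edges flagged per side."""

    label: str
    hc: tuple[float, float]
    oc: tuple[float, float]
    hc_closed_hi: bool = True
    oc_closed_hi: bool = True

    def contains(self, hc: float, oc: float) -> bool:
        lo, hi = self.hc
        if not (lo <= hc and (hc <= hi if self.hc_closed_hi else hc < hi)):
            return False
        lo, hi = self.oc
        return lo <= oc and (oc <= hi if self.oc_closed_hi else oc < hi)


@dataclass(frozen=True)
class ClassScheme:
    """Ordered list of class boxes; first match wins."""

    boxes: tuple[ClassBox, ...]

    def __post_init__(self):
        for box in self.boxes:
            if box.label not in CLASS_LABELS:
                raise ValueError(f"unknown compound class label {box.label!r}")
            if box.hc[0] > box.hc[1] or box.oc[0] > box.oc[1]:
                raise ValueError(f"malformed interval in class box {box.label!r}")

    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.boxes)


def default_class_scheme() -> ClassScheme:
    """Conventional seven-class van Krevelen partition for DOM.

    The exact boundaries vary between laboratories; these follow the common
    convention and every edge is configurable by supplying another scheme.
    """
    return ClassScheme(boxes=(
        ClassBox("lipids", (1.5, 2.0), (0.0, 0.3), oc_closed_hi=False),
        ClassBox("aliphatic/peptides", (1.5, 2.2), (0.3, 0.67), oc_closed_hi=False),
        ClassBox("carbohydrates", (1.5, 2.4), (0.67, 1.2)),
        ClassBox("unsaturated hydrocarbons", (0.7, 1.5), (0.0, 0.1),
                 hc_closed_hi=False, oc_closed_hi=False),
        ClassBox("lignin/CRAM-like", (0.7, 1.5), (0.1, 0.67),
                 hc_closed_hi=False, oc_closed_hi=False),
        ClassBox("tannins", (0.5, 1.5), (0.67, 1.2), hc_closed_hi=False),
        ClassBox("aromatic structures", (0.2, 0.7), (0.0, 0.67),
                 hc_closed_hi=False, oc_closed_hi=False),
    ))


def classify(desc: FormulaDescriptors, scheme: ClassScheme | None = None) -> str:
    """Label a formula by its H/C-O/C position; no match -> "unclassified"."""
    if scheme is None:
        scheme = default_class_scheme()
    for box in scheme.boxes:
        if box.contains(desc.hc_ratio, desc.oc_ratio):
            return box.label
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# Assignment configuration and formula catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssignmentConfig:
    """Validity rules and matching tolerance for formula assignment.

    Element ranges are inclusive. The NOSC window enforces chemically
    plausible carbon oxidation states (the other rules alone do not bound
    NOSC above +4 for small, heteroatom-rich formulas).
    """

    tolerance_ppm: float = 1.0
    c_range: tuple[int, int] = (4, 50)
    h_range: tuple[int, int] = (4, 100)
    n_range: tuple[int, int] = (0, 4)
    o_range: tuple[int, int] = (1, 40)
    s_range: tuple[int, int] = (0, 2)
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_range: tuple[float, float] = (0.0, 1.2)  # lower edge open; o >= 1 enforces > 0
    dbe_range: tuple[float, float] = (0.0, 25.0)
    nosc_range: tuple[float, float] = (-4.0, 4.0)
    mz_window: tuple[float, float] = (100.0, 800.0)

    def __post_init__(self):
        for name in ("c_range", "h_range", "n_range", "o_range", "s_range",
                     "hc_range", "oc_range", "dbe_range", "nosc_range", "mz_window"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if self.tolerance_ppm < 0:
            raise ValueError("tolerance_ppm must be >= 0")


def valid_formula_mask(c, h, n, o, s, config: AssignmentConfig) -> np.ndarray:
    """Vectorized validity test used by both assignment and the generators."""
    c = np.asarray(c, dtype=np.int64)
    h = np.asarray(h, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    o = np.asarray(o, dtype=np.int64)
    s = np.asarray(s, dtype=np.int64)
    ok = (
        (c >= config.c_range[0]) & (c <= config.c_range[1])
        & (h >= config.h_range[0]) & (h <= config.h_range[1])
        & (n >= config.n_range[0]) & (n <= config.n_range[1])
        & (o >= config.o_range[0]) & (o <= config.o_range[1])
        & (s >= config.s_range[0]) & (s <= config.s_range[1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(c > 0, c, 1).astype(float)
        hc = h / cc
        oc = o / cc
        nosc = 4.0 - (4 * c + h - 3 * n - 2 * o - 2 * s) / cc
    dbe2 = 2 * c - h + n + 2  # twice the DBE; must be even and in range
    ok &= (hc >= config.hc_range[0]) & (hc <= config.hc_range[1])
    ok &= (oc <= config.oc_range[1]) & (o >= 1)
    ok &= (dbe2 % 2 == 0) & (dbe2 >= 2 * config.dbe_range[0]) & (dbe2 <= 2 * config.dbe_range[1])
    ok &= (nosc >= config.nosc_range[0]) & (nosc <= config.nosc_range[1])
    return ok


def is_valid_formula(f: MolecularFormula, config: AssignmentConfig) -> bool:
    return bool(valid_formula_mask(*(np.array([x]) for x in f), config)[0])


class _Catalog:
    """All valid formulas under a config, sorted by theoretical [M-H]- m/z."""

    def __init__(self, config: AssignmentConfig):
        c, h, n, o, s = np.meshgrid(
            np.arange(config.c_range[0], config.c_range[1] + 1),
            np.arange(config.h_range[0], config.h_range[1] + 1),
            np.arange(config.n_range[0], config.n_range[1] + 1),
            np.arange(config.o_range[0], config.o_range[1] + 1),
            np.arange(config.s_range[0], config.s_range[1] + 1),
            indexing="ij", copy=False,
        )
        c, h, n, o, s = (a.ravel() for a in (c, h, n, o, s))
        mask = valid_formula_mask(c, h, n, o, s, config)
        mz = (c * MASS_C + h * MASS_H + n * MASS_N + o * MASS_O + s * MASS_S
              - PROTON_MASS)
        pad = config.mz_window[1] * config.tolerance_ppm * 1e-6 + 1e-6
        mask &= (mz >= config.mz_window[0] - pad) & (mz <= config.mz_window[1] + pad)
        order = np.argsort(mz[mask], kind="stable")
        self.mz = mz[mask][order]
        self.elements = np.stack([a[mask][order] for a in (c, h, n, o, s)], axis=1)
        self.elements = self.elements.astype(np.int32)


_CATALOG_CACHE: dict[tuple, _Catalog] = {}


def _catalog_for(config: AssignmentConfig) -> _Catalog:
    key = (config.c_range, config.h_range, config.n_range, config.o_range,
           config.s_range, config.hc_range, config.oc_range, config.dbe_range,
           config.nosc_range, config.mz_window, round(config.tolerance_ppm, 9))
    cat = _CATALOG_CACHE.get(key)
    if cat is None:
        cat = _CATALOG_CACHE[key] = _Catalog(config)
    return cat


def _candidate_sort_key(row, ppm):
    c, h, n, o, s = (int(x) for x in row)
    dbe2 = 2 * c - h + n + 2
    return (abs(ppm), n + s, dbe2, (c, h, n, o, s))


def candidate_formulas(
    mz: float, config: AssignmentConfig | None = None
) -> list[tuple[MolecularFormula, float]]:
    """All valid formulas whose [M-H]- m/z lies within tolerance of ``mz``.

    Returns (formula, ppm_error) pairs, ppm_error = (observed - theoretical)
    / theoretical * 1e6, sorted by the deterministic assignment key
    (|ppm|, then N+S, then DBE, then element counts). Empty list if nothing
    matches. ``mz`` must lie inside the configured instrument window.
    """
    if config is None:
        config = AssignmentConfig()
    if not (config.mz_window[0] <= mz <= config.mz_window[1]):
        raise ValueError(
            f"m/z {mz} outside instrument window {config.mz_window}")
    cat = _catalog_for(config)
    tol = config.tolerance_ppm * 1e-6
    lo = bisect.bisect_left(cat.mz, mz / (1 + tol))
    hi = bisect.bisect_right(cat.mz, mz / (1 - tol) if tol < 1 else np.inf)
    out = []
    for i in range(lo, hi):
        theo = cat.mz[i]
        ppm = (mz - theo) / theo * 1e6
        if abs(ppm) <= config.tolerance_ppm:
            out.append((MolecularFormula(*map(int, cat.elements[i])), ppm))
    out.sort(key=lambda fp: _candidate_sort_key(fp[0], fp[1]))
    return out


# ---------------------------------------------------------------------------
# Peak-list assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssignedPeak:
    """A peak with its chosen formula, descriptors and compound class."""

    mz: float
    intensity: float
    formula: MolecularFormula
    descriptors: FormulaDescriptors
    ppm_error: float
    compound_class: str
    n_candidates: int

    @property
    def peak(self) -> Peak:
        return Peak(self.mz, self.intensity)


@dataclass
class AssignmentResult:
    assigned: list[AssignedPeak]
    unassigned: list[Peak]

    @property
    def n_peaks(self) -> int:
        return len(self.assigned) + len(self.unassigned)


def assign_peaklist(
    peaks: Sequence[Peak],
    config: AssignmentConfig | None = None,
    scheme: ClassScheme | None = None,
) -> AssignmentResult:
    """Assign each peak its best candidate formula.

    Ties are broken deterministically: smallest |ppm error|, then fewest
    N+S atoms, then lowest DBE, then lexicographic element counts. Peaks
    resolving to the same formula are merged by summing intensity (the
    record with the highest intensity supplies the representative m/z).
    Peaks with no candidate are returned unassigned.
    """
    if len(peaks) == 0:
        raise AnalysisError("assign_peaklist requires at least one peak")
    if config is None:
        config = AssignmentConfig()
    if scheme is None:
        scheme = default_class_scheme()
    cat = _catalog_for(config)
    mzs = np.asarray([p[0] for p in peaks], dtype=float)
    tol = config.tolerance_ppm * 1e-6
    lo_idx = np.searchsorted(cat.mz, mzs / (1 + tol), side="left")
    hi_idx = np.searchsorted(cat.mz, mzs / (1 - tol), side="right")

    chosen: dict[MolecularFormula, AssignedPeak] = {}
    unassigned: list[Peak] = []
    for k, peak in enumerate(peaks):
        mz, intensity = float(peak[0]), float(peak[1])
        best = None
        n_cand = 0
        for i in range(lo_idx[k], hi_idx[k]):
            theo = cat.mz[i]
            ppm = (mz - theo) / theo * 1e6
            if abs(ppm) > config.tolerance_ppm:
                continue
            n_cand += 1
            key = _candidate_sort_key(cat.elements[i], ppm)
            if best is None or key < best[0]:
                best = (key, i, ppm)
        if best is None:
            unassigned.append(Peak(mz, intensity))
            continue
        _, i, ppm = best
        formula = MolecularFormula(*map(int, cat.elements[i]))
        prev = chosen.get(formula)
        if prev is None:
            desc = descriptors(formula)
            chosen[formula] = AssignedPeak(
                mz=mz, intensity=intensity, formula=formula, descriptors=desc,
                ppm_error=ppm, compound_class=classify(desc, scheme),
                n_candidates=n_cand,
            )
        else:
            rep_first = prev.intensity >= intensity
            chosen[formula] = AssignedPeak(
                mz=prev.mz if rep_first else mz,
                intensity=prev.intensity + intensity,
                formula=formula, descriptors=prev.descriptors,
                ppm_error=prev.ppm_error if rep_first else ppm,
                compound_class=prev.compound_class,
                n_candidates=max(prev.n_candidates, n_cand),
            )
    assigned = sorted(chosen.values(), key=lambda a: a.descriptors.theoretical_mz)
    return AssignmentResult(assigned=assigned, unassigned=unassigned)


# ---------------------------------------------------------------------------
# Sample-level summaries
# ---------------------------------------------------------------------------

def class_abundance(
    assigned: Sequence[AssignedPeak],
    weighting: str = "intensity",
    scheme: ClassScheme | None = None,
) -> pd.Series:
    """Relative abundance per compound class (sums to 1, "unclassified" included).

    ``weighting="intensity"`` sums peak intensities (the default, matching
    intensity-scaled van Krevelen plots); ``"count"`` counts formulas.
    """
    if len(assigned) == 0:
        raise AnalysisError("class_abundance requires at least one assigned peak")
    if weighting not in ("intensity", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    labels = (scheme.labels() if scheme is not None else CLASS_LABELS)
    totals = dict.fromkeys(tuple(labels) + (UNCLASSIFIED,), 0.0)
    for a in assigned:
        w = a.intensity if weighting == "intensity" else 1.0
        totals[a.compound_class] = totals.get(a.compound_class, 0.0) + w
    series = pd.Series(totals, dtype=float)
    return series / series.sum()


def chemodiversity(assigned: Sequence[AssignedPeak] | np.ndarray) -> float:
    """Shannon diversity (nats) over assigned-formula intensity shares."""
    if hasattr(assigned, "__len__") and len(assigned) == 0:
        raise AnalysisError("chemodiversity requires at least one assigned peak")
    first = assigned[0]
    if isinstance(first, AssignedPeak):
        intensities = np.array([a.intensity for a in assigned], dtype=float)
    else:
        intensities = np.asarray(assigned, dtype=float)
    if np.any(intensities <= 0):
        raise AnalysisError("chemodiversity requires strictly positive intensities")
    return shannon_nats(intensities)


@dataclass
class FormulaSetComparison:
    """Shared / unique formula partitions between two assigned samples."""

    shared: list[MolecularFormula]
    unique_to_a: list[MolecularFormula]
    unique_to_b: list[MolecularFormula]
    class_tallies: dict[str, Counter]


def compare_formula_sets(
    a: Sequence[AssignedPeak], b: Sequence[AssignedPeak]
) -> FormulaSetComparison:
    """Partition the exact (c,h,n,o,s) formula sets of two samples."""
    class_of: dict[MolecularFormula, str] = {}
    for ap in list(a) + list(b):
        class_of[ap.formula] = ap.compound_class
    sa = {ap.formula for ap in a}
    sb = {ap.formula for ap in b}
    shared = sorted(sa & sb)
    ua = sorted(sa - sb)
    ub = sorted(sb - sa)
    tallies = {
        "shared": Counter(class_of[f] for f in shared),
        "unique_to_a": Counter(class_of[f] for f in ua),
        "unique_to_b": Counter(class_of[f] for f in ub),
    }
    return FormulaSetComparison(shared, ua, ub, tallies)
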