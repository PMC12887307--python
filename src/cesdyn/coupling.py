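"""Cross-domain statistics coupling community structure to DOM chemistry.

Four analyses link the microbial side of a sealed microcosm to its
dissolved-organic-matter pool:

* Mantel test between two sample-matched distance matrices (seeded
  permutations, exhaustive mode for small n);
* a genus x (heteroatom series, molecular-weight bin) Spearman correlation
  grid, masked at a minimum |rho|;
* two-sample Kolmogorov-Smirnov comparison of carbon oxidation state
  (NOSC) distributions between time points;
* a linear-vs-logarithmic regression comparison of DOM chemodiversity on
  microbial Shannon diversity, to ask whether chemical diversity collapses
  faster than the community that maintains it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dom import AssignedPeak
from .errors import AnalysisError
from ._util import rng_from_seed

__all__ = [
    "MantelResult",
    "CorrelationGrid",
    "KSResult",
    "FitComparison",
    "mantel",
    "dom_series_bins",
    "genus_dom_correlation_grid",
    "ks_two_sample",
    "diversity_fit",
    "profile_distance_matrix",
]

DEFAULT_SERIES = ("CHO", "CHNO", "CHOS")


@dataclass(frozen=True)
class MantelResult:
    rho: float
    p_value: float
    n_permutations: int
    seed: object = None
    method: str = "spearman"
    alternative: str = "two-sided"
    exhaustive: bool = False


@dataclass
class CorrelationGrid:
    """Spearman rho per (genus, series-bin) cell with a |rho| display mask.

    ``rho``: DataFrame (genus x series-bin); ``masked``: same-shaped boolean
    frame, True where the cell is suppressed; ``reasons`` notes cells masked
    for a reason other than the threshold (zero-variance inputs).
    """

    rho: pd.DataFrame
    masked: pd.DataFrame
    threshold: float
    reasons: dict = field(default_factory=dict)

    def displayed(self) -> pd.DataFrame:
        return self.rho.where(~self.masked)


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str = "asymp"


@dataclass(frozen=True)
class FitComparison:
    linear_slope: float
    linear_intercept: float
    linear_r_squared: float
    linear_p: float
    log_a: float
    log_b: float
    log_r_squared: float
    log_p: float
    preferred: str
    n: int


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _condensed(D: np.ndarray) -> np.ndarray:
    return D[np.triu_indices(D.shape[0], 1)]


def _matrix_and_ids(dm):
    if hasattr(dm, "data") and hasattr(dm, "ids"):
        return np.asarray(dm.data, dtype=float), [str(i) for i in dm.ids]
    arr = np.asarray(dm, dtype=float)
    return arr, None


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise AnalysisError("constant distance vector; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    dm_a,
    dm_b,
    method: str = "spearman",
    n_permutations: int = 999,
    seed=None,
    alternative: str = "two-sided",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test of matrix association on the upper-triangle vectors.

    The null is built by jointly permuting rows and columns of ``dm_b``;
    two-sided p compares |rho|; p = (count + 1)/(n_permutations + 1), or the
    exact proportion over all n! relabelings when ``exhaustive`` (n <= 8).
    Distance matrices must share ids in the same order (checked when both
    carry ids).
    """
    A, ids_a = _matrix_and_ids(dm_a)
    B, ids_b = _matrix_and_ids(dm_b)
    if ids_a is not None and ids_b is not None and ids_a != ids_b:
        raise AnalysisError(
            f"distance matrices are not sample-matched: {ids_a} vs {ids_b}")
    n = A.shape[0]
    if B.shape[0] != n:
        raise AnalysisError("distance matrices differ in size")
    if n < 4:
        raise AnalysisError("mantel needs >= 4 samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    vec_a = _condensed(A)
    rho_obs = _corr(vec_a, _condensed(B), method)

    def extreme(rho_perm: float) -> bool:
        eps = 1e-12
        if alternative == "two-sided":
            return abs(rho_perm) >= abs(rho_obs) - eps
        if alternative == "greater":
            return rho_perm >= rho_obs - eps
        return rho_perm <= rho_obs + eps

    if exhaustive:
        if n > 8:
            raise AnalysisError("exhaustive mantel limited to n <= 8")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            rho_p = _corr(vec_a, _condensed(B[np.ix_(idx, idx)]), method)
            count += extreme(rho_p)
            total += 1
        return MantelResult(rho_obs, count / total, total, seed, method,
                            alternative, True)
    rng = rng_from_seed(seed)
    iu = np.triu_indices(n, 1)
    ra = stats.rankdata(vec_a) if method == "spearman" else vec_a
    ra_c = ra - ra.mean()
    count = 0
    eps = 1e-12
    for start in range(0, n_permutations, 256):  # batched row/col permutation
        batch = min(256, n_permutations - start)
        idx = np.stack([rng.permutation(n) for _ in range(batch)])
        vecs = B[idx[:, :, None], idx[:, None, :]][:, iu[0], iu[1]]
        if method == "spearman":
            vecs = stats.rankdata(vecs, axis=1)
        vc = vecs - vecs.mean(axis=1, keepdims=True)
        denom = np.sqrt((vc ** 2).sum(axis=1) * (ra_c ** 2).sum())
        rho_p = (vc @ ra_c) / denom
        if alternative == "two-sided":
            count += int(np.sum(np.abs(rho_p) >= abs(rho_obs) - eps))
        elif alternative == "greater":
            count += int(np.sum(rho_p >= rho_obs - eps))
        else:
            count += int(np.sum(rho_p <= rho_obs + eps))
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(rho_obs, float(p), n_permutations, seed, method,
                        alternative, False)


# ---------------------------------------------------------------------------
# DOM series x molecular-weight bins
# ---------------------------------------------------------------------------

def dom_series_bins(
    assigned_by_sample: Mapping[str, Sequence[AssignedPeak]],
    bin_width: float = 50.0,
    mass_range: tuple[float, float] = (200.0, 600.0),
    series: Sequence[str] = DEFAULT_SERIES,
) -> pd.DataFrame:
    """Summed intensity per (heteroatom series, neutral-mass bin) per sample.

    Bins are half-open [lo, lo + width) over ``mass_range``; masses outside
    the range and series not listed are excluded. Empty cells are 0.
    """
    lo, hi = mass_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    rows = pd.MultiIndex.from_product(
        [list(series), edges[:-1].tolist()], names=["series", "bin_lo"])
    out = pd.DataFrame(0.0, index=rows, columns=list(assigned_by_sample))
    for sample, assigned in assigned_by_sample.items():
        for a in assigned:
            if a.descriptors.series not in series:
                continue
            mass = a.descriptors.neutral_monoisotopic_mass
            if not (lo <= mass < hi):
                continue
            b = edges[int(np.searchsorted(edges, mass, side="right")) - 1]
            out.loc[(a.descriptors.series, b), sample] += a.intensity
    return out


def profile_distance_matrix(bins: pd.DataFrame, standardize: bool = True):
    """Euclidean distances between samples over their (series, bin) intensity
    profiles — the DOM-side matrix for a global Mantel test. Rows with zero
    variance are dropped before optional z-scoring."""
    from skbio import DistanceMatrix
    from scipy.spatial.distance import pdist, squareform

    X = bins.to_numpy(dtype=float)
    keep = X.std(axis=1) > 0
    X = X[keep]
    if standardize and X.size:
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    D = squareform(pdist(X.T, metric="euclidean"))
    return DistanceMatrix(D, ids=[str(c) for c in bins.columns])


def genus_dom_correlation_grid(
    genus_abundances: pd.DataFrame,
    dom_bins: pd.DataFrame,
    threshold: float = 0.3,
) -> CorrelationGrid:
    """Spearman rho of each genus against each (series, bin) across samples.

    Cells with |rho| below ``threshold`` are masked for display; cells whose
    inputs have zero variance are masked with a recorded reason. Requires
    >= 4 shared samples, compared in matched column order.
    """
    shared = [s for s in genus_abundances.columns if s in dom_bins.columns]
    if len(shared) < 4:
        raise AnalysisError(
            f"correlation grid needs >= 4 shared samples, got {len(shared)}")
    G = genus_abundances[shared]
    Bn = dom_bins[shared]
    rho = pd.DataFrame(np.nan, index=G.index, columns=Bn.index)
    masked = pd.DataFrame(True, index=G.index, columns=Bn.index)
    reasons: dict = {}
    for genus in G.index:
        gv = G.loc[genus].to_numpy(dtype=float)
        for col in Bn.index:
            bv = Bn.loc[col].to_numpy(dtype=float)
            if np.std(gv) == 0 or np.std(bv) == 0:
                reasons[(genus, col)] = "zero variance"
                continue
            r = stats.spearmanr(gv, bv).statistic
            rho.loc[genus, [col]] = r
            masked.loc[genus, [col]] = abs(r) < threshold
    return CorrelationGrid(rho=rho, masked=masked, threshold=threshold,
                           reasons=reasons)


# ---------------------------------------------------------------------------
# KS comparison of NOSC distributions
# ---------------------------------------------------------------------------

def ks_two_sample(x, y, method: str = "asymp") -> KSResult:
    """Two-sample Kolmogorov-Smirnov test (D = sup |ECDF_x - ECDF_y|).

    ``method`` "asymp" (default; appropriate for the thousands of formulas a
    spectrum yields) or "exact" for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("ks_two_sample needs >= 2 values per sample")
    res = stats.ks_2samp(x, y, method=method)
    return KSResult(d_statistic=float(res.statistic), p_value=float(res.pvalue),
                    n_x=len(x), n_y=len(y), method=method)


# ---------------------------------------------------------------------------
# Diversity-chemodiversity regression comparison
# ---------------------------------------------------------------------------

def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R^2, two-sided p of slope; R^2 = 0 for constant y."""
    if np.std(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.pvalue))


def diversity_fit(x, y) -> FitComparison:
    """Compare y = a + b*x against y = a + b*ln(x) by OLS.

    ``x`` are microbial Shannon indices, ``y`` the paired DOM chemodiversity
    values. ``preferred`` names the form with the higher R^2. All x must be
    positive for the logarithmic form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise AnalysisError("x and y must be paired")
    if len(x) < 3:
        raise AnalysisError("diversity_fit needs >= 3 points")
    bad = np.flatnonzero(x <= 0)
    if bad.size:
        raise AnalysisError(
            f"logarithmic fit undefined: x[{bad[0]}] = {x[bad[0]]} <= 0")
    slope, intercept, r2_lin, p_lin = _linfit(x, y)
    b, a, r2_log, p_log = _linfit(np.log(x), y)
    preferred = "logarithmic" if r2_log > r2_lin else "linear"
    return FitComparison(
        linear_slope=slope, linear_intercept=intercept,
        linear_r_squared=r2_lin, linear_p=p_lin,
        log_a=a, log_b=b, log_r_squared=r2_log, log_p=p_log,
        preferred=preferred, n=len(x),
    )
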