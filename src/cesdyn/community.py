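"""Downstream analytics for ASV count tables.

Consumes finished amplicon sequence variant (ASV) tables — sample x ASV
counts with taxonomy lineages — and provides the standard ecology toolkit
used to characterize community succession: singleton filtering, genus-level
relative abundance, Shannon diversity (nats), Bray-Curtis dissimilarity,
principal coordinates analysis (classical scaling), PERMANOVA and the
homogeneity-of-dispersion test. The two permutation tests are seeded, use
the (count + 1)/(permutations + 1) p-value convention, and offer exhaustive
enumeration for small designs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import AnalysisError
from ._util import shannon_nats, rng_from_seed

__all__ = [
    "ASVTable",
    "PcoaResult",
    "PermanovaResult",
    "DispersionResult",
    "filter_asv_table",
    "genus_from_taxonomy",
    "genus_abundance",
    "genus_top_abundance",
    "shannon",
    "bray_curtis",
    "pcoa",
    "permanova",
    "beta_dispersion",
]

UNCLASSIFIED_GENUS = "unclassified_genus"


@dataclass
class ASVTable:
    """ASV x sample counts with taxonomy and per-sample metadata.

    ``counts``: DataFrame, index = ASV ids, columns = sample ids, integral.
    ``taxonomy``: Series mapping ASV id -> semicolon-delimited rank lineage
    whose 6th field is the genus.
    ``sample_metadata``: optional DataFrame indexed by sample id (e.g. a
    ``time_point`` column).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate ASV ids: {list(dups)}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dups)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)


def filter_asv_table(
    table: ASVTable, min_total_reads: int = 2, per_sample: bool = False
) -> ASVTable:
    """Drop rare ASVs.

    Default: remove ASVs whose total count summed over all samples is below
    ``min_total_reads`` (dataset-wide singleton removal at the default of 2).
    ``per_sample=True`` instead zeroes counts below the threshold within each
    sample and drops ASVs that become empty.
    """
    counts = table.counts
    if per_sample:
        counts = counts.where(counts >= min_total_reads, 0)
        keep = counts.sum(axis=1) > 0
    else:
        keep = counts.sum(axis=1) >= min_total_reads
    if not keep.any():
        raise AnalysisError("filtering removed every ASV")
    counts = counts.loc[keep]
    return ASVTable(counts=counts, taxonomy=table.taxonomy.loc[keep],
                    sample_metadata=table.sample_metadata)


def genus_from_taxonomy(lineage: str | float) -> str:
    """Genus = 6th semicolon-delimited rank; strips a 'g__' style prefix.

    Unparseable or empty lineages map to "unclassified_genus"."""
    if not isinstance(lineage, str):
        return UNCLASSIFIED_GENUS
    fields = [f.strip() for f in lineage.split(";")]
    if len(fields) < 6 or not fields[5]:
        return UNCLASSIFIED_GENUS
    genus = fields[5]
    if "__" in genus:
        genus = genus.split("__", 1)[1]
    return genus or UNCLASSIFIED_GENUS


def genus_abundance(table: ASVTable) -> pd.DataFrame:
    """Genus x sample relative abundances (columns sum to 1)."""
    genera = table.taxonomy.map(genus_from_taxonomy)
    summed = table.counts.groupby(genera.to_numpy()).sum()
    totals = summed.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise AnalysisError(f"samples with zero total reads: {empty}")
    return summed / totals


def genus_top_abundance(table: ASVTable, n: int = 20) -> pd.DataFrame:
    """Top-``n`` genera by mean relative abundance; remainder pooled as "other"."""
    rel = genus_abundance(table)
    order = rel.mean(axis=1).sort_values(ascending=False)
    top = list(order.index[:n])
    rest = rel.drop(index=top)
    out = rel.loc[top]
    if len(rest):
        out.loc["other"] = rest.sum(axis=0)
    return out


def shannon(counts) -> float:
    """Shannon diversity H (nats) of one sample's counts."""
    return shannon_nats(counts)


# ---------------------------------------------------------------------------
# Distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(table: ASVTable | pd.DataFrame):
    """Bray-Curtis dissimilarity between samples, from ASV counts.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i). Returns a
    ``skbio.DistanceMatrix`` with the sample ids.
    """
    from skbio import DistanceMatrix

    counts = table.counts if isinstance(table, ASVTable) else table
    if counts.shape[1] < 2:
        raise AnalysisError("bray_curtis needs >= 2 samples")
    X = counts.to_numpy(dtype=float).T  # samples x features
    if (X.sum(axis=1) == 0).any():
        bad = [c for c, tot in zip(counts.columns, X.sum(axis=1)) if tot == 0]
        raise AnalysisError(f"samples with zero total counts: {bad}")
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(c) for c in counts.columns])


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix.

    ``coordinates``: samples x axes (positive eigenvalues only), columns
    PCo1, PCo2, ... ordered by descending eigenvalue. ``eigenvalues`` holds
    the full spectrum including any negative values (reported, never
    embedded); ``proportion_explained`` is each positive eigenvalue over
    the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    ids: list[str]


def _as_square(dm):
    """Accept a skbio DistanceMatrix or a square ndarray; return (array, ids)."""
    if hasattr(dm, "data") and hasattr(dm, "ids"):
        return np.asarray(dm.data, dtype=float), [str(i) for i in dm.ids]
    arr = np.asarray(dm, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def pcoa(dm) -> PcoaResult:
    """Principal coordinates: eigendecompose the double-centered -D^2/2."""
    D, ids = _as_square(dm)
    n = D.shape[0]
    if n < 3:
        raise AnalysisError("pcoa needs >= 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = np.where(pos, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])])
    return PcoaResult(coordinates=frame, eigenvalues=eigvals,
                      proportion_explained=prop, ids=ids)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: object = None
    exhaustive: bool = False


@dataclass
class DispersionResult:
    group_means: dict
    f_statistic: float
    p_value: float
    n_permutations: int
    seed: object = None
    warnings: list = field(default_factory=list)


def _group_codes(groups: Sequence, n: int) -> np.ndarray:
    groups = list(groups)
    if len(groups) != n:
        raise AnalysisError(
            f"{len(groups)} group labels for {n} samples")
    _, codes = np.unique(np.asarray(groups, dtype=object), return_inverse=True)
    return codes


def _permanova_stats(d2: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances (Anderson's formulation)."""
    n = d2.shape[0]
    k = codes.max() + 1
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    if n - k == 0 or ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def _batched_permanova_f(d2: np.ndarray, codes_batch: np.ndarray) -> np.ndarray:
    """Pseudo-F for a batch of label vectors (B x n), vectorized."""
    B, n = codes_batch.shape
    k = codes_batch.max() + 1
    counts = np.apply_along_axis(np.bincount, 1, codes_batch, minlength=k)
    inv = 1.0 / counts  # B x k
    w = inv[np.arange(B)[:, None], codes_batch]  # B x n: 1/n_g per sample
    same = codes_batch[:, :, None] == codes_batch[:, None, :]
    W = np.where(same, w[:, :, None], 0.0)
    ss_within = (W * d2[None, :, :]).sum(axis=(1, 2)) / 2.0
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    f = np.where(ss_within == 0, np.where(ss_between > 0, np.inf, 0.0), f)
    return f


def permanova(
    dm,
    groups: Sequence,
    n_permutations: int = 999,
    seed=None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Free permutation of sample labels (no strata); p-value is
    (#{F_perm >= F_obs} + 1)/(n_permutations + 1), or the exact proportion
    over all distinct label orderings when ``exhaustive`` (n <= 9).
    """
    D, _ = _as_square(dm)
    n = D.shape[0]
    codes = _group_codes(groups, n)
    if codes.max() == 0:
        raise AnalysisError("permanova needs >= 2 groups")
    d2 = D ** 2
    f_obs, r2 = _permanova_stats(d2, codes)
    eps = 1e-12
    if exhaustive:
        if n > 9:
            raise AnalysisError("exhaustive permanova limited to n <= 9")
        perms = np.array(list(itertools.permutations(range(n))))
        f_all = _batched_permanova_f(d2, codes[perms])
        p = float((f_all >= f_obs - eps).mean())
        return PermanovaResult(f_obs, r2, p, len(perms), seed, True)
    rng = rng_from_seed(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    f_perm = _batched_permanova_f(d2, codes[perms])
    p = (np.sum(f_perm >= f_obs - eps) + 1) / (n_permutations + 1)
    return PermanovaResult(f_obs, r2, float(p), n_permutations, seed, False)


def _dispersion_distances(dm, codes: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in the full PCoA space,
    with the imaginary-axis correction (negative-eigenvalue contributions
    subtracted from the squared real-axis distances)."""
    D, _ = _as_square(dm)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    tol = max(abs(eigvals).max(), 1.0) * 1e-12
    pos = eigvals > tol
    neg = eigvals < -tol
    Xr = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    Xi = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    z2 = np.zeros(n)
    for g in range(codes.max() + 1):
        idx = codes == g
        cr = Xr[idx].mean(axis=0)
        ci = Xi[idx].mean(axis=0) if Xi.size else np.zeros(0)
        real = ((Xr[idx] - cr) ** 2).sum(axis=1)
        imag = ((Xi[idx] - ci) ** 2).sum(axis=1) if Xi.size else 0.0
        z2[idx] = np.maximum(real - imag, 0.0)
    return np.sqrt(z2)


def _anova_f(z: np.ndarray, codes: np.ndarray) -> float:
    k = codes.max() + 1
    n = len(z)
    grand = z.mean()
    ss_b = ss_w = 0.0
    for g in range(k):
        zg = z[codes == g]
        ss_b += len(zg) * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return float((ss_b / (k - 1)) / (ss_w / (n - k)))


def beta_dispersion(
    dm,
    groups: Sequence,
    n_permutations: int = 999,
    seed=None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions (betadisper-style).

    Distances to group centroids are computed in the full principal
    coordinate space (imaginary axes subtracted); group differences are
    tested by a one-way F whose null distribution comes from permuting the
    centroid distances across groups.
    """
    D, _ = _as_square(dm)
    codes = _group_codes(groups, D.shape[0])
    if codes.max() == 0:
        raise AnalysisError("beta_dispersion needs >= 2 groups")
    warnings = []
    labels, counts = np.unique(codes, return_counts=True)
    for g, cnt in zip(labels, counts):
        if cnt < 2:
            warnings.append(
                f"group {np.asarray(list(groups), dtype=object)[codes == g][0]!r} "
                "has a single sample and contributes no dispersion information")
    z = _dispersion_distances(dm, codes)
    f_obs = _anova_f(z, codes)
    rng = rng_from_seed(seed)
    count = 0
    eps = 1e-12
    for _ in range(n_permutations):
        if _anova_f(z[rng.permutation(len(z))], codes) >= f_obs - eps:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    group_names = {}
    raw = np.asarray(list(groups), dtype=object)
    for g in range(codes.max() + 1):
        group_names[raw[codes == g][0]] = float(z[codes == g].mean())
    return DispersionResult(group_means=group_names, f_statistic=f_obs,
                            p_value=float(p), n_permutations=n_permutations,
                            seed=seed, warnings=warnings)
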