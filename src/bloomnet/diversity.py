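"""Alpha/beta diversity and the group tests used to compare regions.

Shannon entropy uses natural logarithms so that Pielou's evenness
J = H / ln(S) is internally consistent.  Beta diversity is Bray-Curtis
dissimilarity ordinated by classical PCoA (Gower double-centering); group
separation is tested by PERMANOVA (Anderson 2001 pseudo-F with seeded label
permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "TestResult", "PcoaResult", "alpha_diversity", "wilcoxon_rank_sum",
    "bray_curtis", "pcoa", "permanova", "group_compare_environment",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # samples x retained axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    percent_explained: np.ndarray      # per retained axis, of positive inertia


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Sobs, Shannon H (nats) and Pielou J for a count table.

    J is reported as missing (NaN) for single-ASV samples, where evenness
    is undefined.
    """
    sums = table.sum(axis=1)
    if (sums <= 0).any():
        empty = sums.index[sums <= 0][0]
        raise ValueError(f"sample {empty!r} has zero reads")
    values = table.to_numpy(dtype=float)
    p = values / values.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    sobs = (values > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(sobs > 1, shannon / np.log(sobs), np.nan)
    return pd.DataFrame({"sobs": sobs, "shannon": shannon, "pielou": pielou},
                        index=table.index)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the pooled size is <= 20 and the
    data are tie-free, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=len(x) * len(y) / 2.0, p_value=1.0,
                          n=(len(x), len(y)), method="wilcoxon-rank-sum",
                          degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                   use_continuity=True)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=(len(x), len(y)), method=f"wilcoxon-rank-sum ({method})")


def bray_curtis(matrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix of nonnegative abundance rows."""
    if isinstance(matrix, pd.DataFrame):
        ids = [str(i) for i in matrix.index]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(values.shape[0])]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (values < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = values.sum(axis=1) == 0
    if zero.sum() >= 2 or (zero.sum() == 1 and values.shape[0] == 2):
        raise ValueError("Bray-Curtis undefined between all-zero samples")
    d = squareform(pdist(values, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=ids)


def pcoa(d: DistanceMatrix, n_axes: int | None = None,
         correction: str | None = None) -> PcoaResult:
    """Classical (metric) MDS of a distance matrix.

    Gower double-centering of -d^2/2, eigendecomposition, coordinates
    scaled by sqrt(eigenvalue).  Percent explained divides each positive
    eigenvalue by the sum of positive eigenvalues; negative eigenvalues are
    reported in ``eigenvalues`` but excluded from that denominator and
    yield no axes.  By default no eigenvalue correction is applied
    (negative eigenvalues are reported raw); ``correction="lingoes"`` adds
    the smallest constant to the off-diagonal squared distances that makes
    the matrix Euclidean.
    """
    if correction not in (None, "lingoes"):
        raise ValueError(f"unknown correction {correction!r}")
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if correction == "lingoes":
        raw = pcoa(d, n_axes=None, correction=None)
        lam_min = raw.eigenvalues.min()
        if lam_min < 0:
            d2 = dm ** 2 - 2.0 * lam_min
            np.fill_diagonal(d2, 0.0)
            dm = np.sqrt(d2)
    a = -0.5 * dm ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, abs(eigvals).max() * 1e-10) if n else 0.0
    n_pos = int((eigvals > tol).sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        import warnings
        warnings.warn(f"requested {n_axes} axes but only {n_pos} positive "
                      "eigenvalues; truncating", stacklevel=2)
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    pos_sum = eigvals[:n_pos].sum() if n_pos else 1.0
    percent = 100.0 * eigvals[:n_axes] / pos_sum
    coords_df = pd.DataFrame(coords, index=list(d.ids),
                             columns=[f"PCo{i + 1}" for i in range(n_axes)])
    return PcoaResult(coordinates=coords_df, eigenvalues=eigvals,
                      percent_explained=percent)


def _permanova_ss(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances for a stack of label masks.

    ``masks`` is (n_perm, n_groups, n) boolean; returns (n_perm,) SS_within.
    """
    ss = np.zeros(masks.shape[0])
    for g in range(masks.shape[1]):
        m = masks[:, g, :].astype(float)
        ss += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * sizes[g])
    return ss


def permanova(d: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F from the partition of squared distances into within- and
    between-group components; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    over seeded label permutations, so the attainable minimum is
    1/(1 + n_perm).
    """
    groups = np.asarray(list(groups))
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if len(groups) != n:
        raise ValueError("grouping length does not match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    a, big_n = len(labels), n
    d2 = dm ** 2
    ss_total = d2.sum() / (2.0 * big_n)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm + 1, n), dtype=int)
    perms[0] = np.arange(n)
    for i in range(1, n_perm + 1):
        perms[i] = rng.permutation(n)
    masks = np.stack([groups[perms] == lab for lab in labels], axis=1)
    ss_within = _permanova_ss(d2, masks, counts)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (big_n - a))
    f_obs = f[0]
    p = (1.0 + np.sum(f[1:] >= f_obs)) / (1.0 + n_perm)
    return TestResult(statistic=float(f_obs), p_value=float(p),
                      n=tuple(int(c) for c in counts),
                      method=f"PERMANOVA ({n_perm} permutations)")


def group_compare_environment(frame: pd.DataFrame, layer: str,
                              variables: list[str] | None = None) -> pd.DataFrame:
    """Per-variable BR-vs-NR comparison within one depth layer.

    Returns a DataFrame with group means, fold change (mean BR / mean NR,
    rounded to one decimal) and the Wilcoxon rank-sum p-value per variable.
    Missing values are excluded pairwise; variables entirely missing in the
    layer are flagged and skipped.
    """
    sub = frame[frame["layer"] == layer]
    for region in ("BR", "NR"):
        if (sub["region"] == region).sum() == 0:
            raise ValueError(f"layer {layer!r} has no {region} samples")
    if variables is None:
        variables = [c for c in frame.columns
                     if c not in ("region", "layer", "site")
                     and np.issubdtype(frame[c].dtype, np.number)]
    rows = []
    for var in variables:
        x = sub.loc[sub["region"] == "BR", var].dropna()
        y = sub.loc[sub["region"] == "NR", var].dropna()
        if len(x) < 2 or len(y) < 2:
            rows.append(dict(variable=var, layer=layer, mean_br=np.nan,
                             mean_nr=np.nan, fold_change=np.nan, p_value=np.nan,
                             n_br=len(x), n_nr=len(y), skipped=True))
            continue
        res = wilcoxon_rank_sum(x, y)
        mean_br, mean_nr = float(x.mean()), float(y.mean())
        fold = round(mean_br / mean_nr, 1) if mean_nr != 0 else np.nan
        rows.append(dict(variable=var, layer=layer, mean_br=mean_br,
                         mean_nr=mean_nr, fold_change=fold, p_value=res.p_value,
                         n_br=len(x), n_nr=len(y), skipped=False))
    return pd.DataFrame(rows).set_index("variable")
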