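"""Environment-constrained ordination.

Community data are Hellinger-transformed (square root of relative
abundances), environmental data are mean-imputed then log10(x+1)
transformed, screened for collinearity by iterative VIF removal, and
related to the community by redundancy analysis (RDA).  Key variables are
chosen by permutation-based forward selection with the double stopping rule
of vegan's ``ordiR2step``: a candidate is admitted only while its marginal
permutation p-value is below alpha AND the cumulative adjusted R-squared
stays below that of the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .diversity import TestResult  # noqa: F401  (re-exported result type)

__all__ = [
    "EnvMatrix", "RdaResult", "hellinger", "prepare_env", "vif_screen",
    "rda_fit", "forward_select", "taxon_env_spearman", "aggregate_genus",
]


@dataclass
class EnvMatrix:
    """Imputed + transformed environmental predictors with provenance flags."""

    data: pd.DataFrame       # samples x variables, log10(x+1) scale
    imputed: pd.DataFrame    # same shape, True where the cell was mean-imputed
    dropped: list[str] = field(default_factory=list)


@dataclass
class RdaResult:
    r_squared: float
    adj_r_squared: float
    constrained_inertia: float
    total_inertia: float
    eigenvalues: np.ndarray          # constrained axes, descending
    site_scores: pd.DataFrame
    env_scores: pd.DataFrame         # variable loadings (correlation biplot)
    variables: list[str]


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-relative abundances (unit-norm rows)."""
    sums = table.sum(axis=1)
    if (sums <= 0).any():
        empty = sums.index[sums <= 0][0]
        raise ValueError(f"sample {empty!r} has zero total")
    return np.sqrt(table.div(sums, axis=0))


def aggregate_genus(table: pd.DataFrame, tax: pd.DataFrame) -> pd.DataFrame:
    """Sum ASV counts into genus bins (family;genus, so that 'Unclassified'
    genera in different families stay distinct)."""
    labels = (tax.loc[table.columns, "family"].astype(str) + ";"
              + tax.loc[table.columns, "genus"].astype(str))
    return table.T.groupby(labels.values).sum().T


def prepare_env(frame: pd.DataFrame, variables: list[str] | None = None) -> EnvMatrix:
    """Mean-impute missing cells, then log10(x+1)-transform all variables.

    Imputation strictly precedes the transform; every imputed cell is
    flagged.  Variables with no observed values are dropped with a warning.
    """
    if variables is None:
        variables = [c for c in frame.columns
                     if c not in ("region", "layer", "site")
                     and np.issubdtype(frame[c].dtype, np.number)]
    if not variables:
        raise ValueError("no numeric environmental variables found")
    data = frame[variables].astype(float).copy()
    dropped = [v for v in variables if data[v].notna().sum() == 0]
    if dropped:
        warnings.warn(f"dropping all-missing variables: {dropped}", stacklevel=2)
        data = data.drop(columns=dropped)
    imputed = data.isna()
    data = data.fillna(data.mean())
    transformed = np.log10(data + 1.0)
    return EnvMatrix(data=transformed, imputed=imputed, dropped=dropped)


def vif_screen(env: EnvMatrix | pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the worst-VIF variable until all VIF <= threshold.

    VIF_j = 1/(1 - R^2_j) from regressing variable j on the remaining
    variables (with intercept).  Perfectly collinear sets resolve by
    removing the largest-VIF member first, ties broken by column order.
    Returns the retained variable names in original column order.
    """
    data = env.data if isinstance(env, EnvMatrix) else env
    cols = list(data.columns)
    if len(cols) < 2:
        return cols
    if data.shape[0] <= len(cols):
        warnings.warn("fewer samples than variables; VIF screen proceeds by "
                      "iterative removal but estimates are unstable", stacklevel=2)
    while len(cols) > 1:
        x = np.column_stack([np.ones(data.shape[0]), data[cols].to_numpy()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vifs = np.array([variance_inflation_factor(x, j + 1)
                             for j in range(len(cols))])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        if (vifs <= threshold).all():
            break
        worst = int(np.argmax(vifs))  # argmax takes the first of tied maxima
        cols.pop(worst)
    return cols


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def rda_fit(y: pd.DataFrame, env: EnvMatrix | pd.DataFrame,
            variables: list[str] | None = None) -> RdaResult:
    """Redundancy analysis of a (Hellinger-transformed) community matrix.

    Centers response and predictors, takes the fitted values of the
    multivariate least-squares regression of ``y`` on the predictors, and
    eigen-decomposes them.  R^2 is constrained / total inertia; adjusted
    R^2 applies the Ezekiel correction 1 - (1-R^2)(n-1)/(n-p-1).
    """
    data = env.data if isinstance(env, EnvMatrix) else env
    if variables is None:
        variables = list(data.columns)
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"variables not in environmental matrix: {missing}")
    x = _center(data[variables].to_numpy(dtype=float))
    yc = _center(y.to_numpy(dtype=float))
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need n > number of predictors (n={n}, p={p})")
    rank = np.linalg.matrix_rank(x) if p else 0
    if p and rank < p:
        raise ValueError(
            f"rank-deficient design: {p} predictors span only {rank} dimensions "
            f"(collinear set within {variables})")
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    fitted = x @ beta
    total = float((yc ** 2).sum()) / (n - 1)
    constrained = float((fitted ** 2).sum()) / (n - 1)
    r2 = constrained / total if total > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    u, s, _ = np.linalg.svd(fitted / np.sqrt(n - 1), full_matrices=False)
    eig = s ** 2
    keep = eig > max(1e-12, eig.max() * 1e-9) if eig.size else np.array([], bool)
    eig, u, s = eig[keep], u[:, keep], s[keep]
    site = pd.DataFrame(u * s * np.sqrt(n - 1), index=y.index,
                        columns=[f"RDA{i + 1}" for i in range(len(eig))])
    env_scores = pd.DataFrame(
        np.array([[np.corrcoef(x[:, j], site.iloc[:, k])[0, 1]
                   if site.iloc[:, k].std() > 0 else 0.0
                   for k in range(len(eig))] for j in range(p)]),
        index=variables, columns=site.columns)
    return RdaResult(r_squared=r2, adj_r_squared=adj,
                     constrained_inertia=constrained, total_inertia=total,
                     eigenvalues=eig, site_scores=site, env_scores=env_scores,
                     variables=list(variables))


def _rda_ss(x: np.ndarray, yc: np.ndarray) -> float:
    """Explained sum of squares of centered yc regressed on centered x."""
    if x.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    return float(((x @ beta) ** 2).sum())


def forward_select(y: pd.DataFrame, env: EnvMatrix | pd.DataFrame,
                   alpha: float = 0.05, n_perm: int = 999,
                   seed: int | None = None) -> tuple[pd.DataFrame, RdaResult | None]:
    """Permutation-based forward selection of environmental predictors.

    At each step the candidate giving the largest adjusted-R^2 gain is
    tested by permuting the residuals of the reduced model (n_perm label
    permutations of the residual rows); it is admitted only if the marginal
    p <= alpha and the cumulative adjusted R^2 does not exceed the
    full-model adjusted R^2 (double stopping rule).  Returns the selection
    trace (step, variable, adj R^2, p) and the RDA fit on the selected set
    (``None`` when nothing is admissible).
    """
    data = env.data if isinstance(env, EnvMatrix) else env
    candidates = list(data.columns)
    yc = _center(y.to_numpy(dtype=float))
    n = yc.shape[0]
    ss_total = float((yc ** 2).sum())
    full_adj = rda_fit(y, data, candidates).adj_r_squared
    rng = np.random.default_rng(seed)

    def adj_r2(vars_):
        p = len(vars_)
        if n <= p + 1:
            return -np.inf
        x = _center(data[vars_].to_numpy(dtype=float))
        r2 = _rda_ss(x, yc) / ss_total
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    selected: list[str] = []
    trace_rows = []
    while True:
        remaining = [v for v in candidates if v not in selected]
        if not remaining:
            break
        gains = [(adj_r2(selected + [v]), v) for v in remaining]
        best_adj, best_var = max(gains, key=lambda t: t[0])
        if not np.isfinite(best_adj) or best_adj <= adj_r2(selected):
            break
        if best_adj > full_adj + 1e-12:
            break
        # marginal permutation test: permute reduced-model residual rows
        x_red = _center(data[selected].to_numpy(dtype=float)) if selected \
            else np.empty((n, 0))
        if selected:
            beta, *_ = np.linalg.lstsq(x_red, yc, rcond=None)
            fitted_red = x_red @ beta
        else:
            fitted_red = np.zeros_like(yc)
        resid = yc - fitted_red
        x_full = _center(data[selected + [best_var]].to_numpy(dtype=float))
        p_full = x_full.shape[1]
        ss_red = _rda_ss(x_red, yc)

        def pseudo_f(y_mat):
            ss_full = _rda_ss(x_full, y_mat)
            num = (ss_full - ss_red) / 1.0
            den = (float((y_mat ** 2).sum()) - ss_full) / (n - p_full - 1)
            return num / den if den > 0 else np.inf

        f_obs = pseudo_f(yc)
        count = 0
        for _ in range(n_perm):
            y_perm = fitted_red + resid[rng.permutation(n)]
            if pseudo_f(_center(y_perm)) >= f_obs:
                count += 1
        p_val = (1.0 + count) / (1.0 + n_perm)
        if p_val > alpha:
            break
        selected.append(best_var)
        trace_rows.append(dict(step=len(selected), variable=best_var,
                               adj_r_squared=best_adj, p_value=p_val))
    trace = pd.DataFrame(trace_rows,
                         columns=["step", "variable", "adj_r_squared", "p_value"])
    result = rda_fit(y, data, selected) if selected else None
    return trace, result


def taxon_env_spearman(taxon_rel_abund, env: EnvMatrix | pd.DataFrame
                       ) -> pd.DataFrame:
    """Spearman correlation of one taxon's relative abundance with each
    environmental variable (two-sided p from the t approximation)."""
    data = env.data if isinstance(env, EnvMatrix) else env
    x = np.asarray(taxon_rel_abund, dtype=float)
    if len(x) != data.shape[0]:
        raise ValueError("taxon vector length does not match environment rows")
    if len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    rows = []
    constant_x = np.all(x == x[0])
    for var in data.columns:
        if constant_x or data[var].nunique() <= 1:
            rows.append(dict(variable=var, rho=np.nan, p_value=np.nan,
                             n=len(x)))
            continue
        rho, p = scipy.stats.spearmanr(x, data[var].to_numpy())
        rows.append(dict(variable=var, rho=float(rho), p_value=float(p), n=len(x)))
    return pd.DataFrame(rows).set_index("variable")
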