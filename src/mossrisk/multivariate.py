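"""Nonparametric multivariate screening for survey tables.

Spearman correlation with Holm family-wise control (the family is all
element pairs), two-sided Mann-Whitney comparison of two surveys, and a
correlation-matrix PCA summary with per-sample contributions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .survey import ConcentrationMatrix


@dataclass
class CorrelationResult:
    elements: list[str]
    rho: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray  # boolean mask, adjusted p < alpha
    alpha: float = 0.05

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.elements, columns=self.elements)

    def p_adjusted_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.p_adjusted, index=self.elements, columns=self.elements
        )


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # elements x components, orthonormal columns
    scores: pd.DataFrame  # sites x components
    variance_percent: np.ndarray  # per component, non-increasing
    contributions: pd.DataFrame  # sites x components, percent, sums to 100


@dataclass
class SurveyComparison:
    """Per-element two-sided Mann-Whitney results for two surveys."""

    table: pd.DataFrame  # element, n_a, n_b, u, p, significant
    alpha: float = 0.05


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Null distribution of |rho| for untied data: all n! rank permutations.

    Depends only on n, so it is enumerated once and shared by every pair.
    """
    base = np.arange(n, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1))
    return np.abs(rho)


def _spearman_p(rho: float, ranks_x: np.ndarray, ranks_y: np.ndarray, n: int) -> float:
    if np.isnan(rho):
        return np.nan
    if n < 10:
        tied = (np.unique(ranks_x).size < n) or (np.unique(ranks_y).size < n)
        if not tied:
            null = _exact_spearman_null(n)
            return float(np.mean(null >= abs(rho) - 1e-12))
        warnings.warn(
            "tied ranks at n < 10: falling back to the t approximation",
            stacklevel=3,
        )
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_holm(
    matrix: ConcentrationMatrix | pd.DataFrame, alpha: float = 0.05
) -> CorrelationResult:
    """Pairwise Spearman rho with Holm-adjusted p over all element pairs.

    Constant columns yield undefined (NaN) correlations; those pairs are
    masked not-significant. For n_sites < 10 and untied data, p-values
    come from the exact permutation null of rho.
    """
    frame = matrix.to_frame() if isinstance(matrix, ConcentrationMatrix) else matrix
    elements = [str(c) for c in frame.columns]
    values = frame.to_numpy(dtype=float)
    n, m = values.shape
    if n < 5:
        raise ValueError(f"need at least 5 sites, got {n}")

    constant = values.std(axis=0) == 0.0
    if constant.any():
        warnings.warn(
            f"constant element column(s) {list(np.array(elements)[constant])}: "
            "correlations undefined, masked not-significant",
            stacklevel=2,
        )
    ranks = np.apply_along_axis(stats.rankdata, 0, values)

    rho = np.eye(m)
    p_raw = np.zeros((m, m))
    pairs = list(itertools.combinations(range(m), 2))
    flat_p = []
    for i, j in pairs:
        if constant[i] or constant[j]:
            r, p = np.nan, np.nan
        else:
            r = float(np.corrcoef(ranks[:, i], ranks[:, j])[0, 1])
            p = _spearman_p(r, ranks[:, i], ranks[:, j], n)
        rho[i, j] = rho[j, i] = r
        p_raw[i, j] = p_raw[j, i] = p
        flat_p.append(p)

    flat_p = np.asarray(flat_p)
    valid = ~np.isnan(flat_p)
    adjusted_flat = np.full_like(flat_p, np.nan)
    if valid.any():
        adjusted_flat[valid] = holm_adjust(flat_p[valid])
    p_adj = np.zeros((m, m))
    significant = np.zeros((m, m), dtype=bool)
    for (i, j), p in zip(pairs, adjusted_flat):
        p_adj[i, j] = p_adj[j, i] = p
        significant[i, j] = significant[j, i] = bool(p < alpha) if not np.isnan(p) else False
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    return CorrelationResult(
        elements=elements,
        rho=rho,
        p_raw=p_raw,
        p_adjusted=p_adj,
        significant=significant,
        alpha=alpha,
    )


def mann_whitney_compare(
    a: ConcentrationMatrix | pd.DataFrame,
    b: ConcentrationMatrix | pd.DataFrame,
    alpha: float = 0.05,
) -> SurveyComparison:
    """Two-sided Mann-Whitney U per shared element.

    Exact null for small untied samples (combined n < 50); otherwise the
    normal approximation with tie-corrected variance and continuity
    correction. Elements present in only one survey are skipped with a
    warning.
    """
    fa = a.to_frame() if isinstance(a, ConcentrationMatrix) else a
    fb = b.to_frame() if isinstance(b, ConcentrationMatrix) else b
    shared = [c for c in fa.columns if c in set(fb.columns)]
    skipped = sorted(set(fa.columns).symmetric_difference(fb.columns))
    if skipped:
        warnings.warn(f"element(s) present in only one survey skipped: {skipped}",
                      stacklevel=2)
    if not shared:
        raise ValueError("surveys share no elements")
    rows = []
    for element in shared:
        x = fa[element].to_numpy(dtype=float)
        y = fb[element].to_numpy(dtype=float)
        if x.size < 3 or y.size < 3:
            raise ValueError(f"element {element!r}: need n >= 3 in both surveys")
        has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (x.size + y.size < 50 and not has_ties) else "asymptotic"
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "element": element,
                "n_a": x.size,
                "n_b": y.size,
                "u": float(u),
                "p": float(p),
                "significant": bool(p < alpha),
                "method": method,
            }
        )
    return SurveyComparison(table=pd.DataFrame(rows), alpha=alpha)


def pca_summary(
    matrix: ConcentrationMatrix | pd.DataFrame,
    n_components: int = 3,
    log_transform: bool = False,
) -> PCAResult:
    """PCA of the standardized (correlation) survey table.

    Columns are standardized to unit variance (correlation PCA, the
    defensible default when concentrations span five orders of magnitude);
    ``log_transform`` applies log10 first. Constant columns are dropped
    with a warning. Per-sample contribution to a component is the sample's
    squared-score share of that component (percent).
    """
    frame = matrix.to_frame() if isinstance(matrix, ConcentrationMatrix) else matrix
    frame = frame.astype(float)
    if frame.shape[0] <= frame.shape[1]:
        warnings.warn(
            f"only {frame.shape[0]} sites for {frame.shape[1]} elements; "
            "component estimates will be unstable",
            stacklevel=2,
        )
    if log_transform:
        frame = np.log10(frame)
    constant = frame.std(ddof=0) == 0.0
    if constant.any():
        warnings.warn(
            f"dropping constant element column(s): {list(frame.columns[constant])}",
            stacklevel=2,
        )
        frame = frame.loc[:, ~constant]
    if frame.shape[1] == 0:
        warnings.warn("no non-constant columns left; empty PCA result", stacklevel=2)
        empty = pd.DataFrame(index=frame.index)
        return PCAResult(
            loadings=pd.DataFrame(),
            scores=empty,
            variance_percent=np.empty(0),
            contributions=empty,
        )
    standardized = (frame - frame.mean()) / frame.std(ddof=0)

    n_components = min(n_components, *standardized.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(standardized.to_numpy())
    components = [f"PC{i + 1}" for i in range(n_components)]
    score_frame = pd.DataFrame(scores, index=frame.index, columns=components)
    contributions = 100.0 * scores**2 / (scores**2).sum(axis=0)
    return PCAResult(
        loadings=pd.DataFrame(
            pca.components_.T, index=frame.columns, columns=components
        ),
        scores=score_frame,
        variance_percent=100.0 * pca.explained_variance_ratio_,
        contributions=pd.DataFrame(
            contributions, index=frame.index, columns=components
        ),
    )
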