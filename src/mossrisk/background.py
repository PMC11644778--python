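"""Geochemical background estimation from the least-contaminated sites.

The procedure (rank-sum variant of the Krakovska ordering):

1. Rank sites per element (ascending, ties averaged) and sum the ranks per
   site across elements; sites with the smallest rank sums are globally
   least contaminated.
2. Keep the lowest ``subset_fraction`` of sites (ceiling; minimum 3).
3. Per element, iteratively remove single outliers from the subset with a
   two-sided Grubbs test at ``grubbs_alpha`` (capped at one third of the
   subset, re-testing after each removal).
4. The background value is the upper limit of the bootstrap confidence
   interval for the subset mean (percentile bootstrap; two-sided 95% CI
   upper bound = 97.5th percentile of resampled means by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survey import BackgroundTable, ConcentrationMatrix

logger = logging.getLogger(__name__)


@dataclass
class BackgroundConfig:
    subset_fraction: float = 0.10
    grubbs_alpha: float = 0.05
    n_boot: int = 2000
    conf_level: float = 0.95
    one_sided: bool = False  # True -> 95th percentile instead of 97.5th
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.subset_fraction <= 0.5:
            raise ValueError("subset_fraction must be in (0, 0.5]")
        if not 0.0 < self.grubbs_alpha < 0.2:
            raise ValueError("grubbs_alpha must be in (0, 0.2)")
        if self.n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        if not 0.0 < self.conf_level < 1.0:
            raise ValueError("conf_level must be in (0, 1)")


@dataclass
class BackgroundResult:
    table: BackgroundTable
    selected_site_ids: list[str]
    removed_outliers: dict[str, list[str]]  # element -> removed site ids
    subset_mean: dict[str, float]  # mean after outlier removal
    upper_limit: dict[str, float]  # bootstrap upper limit (== table values)
    config: BackgroundConfig = field(repr=False, default_factory=BackgroundConfig)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": list(self.table),
                "subset_mean": [self.subset_mean[e] for e in self.table],
                "n_removed": [len(self.removed_outliers[e]) for e in self.table],
                "background": [self.table[e] for e in self.table],
            }
        )


def rank_sum_order(matrix: ConcentrationMatrix) -> np.ndarray:
    """Per-site rank sums: sites ranked ascending per element, ranks summed.

    Ties receive average ranks. Returned in site order.
    """
    ranks = np.apply_along_axis(stats.rankdata, 0, matrix.values)
    return ranks.sum(axis=1)


def select_background_subset(
    rank_sums: np.ndarray, fraction: float, site_ids: list[str] | None = None
) -> list[int] | list[str]:
    """Indices (or ids) of the ``ceil(fraction * n)`` lowest-rank-sum sites.

    Ties at the cutoff break by site order (stable sort), so the selection
    is deterministic. Raises if the subset would have fewer than 3 sites.
    """
    rank_sums = np.asarray(rank_sums, dtype=float)
    n = rank_sums.size
    k = math.ceil(fraction * n)
    if k < 3:
        raise ValueError(
            f"subset of {k} site(s) from n={n} at fraction={fraction} is below "
            "the minimum of 3; use a larger fraction"
        )
    order = np.argsort(rank_sums, kind="stable")
    chosen = sorted(order[:k].tolist())
    if site_ids is not None:
        return [site_ids[i] for i in chosen]
    return chosen


def grubbs_test(
    values, alpha: float = 0.05
) -> tuple[int | None, float, float]:
    """Two-sided single-outlier Grubbs test.

    Returns ``(outlier_index_or_None, G, critical_value)`` where
    G = max|x - mean| / sd (sample sd) and the critical value is the
    classical t-based expression
    ``(n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2))`` with
    ``t = t_{1 - alpha/(2n), n-2}``. A zero-sd vector yields no outlier.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got n={x.size}")
    n = x.size
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        logger.debug("Grubbs: zero sd, no outlier reported")
        return None, 0.0, math.inf
    deviations = np.abs(x - mean)
    idx = int(np.argmax(deviations))
    g = float(deviations[idx] / sd)
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    critical = float((n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t)))
    return (idx if g > critical else None), g, critical


def bootstrap_upper_limit(
    values,
    n_boot: int = 2000,
    conf_level: float = 0.95,
    seed: int | None = 0,
    one_sided: bool = False,
) -> float:
    """Percentile-bootstrap upper confidence limit for the mean.

    Two-sided by default: the (1+conf_level)/2 quantile of resampled means
    (97.5th percentile at conf_level 0.95). Deterministic given the seed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"bootstrap needs n >= 3, got n={x.size}")
    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[resamples].mean(axis=1)
    q = conf_level if one_sided else (1.0 + conf_level) / 2.0
    return float(np.quantile(means, q))


def estimate_background(
    matrix: ConcentrationMatrix, config: BackgroundConfig | None = None
) -> BackgroundResult:
    """Run the full background procedure on a survey.

    The subset is selected once, globally, from the rank-sum ordering;
    outlier screening and the bootstrap then run per element on that shared
    subset. Per-element bootstrap seeds are spawned deterministically from
    ``config.seed``, and subset values are sorted before resampling, so the
    result is invariant to site-row permutation.
    """
    config = config or BackgroundConfig()
    rank_sums = rank_sum_order(matrix)
    selected = select_background_subset(rank_sums, config.subset_fraction)
    selected_ids = [matrix.site_ids[i] for i in selected]

    max_removals = len(selected) // 3
    seeds = np.random.SeedSequence(config.seed).generate_state(matrix.n_elements)
    table: dict[str, float] = {}
    removed: dict[str, list[str]] = {}
    subset_mean: dict[str, float] = {}
    for j, element in enumerate(matrix.elements):
        # sort by (value, site_id): deterministic under row permutation
        pool = sorted(zip(matrix.values[selected, j], selected_ids))
        removed[element] = []
        # never shrink the pool below 3 (Grubbs and bootstrap both need it)
        while len(removed[element]) < max_removals and len(pool) > 3:
            idx, g, critical = grubbs_test([v for v, _ in pool], config.grubbs_alpha)
            if idx is None:
                break
            value, site = pool.pop(idx)
            removed[element].append(site)
            logger.info(
                "background[%s]: removed outlier site %s (%.4g; G=%.3f > %.3f)",
                element, site, value, g, critical,
            )
        kept = np.array([v for v, _ in pool])
        subset_mean[element] = float(kept.mean())
        if kept.std() == 0.0:
            table[element] = float(kept[0])
        else:
            table[element] = bootstrap_upper_limit(
                kept,
                n_boot=config.n_boot,
                conf_level=config.conf_level,
                seed=int(seeds[j]) % (2**31),
                one_sided=config.one_sided,
            )
    return BackgroundResult(
        table=BackgroundTable(table),
        selected_site_ids=selected_ids,
        removed_outliers=removed,
        subset_mean=subset_mean,
        upper_limit=dict(table),
        config=config,
    )
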