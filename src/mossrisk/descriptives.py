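"""Per-element descriptive summaries in survey-report conventions.

Conventions: sample sd (n-1 denominator); CV% = 100*sd/mean; MAD is the
raw median absolute deviation about the median (no 1.4826 consistency
factor); quantiles use linear interpolation; skewness is the adjusted
Fisher-Pearson sample coefficient. CV% is rounded to integer percent only
at presentation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survey import ConcentrationMatrix


@dataclass(frozen=True)
class DescriptiveSummary:
    element: str
    n: int
    min: float
    max: float
    mean: float
    sd: float
    median: float
    mad: float
    cv_percent: float
    q1: float
    q3: float
    p90: float
    skewness: float

    @property
    def cv_percent_pretty(self) -> int:
        """CV% rounded to integer percent (presentation convention)."""
        return int(round(self.cv_percent))


def summarize_element(values, element: str = "") -> DescriptiveSummary:
    """Summarize one element's concentration vector.

    Requires n >= 2 strictly positive values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be a 1-D vector")
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"element {element or '?'}: all values must be positive and finite")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    median = float(np.median(x))
    q1, q3, p90 = (float(v) for v in np.quantile(x, [0.25, 0.75, 0.90]))
    if sd == 0.0:
        skewness = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # near-constant data
            skewness = float(stats.skew(x, bias=False))
        if np.isnan(skewness):
            skewness = 0.0
    return DescriptiveSummary(
        element=element,
        n=int(x.size),
        min=float(np.min(x)),
        max=float(np.max(x)),
        mean=mean,
        sd=sd,
        median=median,
        mad=float(np.median(np.abs(x - median))),
        cv_percent=100.0 * sd / mean,
        q1=q1,
        q3=q3,
        p90=p90,
        skewness=skewness,
    )


def summary_table(
    matrix: ConcentrationMatrix, by_species: bool = False
) -> list[DescriptiveSummary]:
    """One summary per element, optionally stratified by moss species.

    Species strata with fewer than 2 sites are skipped with a warning.
    When stratified, the ``element`` field reads ``"<element> [<species>]"``.
    """
    if not by_species:
        return [
            summarize_element(matrix.values[:, j], element=el)
            for j, el in enumerate(matrix.elements)
        ]
    species = np.array([s.species for s in matrix.sites])
    summaries: list[DescriptiveSummary] = []
    for label in dict.fromkeys(species):  # first-appearance order
        mask = species == label
        if mask.sum() < 2:
            warnings.warn(
                f"species stratum {label!r} has n={int(mask.sum())} < 2; skipped",
                stacklevel=2,
            )
            continue
        for j, el in enumerate(matrix.elements):
            summaries.append(
                summarize_element(matrix.values[mask, j], element=f"{el} [{label}]")
            )
    return summaries


def summaries_to_frame(summaries: list[DescriptiveSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame in survey-table column order."""
    return pd.DataFrame(
        [
            {
                "element": s.element,
                "n": s.n,
                "min": s.min,
                "max": s.max,
                "mean": s.mean,
                "sd": s.sd,
                "median": s.median,
                "mad": s.mad,
                "cv_percent": s.cv_percent,
                "q1": s.q1,
                "q3": s.q3,
                "p90": s.p90,
                "skewness": s.skewness,
            }
            for s in summaries
        ]
    )
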