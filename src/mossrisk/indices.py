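"""Contamination and ecological-risk indices with their classification scales.

Definitions (Hakanson / Tomlinson family):

    CF      = C_m / C_b                       (contamination factor)
    PLI     = (prod CF_e)^(1/k)               (pollution load index, k CFs)
    PERI_e  = CF_e * TRF_e                    (per-element ecological risk)
    ERI     = sum_e PERI_e                    (site ecological risk index)

All scales are left-closed step functions except where the published ERI
scale is explicitly inclusive on the upper side (150-300 and 300-600).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .registry import PLI_ELEMENTS
from .survey import (
    BackgroundTable,
    ConcentrationMatrix,
    SiteIndexReport,
    ToxicResponseTable,
)


@dataclass(frozen=True)
class ClassificationScale:
    """Ordered contiguous intervals over (0, inf) mapping values to labels.

    ``intervals`` holds ``(lower, upper, label, upper_inclusive)`` rows;
    intervals must tile [0, inf) without gaps or overlap.
    """

    name: str
    intervals: tuple[tuple[float, float, str, bool], ...]

    def __post_init__(self) -> None:
        expected_lower = 0.0
        for lower, upper, _, _ in self.intervals:
            if lower != expected_lower:
                raise ValueError(f"{self.name}: intervals not contiguous at {lower}")
            if upper <= lower:
                raise ValueError(f"{self.name}: empty interval [{lower}, {upper}]")
            expected_lower = upper
        if expected_lower != math.inf:
            raise ValueError(f"{self.name}: intervals do not cover (0, inf)")

    def classify(self, value: float) -> str:
        if not (value >= 0):
            raise ValueError(f"{self.name}: value must be >= 0, got {value!r}")
        previous_inclusive = False
        for lower, upper, label, upper_inclusive in self.intervals:
            in_lower = value > lower if previous_inclusive else value >= lower
            in_upper = value <= upper if upper_inclusive else value < upper
            if in_lower and in_upper:
                return label
            previous_inclusive = upper_inclusive
        raise AssertionError("unreachable: intervals cover (0, inf)")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, _, label, _ in self.intervals)


CF_SCALE = ClassificationScale(
    "contamination factor",
    (
        (0.0, 1.0, "No Contamination", False),
        (1.0, 2.0, "Suspected", False),
        (2.0, 3.5, "Slight", False),
        (3.5, 8.0, "Moderate", False),
        (8.0, 27.0, "Severe", False),
        (27.0, math.inf, "Extreme", False),
    ),
)

PERI_SCALE = ClassificationScale(
    "potential ecological risk",
    (
        (0.0, 40.0, "low", False),
        (40.0, 80.0, "medium", False),
        (80.0, 160.0, "significant", False),
        (160.0, 320.0, "high", False),
        (320.0, math.inf, "extreme", False),
    ),
)

# upper bounds at 300 and 600 are inclusive in the published scale
ERI_SCALE = ClassificationScale(
    "ecological risk index",
    (
        (0.0, 150.0, "low", False),
        (150.0, 300.0, "moderate", True),
        (300.0, 600.0, "considerable", True),
        (600.0, math.inf, "high", False),
    ),
)

#: PLI classes indexed by floor(PLI), capped at 6.
PLI_LABELS: tuple[str, ...] = (
    "no pollution",
    "minimal to moderate",
    "moderate",
    "moderate to severe",
    "severe",
    "severe to extremely high",
    "extremely high",
)


def contamination_factor(c_m: float, c_b: float) -> float:
    """CF = measured concentration / background concentration."""
    if not (c_m > 0 and math.isfinite(c_m)):
        raise ValueError(f"concentration must be positive and finite, got {c_m!r}")
    if not (c_b > 0 and math.isfinite(c_b)):
        raise ValueError(f"background must be positive and finite, got {c_b!r}")
    return c_m / c_b


def classify_cf(cf: float) -> str:
    return CF_SCALE.classify(cf)


def pollution_load_index(
    cf: Mapping[str, float], element_set: Iterable[str] = PLI_ELEMENTS
) -> float:
    """Geometric mean of the CFs over ``element_set`` (nine by default)."""
    element_set = list(element_set)
    missing = [e for e in element_set if e not in cf]
    if missing:
        raise KeyError(f"PLI element(s) missing from CF vector: {missing}")
    values = np.array([cf[e] for e in element_set], dtype=float)
    if np.any(values <= 0):
        raise ValueError("all CFs must be > 0 for the geometric mean")
    return float(np.exp(np.mean(np.log(values))))


def classify_pli(pli: float) -> str:
    """Class from floor(PLI), capped at 'extremely high' (index 6)."""
    if not (pli >= 0):
        raise ValueError(f"PLI must be >= 0, got {pli!r}")
    return PLI_LABELS[min(6, math.floor(pli))]


def peri(cf: float, trf: float) -> float:
    """PERI for one element: contamination factor times toxicity weight."""
    if cf < 0:
        raise ValueError(f"CF must be >= 0, got {cf!r}")
    if trf < 1:
        raise ValueError(f"TRF must be >= 1, got {trf!r}")
    return cf * trf


def classify_peri(value: float) -> str:
    return PERI_SCALE.classify(value)


def ecological_risk_index(peri_values: Mapping[str, float]) -> float:
    """Sum of the per-element PERI values present."""
    if not peri_values:
        raise ValueError("ERI needs at least one PERI value")
    if any(v < 0 for v in peri_values.values()):
        raise ValueError("PERI values must be >= 0")
    return float(sum(peri_values.values()))


def classify_eri(value: float) -> str:
    return ERI_SCALE.classify(value)


def assess_sites(
    matrix: ConcentrationMatrix,
    background: BackgroundTable,
    trf: ToxicResponseTable | None = None,
    pli_elements: Iterable[str] = PLI_ELEMENTS,
) -> list[SiteIndexReport]:
    """Compute CF, PLI, PERI and ERI (with classes) for every site.

    CFs are computed for every element with a background value; PERI/ERI
    use only the elements carrying a toxic-response factor.
    """
    trf = trf or ToxicResponseTable()
    pli_elements = list(pli_elements)
    missing = [e for e in pli_elements if e not in background]
    if missing:
        raise KeyError(f"background missing for PLI element(s): {missing}")
    missing = [e for e in pli_elements if e not in matrix.elements]
    if missing:
        raise KeyError(f"survey missing PLI element(s): {missing}")

    cf_elements = [e for e in matrix.elements if e in background]
    risk_elements = [e for e in cf_elements if e in trf]
    reports = []
    for i, site_id in enumerate(matrix.site_ids):
        row = dict(zip(matrix.elements, matrix.values[i]))
        cf = {e: contamination_factor(row[e], background[e]) for e in cf_elements}
        peri_values = {e: peri(cf[e], trf[e]) for e in risk_elements}
        eri = ecological_risk_index(peri_values)
        pli = pollution_load_index(cf, pli_elements)
        reports.append(
            SiteIndexReport(
                site_id=site_id,
                cf=cf,
                cf_class={e: classify_cf(v) for e, v in cf.items()},
                pli=pli,
                pli_class=classify_pli(pli),
                peri=peri_values,
                peri_class={e: classify_peri(v) for e, v in peri_values.items()},
                eri=eri,
                eri_class=classify_eri(eri),
            )
        )
    return reports


def reports_to_frame(reports: list[SiteIndexReport]) -> pd.DataFrame:
    """Wide per-site table: CF_<el>, PERI_<el>, PLI, ERI and classes."""
    rows = []
    for r in reports:
        row: dict[str, object] = {"site_id": r.site_id}
        for e, v in r.cf.items():
            row[f"CF_{e}"] = v
        row["PLI"] = r.pli
        row["PLI_class"] = r.pli_class
        for e, v in r.peri.items():
            row[f"PERI_{e}"] = v
        row["ERI"] = r.eri
        row["ERI_class"] = r.eri_class
        rows.append(row)
    return pd.DataFrame(rows)


def reports_to_long_frame(reports: list[SiteIndexReport]) -> pd.DataFrame:
    """Long per-site-per-element table of CF and PERI with classes."""
    rows = []
    for r in reports:
        for e, v in r.cf.items():
            rows.append(
                {
                    "site_id": r.site_id,
                    "element": e,
                    "cf": v,
                    "cf_class": r.cf_class[e],
                    "peri": r.peri.get(e),
                    "peri_class": r.peri_class.get(e),
                }
            )
    return pd.DataFrame(rows)
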