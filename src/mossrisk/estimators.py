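"""scikit-learn estimator interface to the background/CF step.

`BackgroundEstimator` is the one genuinely fit/transform-shaped stage of
the analysis chain: fitting learns per-element geochemical backgrounds
from a reference survey; transforming divides any survey by them, yielding
contamination factors. It follows the sklearn contract (``get_params`` /
``set_params``, trailing-underscore fitted attributes, ``check_is_fitted``
semantics) and composes with sklearn pipelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .background import BackgroundConfig, estimate_background
from .survey import ConcentrationMatrix


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ConcentrationMatrix):
        return X.to_frame()
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class BackgroundEstimator(BaseEstimator, TransformerMixin):
    """Learn element backgrounds; transform surveys to contamination factors.

    Parameters
    ----------
    subset_fraction : float, default 0.10
        Fraction of sites (lowest rank sums) forming the background subset.
    grubbs_alpha : float, default 0.05
        Significance level of the iterative Grubbs outlier screen.
    n_boot : int, default 2000
        Bootstrap replicates for the upper confidence limit of the mean.
    conf_level : float, default 0.95
        Confidence level of the (two-sided) bootstrap interval.
    one_sided : bool, default False
        Use the one-sided 95th percentile instead of the 97.5th.
    random_state : int, default 0
        Seed for the bootstrap.

    Attributes
    ----------
    background_ : pandas.Series
        Per-element background concentration (mg/kg).
    subset_site_ids_ : list of str
        Sites forming the background subset.
    result_ : BackgroundResult
        Full procedure output (removed outliers, subset means).
    """

    def __init__(
        self,
        subset_fraction: float = 0.10,
        grubbs_alpha: float = 0.05,
        n_boot: int = 2000,
        conf_level: float = 0.95,
        one_sided: bool = False,
        random_state: int = 0,
    ) -> None:
        self.subset_fraction = subset_fraction
        self.grubbs_alpha = grubbs_alpha
        self.n_boot = n_boot
        self.conf_level = conf_level
        self.one_sided = one_sided
        self.random_state = random_state

    def fit(self, X, y=None) -> "BackgroundEstimator":
        """Estimate backgrounds from a reference survey.

        ``X`` may be a ConcentrationMatrix, a sites x elements DataFrame,
        or a plain positive array.
        """
        if isinstance(X, ConcentrationMatrix):
            matrix = X
        else:
            frame = _as_frame(X)
            from .survey import SiteMeta

            sites = [
                SiteMeta(str(idx), 0.0, 0.0, 0.0, "unknown") for idx in frame.index
            ]
            matrix = ConcentrationMatrix(
                sites, [str(c) for c in frame.columns], frame.to_numpy(dtype=float)
            )
        config = BackgroundConfig(
            subset_fraction=self.subset_fraction,
            grubbs_alpha=self.grubbs_alpha,
            n_boot=self.n_boot,
            conf_level=self.conf_level,
            one_sided=self.one_sided,
            seed=self.random_state,
        )
        self.result_ = estimate_background(matrix, config)
        self.background_ = pd.Series(dict(self.result_.table), name="background")
        self.subset_site_ids_ = list(self.result_.selected_site_ids)
        self.n_features_in_ = matrix.n_elements
        self.feature_names_in_ = np.asarray(matrix.elements, dtype=object)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Contamination factors: concentrations divided by backgrounds."""
        if not hasattr(self, "background_"):
            raise NotFittedError(
                "BackgroundEstimator is not fitted; call fit() first"
            )
        frame = _as_frame(X)
        if list(map(str, frame.columns)) != list(self.feature_names_in_):
            frame = frame.reindex(columns=list(self.feature_names_in_))
            if frame.isna().any().any():
                raise ValueError("transform input lacks fitted element columns")
        return frame / self.background_

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(
            [f"CF_{e}" for e in self.feature_names_in_], dtype=object
        )
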