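import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mossrisk.simulate import default_georgia_like_config, generate_survey
from mossrisk.survey import ConcentrationMatrix, SiteMeta

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values, elements=None, site_ids=None) -> ConcentrationMatrix:
    """Small survey from a plain array, with dummy metadata."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    elements = list(elements) if elements is not None else [f"E{j}" for j in range(m)]
    site_ids = list(site_ids) if site_ids is not None else [f"S{i}" for i in range(n)]
    sites = [
        SiteMeta(site_ids[i], 42.0, 44.0, 100.0, "Hypnum cupressiforme")
        for i in range(n)
    ]
    return ConcentrationMatrix(sites, elements, values)


@pytest.fixture(scope="session")
def georgia_survey():
    """One default synthetic survey realization (seed 1), shared per session."""
    matrix, truth = generate_survey(default_georgia_like_config(seed=1))
    return matrix, truth


@pytest.fixture
def tiny_survey():
    return make_matrix(
        [[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]],
        elements=["Al", "Pb"],
        site_ids=["A", "B", "C"],
    )
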