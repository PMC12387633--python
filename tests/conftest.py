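"""Shared fixtures: reduced-size and full-size synthetic studies.

The *small* study keeps the four-group, five-replicate design but shrinks
every block so cross-validation loops stay fast; the *default* study uses
the full block dimensions (1049 / 26 / 42 / 8800 variables) and is built
once per session.
"""

import numpy as np
import pytest

from mbmetab import StudyPreprocessor, fit_mbpls, generate_study
from mbmetab.synthetic import SyntheticConfig

SMALL_DIMS = {"X1": 60, "X2": 12, "X3": 16, "X4": 440}


def small_config(seed: int = 0, **kw) -> SyntheticConfig:
    kw.setdefault("block_dims", dict(SMALL_DIMS))
    return SyntheticConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config(seed=0))


@pytest.fixture(scope="session")
def small_model(small_study):
    blocks, design, _ = small_study
    pre, pb = StudyPreprocessor.fit(blocks)
    model = fit_mbpls(pb, design.response_matrix(), 4)
    return model, design, pre


@pytest.fixture(scope="session")
def default_study():
    """Full-size study (paper-scale block dimensions), seed 0."""
    return generate_study(SyntheticConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
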