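"""Shared fixtures: small hand-enumerable matrices and pair generators."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit

from surveyattrition.survey_data import ResponseMatrix
from surveyattrition.simulate import preset, simulate_survey


def make_rm(rows, labels=None) -> ResponseMatrix:
    rows = np.asarray(rows, dtype=np.int8)
    labels = labels or [f"item{q}" for q in range(1, rows.shape[1] + 1)]
    return ResponseMatrix([f"s{i}" for i in range(rows.shape[0])], labels, rows)


def pair_rm(y1, y2) -> ResponseMatrix:
    """Two-item pair preceded by an all-answered anchor item, as in a
    survey where every starter answered item 1."""
    y1 = np.asarray(y1, dtype=np.int8)
    y2 = np.asarray(y2, dtype=np.int8)
    ans = np.column_stack([np.ones(len(y1), dtype=np.int8), y1, y2])
    return make_rm(ans, labels=["anchor", "qa", "qb"])


def gen_pair(beta0, beta1, sigma, n, seed):
    """Draw a correlated binary pair from the random-intercept model."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    y1 = (rng.random(n) < expit(beta0 + u)).astype(np.int8)
    y2 = (rng.random(n) < expit(beta0 + beta1 + u)).astype(np.int8)
    return y1, y2


@pytest.fixture(scope="session")
def toy4() -> ResponseMatrix:
    """4 subjects x 3 items with one skip, one early dropout, 2 completers."""
    return make_rm([[1, 1, 1], [1, 1, 0], [1, 0, 1], [1, 0, 0]])


@pytest.fixture(scope="session")
def paper_like_sim():
    """One paper-like draw shared across tests (deterministic, seed 11)."""
    cfg = preset("paper_like", seed=11)
    rm, covs, truth = simulate_survey(cfg)
    return cfg, rm, covs, truth
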