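"""Shared fixtures: small expression/regulon tables and constructed posteriors."""

from __future__ import annotations

import numpy as np
import pytest

from tfactivity.inference import TFActivityPosterior
from tfactivity.io import ExpressionTimeCourse
from tfactivity.synthetic import TIME_GRID


@pytest.fixture
def toy_expr() -> ExpressionTimeCourse:
    """3 genes x (0, 20, 40) min with one missing cell."""
    values = np.array(
        [
            [0.0, 1.0, 2.0],
            [0.0, -1.0, np.nan],
            [0.0, 0.5, -0.2],
        ]
    )
    return ExpressionTimeCourse(("cydA", "cyoA", "ndh"), (0.0, 20.0, 40.0), values, "aerobic")


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)


def orthonormal_profiles(length: int = 7, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two centered, unit-norm, mutually orthogonal vectors."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=length)
    u -= u.mean()
    u /= np.linalg.norm(u)
    w = rng.normal(size=length)
    w -= w.mean()
    w -= (w @ u) * u
    w /= np.linalg.norm(w)
    return u, w


def draws_with_abs_rho(rhos: np.ndarray, length: int = 7, seed: int = 0):
    """Paired draw sets whose per-pair Pearson correlations are exactly ``rhos``.

    Condition-B draws are all the fixed profile u; condition-A draw i is
    ``r_i * u + sqrt(1 - r_i^2) * w`` with u, w centered orthonormal vectors,
    so pearson(a_i, b_j) = r_i for every pairing.
    """
    u, w = orthonormal_profiles(length, seed)
    rhos = np.asarray(rhos, dtype=float)
    a = rhos[:, None] * u + np.sqrt(1.0 - rhos**2)[:, None] * w
    b = np.tile(u, (len(rhos), 1))
    return a, b


def interval_rhos(center: float, half_width: float, n: int = 41) -> np.ndarray:
    """|rho| draw values whose central 95% percentile interval has exactly
    the requested half-width (for n=41, numpy's linear percentile lands on
    the 2nd and 40th order statistics)."""
    assert n == 41
    inner = np.linspace(center - half_width, center + half_width, n - 2)
    return np.sort(
        np.concatenate([[center - half_width - 0.01], inner, [center + half_width + 0.01]])
    )


def posterior_from_draws(draws: np.ndarray, tf_ids=("TF00",), timepoints=TIME_GRID):
    """Wrap raw draw arrays (n, M, T) into a TFActivityPosterior."""
    draws = np.asarray(draws, dtype=float)
    return TFActivityPosterior(
        tf_ids=tuple(tf_ids),
        timepoints_min=tuple(timepoints),
        mean=draws.mean(axis=0),
        lower=np.percentile(draws, 2.5, axis=0),
        upper=np.percentile(draws, 97.5, axis=0),
        draws=draws,
        draws_raw=draws,
        rhat=np.ones(draws.shape[1]),
    )
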