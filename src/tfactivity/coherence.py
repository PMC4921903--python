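"""Two-condition coherence comparison of TF activity profiles.

For each TF shared between two conditions the *profile difference* is
``d = 1 - |rho|`` where ``rho`` is the Pearson correlation between the two
posterior-mean activity profiles, and the *magnitude difference* is
``m = | ||a|| - ||b|| |`` with the Euclidean norm.  TFs similar in both
kinetics and amplitude sit near the origin of the (d, m) scatter; TFs in
the top-right corner differ in both.  95% intervals for d and m come from
paired independent posterior draws of the two conditions; a TF whose |rho|
interval has half-width greater than 0.15 is marked ``omitted`` (it is kept
in the table — omission affects plotting and reporting, not storage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import TFActivityPosterior

QUADRANTS = ("lower-left", "upper-left", "lower-right", "upper-right", "undefined")

#: Half-width of the |rho| 95% interval beyond which a TF is omitted.
OMISSION_HALF_WIDTH = 0.15


class CoherenceError(ValueError):
    pass


class ConstantProfileError(CoherenceError):
    """Pearson correlation undefined: a profile has zero variance."""

    reason = "constant_profile"


@dataclass(frozen=True)
class CoherencePoint:
    """One TF's position on the two-condition coherence plot."""

    tf_id: str
    profile_difference: float  # d = 1 - |rho|, NaN when undefined
    magnitude_difference: float  # m = | ||a|| - ||b|| |
    d_lo95: float
    d_hi95: float
    m_lo95: float
    m_hi95: float
    omitted: bool
    quadrant: str
    reason: str = ""


@dataclass(frozen=True)
class CoherenceConfig:
    """Thresholds and draw settings for building a coherence table.

    ``d_threshold`` splits the profile-difference axis (default: midpoint of
    [0, 1]); ``m_threshold`` splits the magnitude axis and defaults to the
    median magnitude difference across non-omitted TFs.  Boundary values go
    to the high side.
    """

    d_threshold: float = 0.5
    m_threshold: float | None = None
    n_draws: int | None = None
    seed: int = 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt(np.sum(da**2) * np.sum(db**2))
    if denom == 0.0:
        raise ConstantProfileError(
            "Pearson correlation undefined for a constant profile"
        )
    return float(np.sum(da * db) / denom)


def profile_difference(a: np.ndarray, b: np.ndarray) -> float:
    """d = 1 - |Pearson correlation| between two activity profiles.

    Requires equal length >= 3 and non-constant profiles; a constant profile
    raises :class:`ConstantProfileError` (reason code ``constant_profile``)
    rather than returning a silent number.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise CoherenceError(f"profile lengths differ: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise CoherenceError("profiles must have length >= 3")
    d = 1.0 - abs(_pearson(a, b))
    # guard against tiny negative round-off
    return float(min(max(d, 0.0), 1.0))


def magnitude_difference(a: np.ndarray, b: np.ndarray) -> float:
    """m = absolute difference of the Euclidean norms of the two profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise CoherenceError(f"profile lengths differ: {a.shape} vs {b.shape}")
    return float(abs(np.linalg.norm(a) - np.linalg.norm(b)))


def classify_quadrant(
    d: float, m: float, d_threshold: float = 0.5, m_threshold: float = 0.0
) -> str:
    """Quadrant of the coherence plot; boundaries go to the high side.

    lower-left: similar kinetics and amplitude (near the origin);
    upper-right: different in both.  Undefined d yields ``undefined``.
    """
    if not np.isfinite(d):
        return "undefined"
    right = d >= d_threshold
    upper = m >= m_threshold
    if right and upper:
        return "upper-right"
    if right:
        return "lower-right"
    if upper:
        return "upper-left"
    return "lower-left"


def _paired_draw_stats(
    draws_a: np.ndarray, draws_b: np.ndarray, n_draws: int | None, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair d and m over paired independent posterior draws.

    The two conditions are independent experiments, so pairing is arbitrary;
    one side is randomly permuted before pairing.  Pairs with a constant
    drawn profile are skipped.
    """
    rng = np.random.default_rng(seed)
    n = min(draws_a.shape[0], draws_b.shape[0])
    if n_draws is not None:
        n = min(n, n_draws)
    ia = rng.permutation(draws_a.shape[0])[:n]
    ib = rng.permutation(draws_b.shape[0])[:n]
    ds, ms = [], []
    for i, j in zip(ia, ib):
        a, b = draws_a[i], draws_b[j]
        try:
            ds.append(profile_difference(a, b))
        except ConstantProfileError:
            continue
        ms.append(magnitude_difference(a, b))
    return np.asarray(ds), np.asarray(ms)


def coherence_point(
    post_a: TFActivityPosterior,
    post_b: TFActivityPosterior,
    tf_id: str,
    n_draws: int | None = None,
    seed: int = 0,
    d_threshold: float = 0.5,
    m_threshold: float | None = None,
) -> CoherencePoint:
    """Coherence record for one TF shared by two condition posteriors.

    d and m are computed on the posterior-mean profiles; 95% intervals are
    central percentile intervals of per-pair d and m over paired draws.  The
    quadrant is assigned when ``m_threshold`` is given (otherwise left empty
    for :func:`coherence_table` to fill with its median rule).
    """
    if tuple(post_a.timepoints_min) != tuple(post_b.timepoints_min):
        raise CoherenceError(
            f"timepoint grids differ: {post_a.timepoints_min} vs {post_b.timepoints_min}"
        )
    ma = post_a.mean[post_a.tf_index(tf_id)]
    mb = post_b.mean[post_b.tf_index(tf_id)]
    m = magnitude_difference(ma, mb)
    try:
        d = profile_difference(ma, mb)
        reason = ""
    except ConstantProfileError as exc:
        d = float("nan")
        reason = exc.reason

    draws_a = post_a.draws[:, post_a.tf_index(tf_id), :]
    draws_b = post_b.draws[:, post_b.tf_index(tf_id), :]
    ds, ms = _paired_draw_stats(draws_a, draws_b, n_draws, seed)
    if ds.size:
        d_lo, d_hi = np.percentile(ds, [2.5, 97.5])
        m_lo, m_hi = np.percentile(ms, [2.5, 97.5])
    else:
        d_lo = d_hi = float("nan")
        m_lo, m_hi = np.percentile(
            [magnitude_difference(draws_a[i], draws_b[i])
             for i in range(min(draws_a.shape[0], draws_b.shape[0]))],
            [2.5, 97.5],
        )
    # the |rho| interval has the same half-width as the d = 1 - |rho| interval
    omitted = bool(np.isfinite(d_lo) and (d_hi - d_lo) / 2.0 > OMISSION_HALF_WIDTH)
    if not np.isfinite(d):
        quadrant = "undefined"
    elif m_threshold is None:
        quadrant = ""
    else:
        quadrant = classify_quadrant(d, m, d_threshold, m_threshold)
    return CoherencePoint(
        tf_id=tf_id,
        profile_difference=d,
        magnitude_difference=m,
        d_lo95=float(d_lo),
        d_hi95=float(d_hi),
        m_lo95=float(m_lo),
        m_hi95=float(m_hi),
        omitted=omitted,
        quadrant=quadrant,
        reason=reason,
    )


def coherence_table(
    post_a: TFActivityPosterior,
    post_b: TFActivityPosterior,
    config: CoherenceConfig = CoherenceConfig(),
) -> list[CoherencePoint]:
    """Coherence records for every TF shared by the two conditions.

    Omitted TFs are retained with ``omitted = true``.  When the config gives
    no magnitude threshold, the median magnitude difference across
    non-omitted TFs (with defined d) is used.
    """
    shared = sorted(set(post_a.tf_ids) & set(post_b.tf_ids))
    if not shared:
        raise CoherenceError("no TFs shared between the two posteriors")
    points = [
        coherence_point(
            post_a, post_b, tf, n_draws=config.n_draws, seed=config.seed,
            d_threshold=config.d_threshold, m_threshold=None,
        )
        for tf in shared
    ]
    m_threshold = config.m_threshold
    if m_threshold is None:
        usable = [
            p.magnitude_difference
            for p in points
            if not p.omitted and np.isfinite(p.profile_difference)
        ]
        m_threshold = float(np.median(usable)) if usable else 0.0
    out = []
    for p in points:
        quadrant = classify_quadrant(
            p.profile_difference, p.magnitude_difference, config.d_threshold, m_threshold
        )
        out.append(
            CoherencePoint(
                tf_id=p.tf_id,
                profile_difference=p.profile_difference,
                magnitude_difference=p.magnitude_difference,
                d_lo95=p.d_lo95,
                d_hi95=p.d_hi95,
                m_lo95=p.m_lo95,
                m_hi95=p.m_hi95,
                omitted=p.omitted,
                quadrant=quadrant,
                reason=p.reason,
            )
        )
    return out
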