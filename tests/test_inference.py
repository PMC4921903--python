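"""Connectivity building and the Gibbs sampler's statistical behaviour."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import ks_2samp

from tfactivity.inference import (
    InferenceError,
    ModelHyperparameters,
    activity_profile,
    build_connectivity,
    infer_tf_activities,
    infer_tf_activities_multi,
)
from tfactivity.io import ExpressionTimeCourse, RegulonNetwork
from tfactivity.synthetic import (
    TIME_GRID,
    ActivityShape,
    GeneratorConfig,
    generate_dataset,
)

GRID = tuple(TIME_GRID)


def quiet_infer(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return infer_tf_activities(*args, **kwargs)


class TestBuildConnectivity:
    def test_tf_without_surviving_targets_dropped_and_reported(self):
        net = RegulonNetwork({("TFa", "g1"): None, ("TFb", "absent"): None})
        expr = ExpressionTimeCourse(("g1",), (0.0, 5.0), np.zeros((1, 2)))
        conn = build_connectivity(net, expr)
        assert conn.tf_ids == ("TFa",)
        assert conn.dropped_tfs == ("TFb",)

    def test_row_sums_count_regulators(self):
        net = RegulonNetwork(
            {("TFa", "g1"): 1, ("TFa", "g2"): None, ("TFb", "g1"): -1}
        )
        expr = ExpressionTimeCourse(("g1", "g2"), (0.0, 5.0), np.zeros((2, 2)))
        conn = build_connectivity(net, expr)
        by_gene = dict(zip(conn.gene_ids, conn.X.sum(axis=1)))
        assert by_gene == {"g1": 2.0, "g2": 1.0}
        assert conn.signs[conn.gene_ids.index("g1"), conn.tf_ids.index("TFb")] == -1

    def test_empty_intersection_is_error(self):
        net = RegulonNetwork({("TFa", "gX"): None})
        expr = ExpressionTimeCourse(("g1",), (0.0, 5.0), np.zeros((1, 2)))
        with pytest.raises(InferenceError, match="no overlap"):
            build_connectivity(net, expr)


def single_target_instance(sigma=0.05):
    """One TF, one target, weight fixed at 1: the model reduces to smoothing."""
    profile = ActivityShape("transient_pulse", 2.0, 20.0).evaluate(np.asarray(GRID))
    expr = ExpressionTimeCourse(("g1",), GRID, profile[None, :], "A")
    net = RegulonNetwork({("TF00", "g1"): None})
    conn = build_connectivity(net, expr)
    return expr, conn, sigma


class TestSampler:
    def test_single_target_fixed_weight_recovers_profile(self):
        expr, conn, sigma = single_target_instance()
        hp = ModelHyperparameters(seed=5, n_samples=1000, n_burnin=200, n_chains=2)
        post = quiet_infer(
            expr, conn, hp, fix_b=np.ones_like(conn.X), fix_mu=np.zeros(1), fix_sigma=sigma
        )
        raw_mean = post.draws_raw.mean(axis=0)[0]
        assert np.allclose(raw_mean, expr.values[0], atol=0.15)

    def test_gene_row_permutation_leaves_posterior_unchanged(self):
        cfg = GeneratorConfig(n_genes=30, n_tfs=3, mean_regulon_size=6, seed=2)
        exprs, network, _ = generate_dataset(cfg)
        expr = exprs["A"]
        perm = np.random.default_rng(0).permutation(expr.n_genes)
        permuted = ExpressionTimeCourse(
            tuple(expr.gene_ids[i] for i in perm),
            expr.timepoints_min,
            expr.values[perm],
            expr.condition_label,
        )
        hp = ModelHyperparameters(seed=17, n_samples=200, n_burnin=100, n_chains=1)
        p1 = quiet_infer(expr, build_connectivity(network, expr), hp)
        p2 = quiet_infer(permuted, build_connectivity(network, permuted), hp)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.draws, p2.draws)

    def test_scale_rescaled_truth_gives_same_posterior_distribution(self):
        """Generator (b, c) -> (2b, c/2) leaves the data unchanged, and the
        gauge-fixed posterior must be statistically indistinguishable."""
        for alpha in (0.5, 2.0):
            base = GeneratorConfig(
                n_genes=40, n_tfs=2, mean_regulon_size=8, seed=31, sign_fraction=0.5,
                shape_pairs=(
                    (ActivityShape("transient_pulse", 2.0, 10.0),) * 2,
                    (ActivityShape("monotone_rise", 1.5),) * 2,
                ),
            )
            scaled = replace(
                base,
                weight_sd=base.weight_sd * alpha,
                shape_pairs=tuple(
                    (replace(a, amplitude=a.amplitude / alpha), replace(b, amplitude=b.amplitude / alpha))
                    for a, b in base.shape_pairs
                ),
            )
            e1, n1, _ = generate_dataset(base)
            e2, n2, _ = generate_dataset(scaled)
            assert np.allclose(e1["A"].values, e2["A"].values)
            hp1 = ModelHyperparameters(seed=71, n_samples=600, n_burnin=400, n_chains=1)
            hp2 = replace(hp1, seed=72)
            p1 = quiet_infer(e1["A"], build_connectivity(n1, e1["A"]), hp1)
            p2 = quiet_infer(e2["A"], build_connectivity(n2, e2["A"]), hp2)
            for m in range(2):
                stat = ks_2samp(
                    p1.draws[::5, m, :].ravel(), p2.draws[::5, m, :].ravel()
                ).statistic
                assert stat < 0.15, f"alpha={alpha}, TF {m}: KS={stat:.3f}"

    def test_interval_width_nondecreasing_in_noise(self):
        """Mean credible-interval width grows with the noise level."""
        widths = {0.1: [], 0.3: [], 1.0: []}
        for noise in widths:
            for seed in range(5):
                cfg = GeneratorConfig(
                    n_genes=40, n_tfs=3, mean_regulon_size=10, noise_sd=noise, seed=seed,
                )
                exprs, network, _ = generate_dataset(cfg)
                hp = ModelHyperparameters(seed=50 + seed, n_samples=600, n_burnin=300, n_chains=2)
                post = quiet_infer(exprs["A"], build_connectivity(network, exprs["A"]), hp)
                widths[noise].append(float(np.mean(post.upper - post.lower)))
        means = [np.mean(widths[n]) for n in (0.1, 0.3, 1.0)]
        assert means[0] <= means[1] <= means[2]

    def test_uninformed_tf_flagged_and_returned_at_prior(self):
        values = np.zeros((2, len(GRID)))
        values[1, :] = np.nan  # the only target of TFb is never observed
        values[0, :] = ActivityShape("monotone_rise", 1.0).evaluate(np.asarray(GRID))
        expr = ExpressionTimeCourse(("g1", "g2"), GRID, values)
        net = RegulonNetwork({("TFa", "g1"): None, ("TFb", "g2"): None})
        conn = build_connectivity(net, expr)
        hp = ModelHyperparameters(seed=3, n_samples=200, n_burnin=100, n_chains=1)
        post = quiet_infer(expr, conn, hp)
        assert post.flags == {"TFb": "uninformed"}
        prof = activity_profile(post, "TFb")
        assert (prof["flag"] == "uninformed").all()

    def test_unknown_tf_error_names_available(self):
        expr, conn, _ = single_target_instance()
        hp = ModelHyperparameters(seed=1, n_samples=100, n_burnin=50, n_chains=1)
        post = quiet_infer(expr, conn, hp)
        with pytest.raises(KeyError, match="TF00"):
            activity_profile(post, "nonexistent")

    def test_profile_export_matches_posterior_summaries(self):
        expr, conn, _ = single_target_instance()
        hp = ModelHyperparameters(seed=1, n_samples=150, n_burnin=50, n_chains=1)
        post = quiet_infer(expr, conn, hp)
        prof = activity_profile(post, "TF00")
        assert len(prof) == len(GRID)
        assert np.array_equal(prof["mean"].to_numpy(), post.mean[0])
        assert (prof["lo95"] <= prof["mean"]).all() and (prof["mean"] <= prof["hi95"]).all()


class TestJointInference:
    def test_joint_fit_returns_aligned_posteriors(self):
        cfg = GeneratorConfig(n_genes=30, n_tfs=2, mean_regulon_size=8, seed=8)
        exprs, network, _ = generate_dataset(cfg)
        conn = build_connectivity(network, exprs["A"])
        hp = ModelHyperparameters(seed=19, n_samples=200, n_burnin=100, n_chains=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            posts = infer_tf_activities_multi(exprs, conn, hp)
        assert set(posts) == {"A", "B"}
        assert posts["A"].joint and posts["B"].joint
        assert posts["A"].n_draws == posts["B"].n_draws == 200

    def test_mismatched_grids_rejected(self):
        e1 = ExpressionTimeCourse(("g1",), (0.0, 5.0), np.zeros((1, 2)))
        e2 = ExpressionTimeCourse(("g1",), (0.0, 10.0), np.zeros((1, 2)))
        net = RegulonNetwork({("TFa", "g1"): None})
        conn = build_connectivity(net, e1)
        with pytest.raises(InferenceError, match="grids"):
            infer_tf_activities_multi({"A": e1, "B": e2}, conn, ModelHyperparameters(seed=0))
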