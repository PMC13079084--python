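import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peatmix.mixing import (
    CombinedEstimate,
    EndMember,
    MixingProblem,
    MixtureObs,
    PosteriorSummary,
    SingularSystemError,
    ZeroAcceptanceError,
    combine_inverse_variance,
    consistency_check,
    run_monte_carlo,
    solve_exact,
)


def make_summary(mean, sd, source="peat", model=None):
    """A minimal hand-built posterior for combination/consistency tests."""
    return PosteriorSummary(
        source_names=(source,),
        samples=np.array([[mean]]),
        fractions_mean=np.array([mean]),
        fractions_sd=np.array([sd]),
        n_iter=1,
        n_accepted=1,
        acceptance_rate=1.0,
        model=model,
    )


class TestSolveExact:
    def test_two_source_closed_form(self):
        # (1.0 - 0.76) / (1.0 - 0.4) = 0.40
        f = solve_exact(np.array([[0.4], [1.0]]), np.array([0.76]))
        assert f == pytest.approx([0.40, 0.60], abs=1e-12)

    def test_mixture_at_vertex(self):
        S = np.array([[-28.0, 0.35], [-29.0, 1.02], [-9.8, 1.01]])
        f = solve_exact(S, S[0])
        assert f == pytest.approx([1.0, 0.0, 0.0], abs=1e-10)

    def test_three_source_construct_then_invert(self):
        S = np.array([[-28.0, 0.35], [-29.0, 1.02], [-9.8, 1.01]])
        truth = np.array([0.4, 0.5, 0.1])
        f = solve_exact(S, truth @ S)
        assert np.max(np.abs(f - truth)) < 1e-10

    def test_not_clamped_outside_simplex(self):
        f = solve_exact(np.array([[0.4], [1.0]]), np.array([1.2]))
        assert f[0] < 0 and f[1] > 1
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_collinear_sources_raise(self):
        S = np.array([[0.5, 1.0], [0.5, 1.0], [0.5, 1.0]])
        with pytest.raises(SingularSystemError, match="peat"):
            solve_exact(S, np.array([0.5, 1.0]), ["peat", "modern", "atmosphere"])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            solve_exact(np.array([[0.4, 1.0], [1.0, 2.0]]), np.array([0.76]))

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_oracle_equivalence_random_simplex(self, data):
        # construct a mixture from a known fraction vector, invert, recover
        k = data.draw(st.integers(min_value=2, max_value=4))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31)))
        raw = rng.dirichlet(np.ones(k))
        S = np.column_stack(
            [rng.uniform(-40, 0, size=k)] + [rng.uniform(0.2, 1.2, size=k)] * (k - 2)
        )
        # keep the system well conditioned so 1e-10 is meaningful
        A = np.vstack([S.T, np.ones(k)])
        if np.linalg.cond(A) > 1e6:
            return
        f = solve_exact(S, raw @ S)
        assert np.max(np.abs(f - raw)) < 1e-10


class TestProblemValidation:
    def test_equilibration_needs_three_sources(self):
        with pytest.raises(ValueError, match="3 sources"):
            MixingProblem(
                model="equilibration",
                sources=(
                    EndMember("peat", -28, 1, 0.35, 0.15),
                    EndMember("modern", -29, 1, 1.02, 0.02),
                ),
                mixture=MixtureObs(-25, 1, 0.76, 0.02),
            )

    def test_outgassing_needs_two_sources(self):
        with pytest.raises(ValueError, match="2 sources"):
            MixingProblem(
                model="outgassing",
                sources=(
                    EndMember("peat", -28, 1, 0.35, 0.15),
                    EndMember("modern", -29, 1, 1.02, 0.02),
                    EndMember("atmosphere", -9.8, 0.1, 1.01, 0.01),
                ),
                mixture=MixtureObs(-25, 1, 0.76, 0.02),
            )

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown model"):
            MixingProblem(
                model="diffusion",
                sources=(EndMember("a", 0, 0, 1, 0), EndMember("b", 1, 0, 2, 0)),
                mixture=MixtureObs(0.5, 0, 1.5, 0),
            )

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            EndMember("peat", -28, -1.0, 0.35, 0.15)

    def test_tracer_selection(self, equilibration_problem, outgassing_problem):
        assert equilibration_problem.tracers == ("d13c", "f14c")
        assert outgassing_problem.tracers == ("f14c",)


class TestMonteCarlo:
    def test_degenerate_normals_equal_exact(self, equilibration_problem):
        S = np.array([[-28.0, 0.35], [-29.0, 1.02], [-9.8, 1.01]])
        truth = np.array([0.4, 0.5, 0.1])
        mix = truth @ S
        prob = MixingProblem(
            model="equilibration",
            sources=tuple(
                EndMember(n, S[i, 0], 0.0, S[i, 1], 0.0)
                for i, n in enumerate(("peat", "modern", "atmosphere"))
            ),
            mixture=MixtureObs(mix[0], 0.0, mix[1], 0.0),
        )
        post = run_monte_carlo(prob, n_iter=500, seed=0)
        assert post.acceptance_rate == 1.0
        exact = solve_exact(S, mix)
        assert np.array_equal(post.fractions_mean, exact)
        assert np.array_equal(post.samples[0], post.samples[-1])

    def test_outgassing_affine_sd(self, outgassing_problem):
        # f_peat = (F_modern - F_mix) / 0.6 is affine in the only noisy draw,
        # so sd = 0.02 / 0.6; MC estimate must land within 3 MC s.e. of that
        n = 100_000
        post = run_monte_carlo(outgassing_problem, n_iter=n, seed=42)
        target = 0.02 / 0.6
        mc_se_of_sd = target / np.sqrt(2 * (n - 1))
        assert abs(post.sd("peat") - target) < 3 * mc_se_of_sd
        assert post.mean("peat") == pytest.approx(0.40, abs=3 * target / np.sqrt(n))

    def test_simplex_closure(self, equilibration_problem):
        post = run_monte_carlo(equilibration_problem, n_iter=5_000, seed=7)
        sums = post.samples.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-12
        assert post.samples.min() >= 0.0 and post.samples.max() <= 1.0

    def test_seed_determinism(self, equilibration_problem):
        a = run_monte_carlo(equilibration_problem, n_iter=3_000, seed=11)
        b = run_monte_carlo(equilibration_problem, n_iter=3_000, seed=11)
        assert a.n_accepted == b.n_accepted
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.fractions_mean, b.fractions_mean)

    def test_rejection_refilter_matches(self, equilibration_problem):
        post = run_monte_carlo(
            equilibration_problem, n_iter=5_000, seed=3, keep_raw=True
        )
        raw = post.raw_fractions
        assert raw.shape == (5_000, 3)
        ok = np.isfinite(raw).all(axis=1) & (raw >= 0).all(axis=1) & (raw <= 1).all(axis=1)
        assert int(ok.sum()) == post.n_accepted

    def test_zero_acceptance_raises(self):
        prob = MixingProblem(
            model="outgassing",
            sources=(
                EndMember("peat", -28, 0, 0.4, 0.0),
                EndMember("modern", -29, 0, 1.0, 0.0),
            ),
            mixture=MixtureObs(-25, 0, 2.0, 0.01),
        )
        with pytest.raises(ZeroAcceptanceError, match="acceptance_rate 0"):
            run_monte_carlo(prob, n_iter=1_000, seed=5)

    def test_zero_acceptance_names_constraint(self):
        prob = MixingProblem(
            model="outgassing",
            sources=(
                EndMember("peat", -28, 0, 0.4, 0.0),
                EndMember("modern", -29, 0, 1.0, 0.0),
            ),
            mixture=MixtureObs(-25, 0, 2.0, 0.01),
        )
        with pytest.raises(ZeroAcceptanceError, match=r"f\[peat\] < 0"):
            run_monte_carlo(prob, n_iter=200, seed=5)

    def test_n_iter_validation(self, outgassing_problem):
        with pytest.raises(ValueError):
            run_monte_carlo(outgassing_problem, n_iter=0)

    def test_mc_converges_to_exact_as_sds_shrink(self):
        exact = solve_exact(np.array([[0.4], [1.0]]), np.array([0.76]))[0]
        gaps = []
        for sd in (0.05, 0.005, 0.0005):
            prob = MixingProblem(
                model="outgassing",
                sources=(
                    EndMember("peat", -28, 0, 0.4, sd),
                    EndMember("modern", -29, 0, 1.0, sd),
                ),
                mixture=MixtureObs(-25, 0, 0.76, sd),
            )
            post = run_monte_carlo(prob, n_iter=20_000, seed=9)
            gaps.append(abs(post.mean("peat") - exact))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 1e-3

    def test_unseeded_runs_work(self, outgassing_problem):
        post = run_monte_carlo(outgassing_problem, n_iter=100)
        assert post.n_accepted > 0


class TestCombine:
    def test_agreement_fixed_point(self):
        c = combine_inverse_variance(make_summary(0.4, 0.2), make_summary(0.4, 0.01))
        assert c.mean == pytest.approx(0.4)

    def test_equal_weights(self):
        c = combine_inverse_variance(make_summary(0.3, 0.1), make_summary(0.5, 0.1))
        assert c.mean == pytest.approx(0.40)
        assert c.sd == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)

    def test_unequal_weights(self):
        c = combine_inverse_variance(make_summary(0.3, 0.05), make_summary(0.5, 0.10))
        assert c.mean == pytest.approx(0.34)
        assert c.sd == pytest.approx(np.sqrt(1 / (400 + 100)), rel=1e-12)
        assert c.weights == {"a": pytest.approx(400.0), "b": pytest.approx(100.0)}

    def test_pooled_posterior_mode_wider_under_disagreement(self):
        a, b = make_summary(0.3, 0.1), make_summary(0.5, 0.1)
        pooled = combine_inverse_variance(a, b, mode="pooled_posterior")
        standard = combine_inverse_variance(a, b)
        assert pooled.mean == pytest.approx(standard.mean)
        assert pooled.sd > standard.sd

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            combine_inverse_variance(make_summary(0.3, 0.0), make_summary(0.5, 0.1))

    def test_missing_source_rejected(self):
        with pytest.raises(KeyError):
            combine_inverse_variance(
                make_summary(0.3, 0.1, source="modern"), make_summary(0.5, 0.1)
            )

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="mode"):
            combine_inverse_variance(
                make_summary(0.3, 0.1), make_summary(0.5, 0.1), mode="median"
            )

    @given(
        st.floats(0.01, 0.99), st.floats(0.001, 0.5),
        st.floats(0.01, 0.99), st.floats(0.001, 0.5),
    )
    def test_mean_bounded_by_components(self, ma, sa, mb, sb):
        c = combine_inverse_variance(make_summary(ma, sa), make_summary(mb, sb))
        assert min(ma, mb) - 1e-12 <= c.mean <= max(ma, mb) + 1e-12

    def test_shrinking_sd_pulls_mean_monotonically(self):
        means = [
            combine_inverse_variance(make_summary(0.3, s), make_summary(0.5, 0.1)).mean
            for s in (0.2, 0.1, 0.05, 0.01)
        ]
        assert means == sorted(means, reverse=True)
        assert means[-1] == pytest.approx(0.3, abs=0.01)


class TestConsistency:
    def test_identical_summaries(self):
        ok, _ = consistency_check(make_summary(0.4, 0.1), make_summary(0.4, 0.1))
        assert ok

    def test_headline_style_values_consistent(self):
        # 0.39 +/- 0.08 vs 0.40 +/- 0.06: |diff| = 0.01 < sqrt(0.08^2+0.06^2) = 0.1
        ok, report = consistency_check(make_summary(0.39, 0.08), make_summary(0.40, 0.06))
        assert ok
        assert report["abs_difference"] == pytest.approx(0.01)
        assert report["threshold"] == pytest.approx(0.1)

    def test_far_apart_inconsistent(self):
        ok, _ = consistency_check(make_summary(0.2, 0.01), make_summary(0.5, 0.01))
        assert not ok

    def test_k_scales_threshold(self):
        a, b = make_summary(0.2, 0.05), make_summary(0.4, 0.05)
        assert not consistency_check(a, b, k=1.0)[0]
        assert consistency_check(a, b, k=3.0)[0]


def test_combined_estimate_serializable():
    c = combine_inverse_variance(
        make_summary(0.3, 0.1, model="equilibration"),
        make_summary(0.5, 0.1, model="outgassing"),
    )
    d = c.as_dict()
    assert set(d) == {"source", "mean", "sd", "weights", "mode"}
    assert set(d["weights"]) == {"equilibration", "outgassing"}
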