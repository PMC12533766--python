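"""Joint posterior structure: prior/likelihood additivity, the non-centered
identity, gradient exactness and small-scale fitting contracts."""

import numpy as np
import pandas as pd
import pytest

from lbaspeech import (DesignSpec, HierarchicalLBA, SamplerConfig,
                       default_population, fit_model, joint_log_posterior,
                       pack_data, simulate_dataset)
from lbaspeech import convergence_diagnostics, load_fit_state, \
    posterior_predictive_simulate, save_fit_state
from lbaspeech import transforms
from lbaspeech.lba import N_PARAMS, T0_FLOOR


@pytest.fixture(scope="module")
def small_table(default_pop):
    spec = DesignSpec(n_per_group=2, trials_per_mode=3, seed=31)
    return simulate_dataset(spec, default_pop, seed=32)


@pytest.fixture(scope="module")
def small_fit(small_table):
    cfg = SamplerConfig(chains=2, warmup_iterations=150,
                        sampling_iterations=150, seed=9)
    return fit_model(small_table, cfg)


def _model_and_point(table, seed=0, **kw):
    model = HierarchicalLBA(pack_data(table, **kw))
    rng = np.random.default_rng(seed)
    x = model.initial_point(rng, 0.3)
    return model, x


class TestJointLogPosterior:
    def test_empty_table_reduces_to_prior(self, small_table):
        empty = small_table.iloc[0:0]
        model, _ = _model_and_point(empty, groups=("AH", "CI"), t_max=10.0)
        rng = np.random.default_rng(1)
        x = model.initial_point(rng, 0.3)
        lp = model.logp(x)
        assert np.isfinite(lp)
        # prior structure: shifting one group mean changes the log density
        # exactly as a Normal(0, 5) would
        x2 = x.copy()
        x2[0] += 1.0
        expected_delta = (-0.5 * x2[0] ** 2 + 0.5 * x[0] ** 2) / 25.0
        assert model.logp(x2) - lp == pytest.approx(expected_delta, abs=1e-9)

    def test_duplicating_rows_doubles_likelihood_term(self, small_table):
        t_max = float(small_table["rt_seconds"].max())
        single, x = _model_and_point(small_table, t_max=t_max)
        x[single.off_z:] = 0.0  # zero offsets so the z prior term vanishes
        doubled = pd.concat([small_table, small_table], ignore_index=True)
        dbl_model = HierarchicalLBA(pack_data(doubled, t_max=t_max))
        empty = small_table.iloc[0:0]
        prior_model = HierarchicalLBA(
            pack_data(empty, groups=single.data.groups, t_max=t_max))
        # hyper blocks lead the packed vector, so the prior model reads the
        # same mu/tau/corr/lambda values from the truncated vector
        lp1 = single.logp(x)
        lp2 = dbl_model.logp(x)
        lp0 = prior_model.logp(x[: prior_model.dim])
        assert lp2 - lp0 == pytest.approx(2 * (lp1 - lp0), rel=1e-9)

    def test_finite_for_rt_below_nondecision_time(self, small_table):
        table = small_table.copy()
        table.loc[table.index[0], "rt_seconds"] = 0.05  # below any valid t0
        lp = joint_log_posterior(
            table, _model_and_point(table)[1])
        assert np.isfinite(lp)

    def test_gradient_matches_finite_differences(self, small_table):
        model, _ = _model_and_point(small_table)
        rng = np.random.default_rng(3)
        for _ in range(3):
            x = model.initial_point(rng, 0.4)
            lp, g = model.logp_and_grad(x)
            for i in rng.choice(model.dim, 6, replace=False):
                eps = 1e-6
                xp, xm = x.copy(), x.copy()
                xp[i] += eps
                xm[i] -= eps
                fd = (model.logp(xp) - model.logp(xm)) / (2 * eps)
                assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-4)


class TestNonCenteredIdentity:
    def test_reconstruction_to_1e10(self, small_table):
        model, x = _model_and_point(small_table, seed=7)
        p = model.unpack(x)
        tau = np.exp(p["log_tau"])
        L = transforms.corr_cholesky(p["y"])
        manual = p["mu"][model.data.group_of] + (p["z"] @ L.T) * tau
        stored = model.individual_constrained(x)
        back = transforms.unconstrain_matrix(stored)
        assert np.allclose(back, manual, atol=1e-10)

    def test_constraints_hold_for_every_draw(self, small_fit):
        ind = small_fit.individual_draws(thin=10)
        A, b, t0 = ind[..., 14], ind[..., 15], ind[..., 16]
        assert np.all(A > 0)
        assert np.all(b > A)
        assert np.all(t0 >= T0_FLOOR)


class TestFitContract:
    def test_draw_counts_match_config(self, small_fit):
        assert small_fit.n_chains == 2
        assert small_fit.n_iterations == 150
        assert small_fit.n_draws == 300

    def test_group_level_t0_respects_floor(self, small_fit):
        gl = small_fit.group_level()
        for g in ("AH", "CI"):
            assert np.all(gl[f"t0[{g}]"] >= T0_FLOOR)
            assert np.all(gl[f"b[{g}]"] > gl[f"A[{g}]"])
        assert np.all((gl["lambda"] > 0) & (gl["lambda"] < 1))

    def test_deterministic_given_seed(self, small_table):
        cfg = SamplerConfig(chains=1, warmup_iterations=40,
                            sampling_iterations=30, seed=77)
        a = fit_model(small_table, cfg)
        b = fit_model(small_table, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_save_load_roundtrip(self, small_fit, small_table, tmp_path):
        path = tmp_path / "state.npz"
        save_fit_state(small_fit, path)
        back = load_fit_state(path, small_table)
        assert np.array_equal(back.draws, small_fit.draws)
        assert back.groups == small_fit.groups
        assert back.config.seed == small_fit.config.seed
        # hash check trips on modified data
        tampered = small_table.copy()
        tampered.loc[tampered.index[0], "rt_seconds"] += 0.1
        with pytest.raises(ValueError):
            load_fit_state(path, tampered)

    def test_long_dataframe_roundtrip(self, small_fit, tmp_path):
        from lbaspeech.io import read_draws_table, write_draws_table

        df = small_fit.to_long_dataframe()
        path = tmp_path / "draws.csv"
        write_draws_table(df, path, {"seed": 9})
        back = read_draws_table(path)
        assert len(back) == len(df)
        merged = df.merge(back, on=["chain", "iteration", "parameter"],
                          suffixes=("_a", "_b"))
        assert np.allclose(merged["value_a"], merged["value_b"])


class TestConvergenceDiagnostics:
    def test_constant_chains_flagged_degenerate(self):
        arr = np.ones((4, 500))
        diag = convergence_diagnostics({"p": arr})
        assert bool(diag["degenerate"].iloc[0])

    def test_null_normal_draws_near_one(self):
        rng = np.random.default_rng(5)
        arr = rng.standard_normal((4, 2000))
        diag = convergence_diagnostics({"p": arr})
        assert 0.999 <= float(diag["rhat"].iloc[0]) <= 1.005

    def test_shifted_chain_detected(self):
        rng = np.random.default_rng(6)
        arr = rng.standard_normal((4, 2000))
        arr[0] += 5.0
        diag = convergence_diagnostics({"p": arr})
        assert float(diag["rhat"].iloc[0]) > 1.2
        assert bool(diag["flagged"].iloc[0])

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            convergence_diagnostics({"p": np.zeros((1, 100))})


class TestPosteriorPredictive:
    def test_zero_datasets_empty_list(self, small_fit, small_table):
        assert posterior_predictive_simulate(small_fit, small_table, 0, 1) == []

    def test_participant_mismatch_rejected(self, small_fit, small_table):
        bad = small_table.copy()
        bad["participant_id"] = bad["participant_id"] + 100
        with pytest.raises(ValueError):
            posterior_predictive_simulate(small_fit, bad, 1, 1)

    def test_replicates_share_design(self, small_fit, small_table):
        reps = posterior_predictive_simulate(small_fit, small_table, 3, seed=8)
        assert len(reps) == 3
        for r in reps:
            assert len(r) == len(small_table)
            assert set(r["response"]).issubset(
                {"correct", "semantic", "phonetic", "neither"})
            assert (r["rt_seconds"] > 0).all()


def test_prior_predictive_yields_valid_tables(default_pop):
    """Hyperparameters drawn from the priors still simulate clean data."""
    from lbaspeech import TruePopulation

    rng = np.random.default_rng(10)
    for _ in range(3):
        mu = rng.normal(0, 1.0, (2, N_PARAMS))  # central prior mass
        tau = np.abs(rng.standard_t(3, N_PARAMS)) * 0.3
        pop = TruePopulation(
            group_means={"AH": mu[0], "CI": mu[1]},
            scales=np.minimum(tau, 2.0),
            correlation=np.eye(N_PARAMS),
            contaminant_prop=float(rng.beta(1, 19)),
        )
        spec = DesignSpec(n_per_group=2, trials_per_mode=2, seed=11)
        table = simulate_dataset(spec, pop, seed=int(rng.integers(2**31)))
        assert not table.isna().any().any()
        assert (table["rt_seconds"] > 0).all()
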