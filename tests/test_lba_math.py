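"""Closed-form LBA mathematics against analytic limits, quadrature and
Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from lbaspeech import (IndividualParams, TrialContext, accumulator_cdf,
                       accumulator_pdf, effective_drifts,
                       race_defective_log_density, trial_log_likelihood)
from lbaspeech.lba import LOG_FLOOR
from lbaspeech.synthetic import simulate_trial


def _mc_first_passage_times(A, b, v, s, n, seed):
    """Independent simulation oracle for a single accumulator."""
    rng = np.random.default_rng(seed)
    start = rng.uniform(0, A, n)
    drift = rng.normal(v, s, n)
    t = np.full(n, np.inf)
    pos = drift > 0
    t[pos] = (b - start[pos]) / drift[pos]
    return t


class TestAccumulatorCdf:
    def test_zero_at_origin(self):
        assert accumulator_cdf(0.0, 0.5, 1.0, 1.0) == 0.0
        assert accumulator_cdf(1e-12, 0.5, 1.0, 1.0) < 1e-9

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            accumulator_cdf(-0.1, 0.5, 1.0, 1.0)

    @pytest.mark.parametrize("v,s", [(1.0, 1.0), (-0.5, 1.0), (2.0, 0.7)])
    def test_limit_is_probability_of_positive_drift(self, v, s):
        # the defective mass equals Phi(v / s)
        assert accumulator_cdf(1e6, 0.5, 1.0, v, s) == pytest.approx(
            norm.cdf(v / s), abs=1e-6
        )

    def test_monotone_nondecreasing(self):
        t = np.linspace(0, 10, 500)
        vals = accumulator_cdf(t, 0.5, 1.0, 1.0)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_against_monte_carlo(self):
        # empirical CDF from 10^6 simulated accumulators
        times = _mc_first_passage_times(0.5, 1.0, 1.0, 1.0, 10**6, 99)
        for t in (0.3, 1.0, 3.0):
            emp = float(np.mean(times <= t))
            assert accumulator_cdf(t, 0.5, 1.0, 1.0) == pytest.approx(emp, abs=0.002)


class TestAccumulatorPdf:
    def test_zero_at_and_below_origin(self):
        assert accumulator_pdf(0.0, 0.5, 1.0, 1.0) == 0.0
        assert accumulator_pdf(-1.0, 0.5, 1.0, 1.0) == 0.0

    def test_matches_cdf_derivative(self):
        # central difference of F at t = 1 agrees with f within 1e-5
        h = 1e-5
        fd = (accumulator_cdf(1 + h, 0.5, 1, 1) - accumulator_cdf(1 - h, 0.5, 1, 1)) / (2 * h)
        assert accumulator_pdf(1.0, 0.5, 1, 1) == pytest.approx(fd, abs=1e-5)

    def test_cdf_pdf_consistency_on_grid(self):
        h = 1e-6
        for t in np.linspace(0.2, 5.0, 25):
            fd = (accumulator_cdf(t + h, 0.8, 1.3, 0.6)
                  - accumulator_cdf(t - h, 0.8, 1.3, 0.6)) / (2 * h)
            assert accumulator_pdf(t, 0.8, 1.3, 0.6) == pytest.approx(fd, abs=1e-5)

    @pytest.mark.parametrize("v,s", [(1.0, 1.0), (0.2, 1.0), (-0.8, 1.0)])
    def test_integrates_to_defective_mass(self, v, s):
        total, err = quad(lambda t: accumulator_pdf(t, 0.5, 1.0, v, s), 0, np.inf,
                          limit=200)
        assert total == pytest.approx(norm.cdf(v / s), abs=1e-4)


class TestRaceDensity:
    def _mass(self, r, drifts, A=0.8, b=1.3):
        val, _ = quad(
            lambda t: np.exp(race_defective_log_density(t, r, drifts, A, b)),
            0, np.inf, limit=200,
        )
        return val

    def test_symmetric_accumulators_share_mass_equally(self):
        drifts = np.array([1.0, 1.0, 1.0, 1.0])
        masses = [self._mass(r, drifts) for r in range(4)]
        assert np.allclose(masses, masses[0], atol=1e-6)
        # total mass = P(at least one accumulator finishes)
        p_any = 1 - np.prod(norm.cdf(-drifts))
        assert sum(masses) == pytest.approx(p_any, abs=1e-4)

    def test_masses_sum_below_one(self):
        drifts = np.array([0.5, -0.5, 0.2, -1.0])
        total = sum(self._mass(r, drifts) for r in range(4))
        assert total <= 1.0 + 1e-9

    def test_dominant_accumulator_takes_all(self):
        drifts = np.array([30.0, 0.5, 0.5, 0.5])
        assert self._mass(0, drifts) == pytest.approx(1.0, abs=1e-3)
        assert self._mass(1, drifts) < 1e-3

    def test_nonpositive_time_hits_log_floor(self):
        out = race_defective_log_density(0.0, 0, np.ones(4), 0.8, 1.3)
        assert out == LOG_FLOOR

    def test_matches_simulator_choice_proportions(self, example_params):
        # likelihood-vs-simulator cross-validation at n = 1e5 (audio mode)
        drifts = example_params.v[0]
        masses = np.array([self._mass(r, drifts, example_params.A, example_params.b)
                           for r in range(4)])
        probs = masses / masses.sum()
        rng = np.random.default_rng(7)
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            r, _t = simulate_trial(example_params, "audio", 1, False, False,
                                   0.0, 10.0, rng)
            counts[r] += 1
        assert np.all(np.abs(counts / n - probs) < 0.01)


class TestSimulatorLikelihoodAgreement:
    """Simulated (response, RT) histograms match the normalized density."""

    @pytest.mark.parametrize("drifts,lam", [
        ((2.0, 0.5, 0.4, 0.3), 0.0),
        ((1.2, 0.8, 0.8, -0.5), 0.0),   # negative error drift
        ((2.5, 0.6, 0.6, 0.6), 0.05),   # with contaminant
    ])
    def test_rt_distribution_ks(self, drifts, lam):
        v = np.tile(np.asarray(drifts, float), (3, 1))
        params = IndividualParams(v=v, boost_kw2=0.0, boost_kw3=0.0,
                                  A=0.8, b=1.3, t0=0.3)
        t_max = 10.0
        rng = np.random.default_rng(13)
        n = 100_000
        resp = np.empty(n, dtype=int)
        rts = np.empty(n)
        for i in range(n):
            resp[i], rts[i] = simulate_trial(params, "audio", 1, False, False,
                                             lam, t_max, rng)
        grid = np.linspace(1e-4, t_max, 2500)
        for r in range(4):
            sel = rts[resp == r]
            if len(sel) < 2000:
                continue
            dens = (1 - lam) * np.exp(race_defective_log_density(
                np.maximum(grid - params.t0, 1e-12), r, v[0],
                params.A, params.b)) * (grid > params.t0) \
                + lam / (4 * t_max)
            cdf = np.concatenate([[0], np.cumsum(
                (dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
            cdf /= cdf[-1]
            emp = np.searchsorted(np.sort(sel), grid, side="right") / len(sel)
            ks = np.max(np.abs(emp - cdf))
            # 0.01 at full n; smaller cells get their 99% KS null quantile
            bound = max(0.01, 1.63 / np.sqrt(len(sel)))
            assert ks < bound, f"response {r}: KS={ks:.4f} (n={len(sel)})"


class TestEffectiveDrifts:
    def test_boost_applied_on_keyword_two_after_correct(self, example_params):
        ctx = TrialContext(mode="audio", keyword_index=2, kw1_correct=True)
        d = effective_drifts(example_params, ctx)
        assert d[0] == pytest.approx(2.0 + 0.4)
        assert np.allclose(d[1:], example_params.v[0][1:])

    def test_no_boost_on_first_keyword(self, example_params):
        ctx = TrialContext(mode="video", keyword_index=1)
        assert np.allclose(effective_drifts(example_params, ctx),
                           example_params.v[1])

    def test_keyword_three_requires_both_previous_correct(self, example_params):
        partial = TrialContext(mode="audio", keyword_index=3,
                               kw1_correct=True, kw2_correct=False)
        assert effective_drifts(example_params, partial)[0] == pytest.approx(2.0)
        full = TrialContext(mode="audio", keyword_index=3,
                            kw1_correct=True, kw2_correct=True)
        assert effective_drifts(example_params, full)[0] == pytest.approx(2.6)


class TestTrialLogLikelihood:
    def test_pure_contaminant_is_uniform(self, example_params):
        ctx = TrialContext(mode="audio", keyword_index=1)
        expected = np.log(1 / (4 * 10.0))
        for rt, r in [(0.1, 0), (5.0, 3), (9.9, 2)]:
            assert trial_log_likelihood(rt, r, example_params, ctx, 1.0, 10.0) \
                == pytest.approx(expected)

    def test_response_below_t0_carried_by_contaminant(self, example_params):
        ctx = TrialContext(mode="audio", keyword_index=1)
        val = trial_log_likelihood(0.2, 0, example_params, ctx, 0.02, 10.0)
        assert val == pytest.approx(np.log(0.02 / (4 * 10.0)))

    def test_no_contaminant_reduces_to_race(self, example_params):
        ctx = TrialContext(mode="captions", keyword_index=1)
        rt = 1.1
        race = race_defective_log_density(
            rt - example_params.t0, 0, example_params.v[2],
            example_params.A, example_params.b)
        assert trial_log_likelihood(rt, 0, example_params, ctx, 0.0, 10.0) \
            == pytest.approx(float(race))

    def test_renormalized_race_divides_by_finish_probability(self, example_params):
        from lbaspeech import race_finish_probability

        ctx = TrialContext(mode="audio", keyword_index=1)
        drifts = example_params.v[0]
        p_any = race_finish_probability(drifts)
        # closed form: 1 - prod Phi(-v_j)
        from scipy.stats import norm as _norm
        assert p_any == pytest.approx(1 - np.prod(_norm.cdf(-drifts)), rel=1e-12)
        rt = 1.1
        plain = trial_log_likelihood(rt, 0, example_params, ctx, 0.0, 10.0)
        renorm = trial_log_likelihood(rt, 0, example_params, ctx, 0.0, 10.0,
                                      renormalize=True)
        assert renorm == pytest.approx(plain - np.log(p_any), abs=1e-10)
        # the kernel's renormalized per-row likelihood agrees with the
        # scalar reference path
        from lbaspeech import pack_data
        from lbaspeech.model import HierarchicalLBA

        import pandas as pd
        row = pd.DataFrame({
            "participant_id": [0], "group": ["AH"], "trial_id": [1],
            "mode": ["audio"], "keyword_index": [1], "response": ["correct"],
            "rt_seconds": [rt], "kw1_correct": [False], "kw2_correct": [False],
        })
        model = HierarchicalLBA(pack_data(row, t_max=10.0))
        x = np.zeros(model.dim)
        theta_unc = np.concatenate([
            example_params.v.ravel(),
            [example_params.boost_kw2, example_params.boost_kw3,
             np.log(example_params.A),
             np.log(example_params.b - example_params.A),
             np.log(example_params.t0 - 0.150)],
        ])
        x[:17] = theta_unc  # single AH group mean; z = 0, tau arbitrary
        lam = model.lam(x)
        mix = (1 - lam) * np.exp(renorm) + lam / 40.0
        assert model.per_row_loglik(x)[0] == pytest.approx(np.log(mix), rel=1e-9)

    def test_rt_beyond_t_max_rejected(self, example_params):
        ctx = TrialContext(mode="audio", keyword_index=1)
        with pytest.raises(ValueError):
            trial_log_likelihood(11.0, 0, example_params, ctx, 0.02, 10.0)
        with pytest.raises(ValueError):
            trial_log_likelihood(1.0, 0, example_params, ctx, 1.5, 10.0)


def test_dataset_loglik_invariant_to_row_order(tiny_table, default_pop):
    from lbaspeech import dataset_log_likelihood, draw_individual_parameters

    pids = tiny_table["participant_id"].unique()
    params = dict(zip(
        pids, draw_individual_parameters(default_pop, "AH", len(pids), 5)))
    a = dataset_log_likelihood(tiny_table, params, 0.02, 12.0)
    shuffled = tiny_table.sample(frac=1.0, random_state=1)
    b = dataset_log_likelihood(shuffled, params, 0.02, 12.0)
    assert a == pytest.approx(b, rel=1e-12)
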