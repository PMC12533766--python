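"""Synthetic cohort generator: design balance, determinism, generative
distributional properties and serial-dependency context bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from lbaspeech import (DesignSpec, TruePopulation, build_design,
                       default_population, draw_individual_parameters,
                       simulate_dataset, simulate_preferences, simulate_trial)
from lbaspeech.lba import IDX_A, IDX_T0, N_PARAMS
from lbaspeech.synthetic import InvalidDesignError


class TestBuildDesign:
    def test_full_design_has_18000_keyword_slots(self):
        design = build_design(DesignSpec())
        assert len(design) == 18_000
        assert design["participant_id"].nunique() == 100

    def test_sixty_trials_twenty_per_mode(self):
        design = build_design(DesignSpec(seed=5))
        per_trial = design.groupby("participant_id")["trial_id"].nunique()
        assert (per_trial == 60).all()
        mode_counts = (design.drop_duplicates(["participant_id", "trial_id"])
                       .groupby(["participant_id", "mode"]).size())
        assert (mode_counts == 20).all()

    def test_identity_case(self):
        spec = DesignSpec(n_per_group=1, groups=("AH",), modes=("audio",),
                          trials_per_mode=1, keywords_per_trial=1)
        assert len(build_design(spec)) == 1

    def test_same_seed_is_byte_identical(self):
        a = build_design(DesignSpec(seed=7))
        b = build_design(DesignSpec(seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = build_design(DesignSpec(seed=8))
        assert not a["mode"].equals(c["mode"])

    def test_invalid_counts_rejected(self):
        with pytest.raises(InvalidDesignError):
            DesignSpec(n_per_group=0)
        with pytest.raises(InvalidDesignError):
            DesignSpec(trials_per_mode=-1)


class TestDrawIndividualParameters:
    def test_zero_scales_collapse_to_group_mean(self, default_pop):
        pop = TruePopulation(
            group_means=default_pop.group_means,
            scales=np.zeros(N_PARAMS),
            correlation=np.eye(N_PARAMS),
        )
        draws = draw_individual_parameters(pop, "CI", 5, seed=1)
        expected = pop.group_means["CI"]
        for p in draws:
            vec = p.to_vector()
            assert np.allclose(vec[:14], expected[:14])
            assert vec[IDX_A] == pytest.approx(np.exp(expected[IDX_A]))

    def test_sample_mean_within_3_se(self, default_pop):
        n = 5000
        draws = draw_individual_parameters(default_pop, "AH", n, seed=2)
        # drifts/boosts are identity-mapped, so compare on those components
        mat = np.stack([p.to_vector() for p in draws])[:, :14]
        mean = mat.mean(axis=0)
        se = default_pop.scales[:14] / np.sqrt(n)
        assert np.all(np.abs(mean - default_pop.group_means["AH"][:14]) <= 3 * se + 1e-12)

    def test_identity_correlation_yields_uncorrelated_parameters(self, default_pop):
        n = 10_000
        draws = draw_individual_parameters(default_pop, "CI", n, seed=3)
        mat = np.stack([p.to_vector() for p in draws])
        unc = np.column_stack([mat[:, 0], mat[:, 5], np.log(mat[:, IDX_A]),
                               np.log(mat[:, IDX_T0] - 0.150)])
        r = np.corrcoef(unc, rowvar=False)
        off = r[np.triu_indices_from(r, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_non_positive_definite_correlation_raises(self, default_pop):
        corr = np.full((N_PARAMS, N_PARAMS), 0.99)
        np.fill_diagonal(corr, 1.0)
        corr[0, 1] = corr[1, 0] = -0.99  # inconsistent -> not PD
        pop = TruePopulation(group_means=default_pop.group_means,
                             scales=default_pop.scales, correlation=corr)
        with pytest.raises(np.linalg.LinAlgError):
            draw_individual_parameters(pop, "AH", 3, seed=1)


class TestSimulateTrial:
    def test_pure_contaminant_uniform_response_and_rt(self, example_params):
        from scipy.stats import chisquare, kstest

        rng = np.random.default_rng(11)
        n = 10_000
        resp = np.empty(n, int)
        rts = np.empty(n)
        for i in range(n):
            resp[i], rts[i] = simulate_trial(example_params, "audio", 1,
                                             False, False, 1.0, 10.0, rng)
        counts = np.bincount(resp, minlength=4)
        assert chisquare(counts).pvalue > 0.001
        assert kstest(rts, "uniform", args=(0, 10.0)).pvalue > 0.001

    def test_no_contaminant_rt_above_t0(self, example_params):
        rng = np.random.default_rng(12)
        for _ in range(500):
            _, rt = simulate_trial(example_params, "video", 1, False, False,
                                   0.0, 10.0, rng)
            assert rt > example_params.t0

    def test_equal_drifts_symmetric_choice(self):
        from lbaspeech import IndividualParams

        params = IndividualParams(v=np.full((3, 4), 1.5), boost_kw2=0.0,
                                  boost_kw3=0.0, A=0.8, b=1.3, t0=0.3)
        rng = np.random.default_rng(13)
        n = 100_000
        counts = np.zeros(4)
        for _ in range(n):
            r, _ = simulate_trial(params, "audio", 1, False, False, 0.0, 10.0, rng)
            counts[r] += 1
        assert np.all(np.abs(counts / n - 0.25) < 0.01)


class TestSimulateDataset:
    def test_default_spec_gives_18000_rows(self, default_pop):
        spec = DesignSpec(seed=21)
        table = simulate_dataset(spec, default_pop, seed=22)
        assert len(table) == 18_000

    def test_determinism(self, tiny_spec, default_pop):
        a = simulate_dataset(tiny_spec, default_pop, seed=5)
        b = simulate_dataset(tiny_spec, default_pop, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_context_flags_consistent(self, default_pop):
        spec = DesignSpec(n_per_group=4, trials_per_mode=5, seed=6)
        table = simulate_dataset(spec, default_pop, seed=7)
        for (_, _), trial in table.groupby(["participant_id", "trial_id"]):
            trial = trial.sort_values("keyword_index")
            r = trial["response"].tolist()
            assert not trial.iloc[0]["kw1_correct"]
            assert bool(trial.iloc[1]["kw1_correct"]) == (r[0] == "correct")
            assert bool(trial.iloc[2]["kw1_correct"]) == (r[0] == "correct")
            assert bool(trial.iloc[2]["kw2_correct"]) == (r[1] == "correct")

    def test_large_boost_raises_keyword2_accuracy(self, default_pop):
        base = default_pop.group_means["CI"].copy()
        boosted = base.copy()
        boosted[12] = 6.0  # huge keyword-2 boost
        pop = TruePopulation(
            group_means={"AH": default_pop.group_means["AH"], "CI": boosted},
            scales=np.zeros(N_PARAMS), correlation=np.eye(N_PARAMS),
            contaminant_prop=0.0,
        )
        spec = DesignSpec(n_per_group=30, trials_per_mode=10,
                          groups=("AH", "CI"), seed=8)
        table = simulate_dataset(spec, pop, seed=9)
        ci = table[table.group == "CI"]
        kw1_acc = ci[ci.keyword_index == 1]["response"].eq("correct").mean()
        kw2 = ci[(ci.keyword_index == 2) & ci.kw1_correct]
        assert kw2["response"].eq("correct").mean() >= kw1_acc

    def test_zero_boost_no_serial_dependency(self, default_pop):
        from scipy.stats import fisher_exact

        means = {g: m.copy() for g, m in default_pop.group_means.items()}
        for g in means:
            means[g][12] = means[g][13] = 0.0
        pop = TruePopulation(group_means=means, scales=np.zeros(N_PARAMS),
                             correlation=np.eye(N_PARAMS), contaminant_prop=0.0)
        spec = DesignSpec(n_per_group=25, trials_per_mode=10, seed=10)
        table = simulate_dataset(spec, pop, seed=11)
        kw2 = table[table.keyword_index == 2]
        tab = pd.crosstab(kw2["kw1_correct"], kw2["response"].eq("correct"))
        _, p = fisher_exact(tab.to_numpy())
        assert p > 0.001  # no association between context and accuracy


class TestSimulatePreferences:
    def test_expected_captions_count(self):
        probs = {("CI", "A"): (0.02, 0.06, 0.92)}
        means = []
        for seed in range(200):
            c = simulate_preferences(probs, 50, seed=seed)
            means.append(c[c["mode"] == "captions"]["count"].iloc[0])
        assert np.mean(means) == pytest.approx(46.0, abs=0.5)

    def test_degenerate_probability(self):
        c = simulate_preferences({("AH", "A"): (1.0, 0.0, 0.0)}, 50, seed=0)
        assert c.set_index("mode")["count"].to_dict() == {
            "audio": 50, "video": 0, "captions": 0}

    def test_totals_conserved(self):
        from lbaspeech import study_preference_probs

        c = simulate_preferences(study_preference_probs(), 50, seed=4)
        sums = c.groupby(["group", "conversation"])["count"].sum()
        assert (sums == 50).all()

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            simulate_preferences({("AH", "A"): (0.5, 0.2, 0.2)}, 50, seed=0)
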