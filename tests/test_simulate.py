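import numpy as np
import pytest
from scipy import stats

from membandit import (
    AgentParams,
    CohortSpec,
    GenerativeParams,
    RewardWalkConfig,
    build_schedule,
    expected_ldi,
    generate_cohort,
    generate_reward_walk,
    kendall_tau_b,
    sequence_log_likelihood,
    simulate_agent,
    simulate_learning_phase,
    simulate_mst,
)
from membandit.mst import compute_ldi


class TestLearningPhase:
    def test_uniform_policy_chooses_each_deck_equally(self):
        sched = build_schedule(1, seed=0, n_learning_trials=9990,
                               n_probe_phase_choice_trials=0,
                               n_old_probes=0, n_novel_probes=0)
        walk = generate_reward_walk(RewardWalkConfig(), sched, seed=1)
        gp = GenerativeParams(agent=AgentParams(beta_rl=0, beta_sample=0, beta_p=0))
        ds = simulate_learning_phase(gp, walk, sched, seed=2)
        counts = np.bincount(ds.learning_arrays()[0], minlength=3)
        n = counts.sum()
        se = np.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < 3 * se)

    def test_greedy_rl_agent_prefers_best_deck_in_stable_blocks(self):
        """A high-beta RL agent tracks the 60%-center deck on a majority of
        trials within stable rotation blocks (zero-noise walk; majority in
        expectation over 50 seeds, since binary rewards keep single blocks
        noisy)."""
        picked_by_block: dict[int, list] = {}
        wins = 0
        total = 0
        for seed in range(50):
            sched = build_schedule(1, seed=seed)
            walk = generate_reward_walk(
                RewardWalkConfig(noise_sd=0.0), sched, seed=seed + 1
            )
            gp = GenerativeParams(
                agent=AgentParams(alpha_rl=0.5, beta_rl=20.0,
                                  beta_sample=0.0, beta_p=0.0)
            )
            ds = simulate_learning_phase(gp, walk, sched, seed=seed + 2)
            choices, _ = ds.learning_arrays()
            # examine the second half of each stable block, after learning
            for start in range(40, 180, 30):
                block = slice(start + 15, start + 30)
                best = np.argmax(walk.target_center[:, start + 15])
                picked = (choices[block] == best).mean()
                picked_by_block.setdefault(start, []).append(picked)
                total += 1
                wins += picked > 0.5
        # majority of single blocks track the best deck ...
        assert wins / total > 0.6
        # ... and every block position does so in expectation
        for start, vals in picked_by_block.items():
            assert np.mean(vals) > 0.5

    def test_seed_determinism(self, value_guided_params, walk_v1, schedule_v1):
        a = simulate_agent(value_guided_params, walk_v1, schedule_v1, seed=5)
        b = simulate_agent(value_guided_params, walk_v1, schedule_v1, seed=5)
        assert a.trials.equals(b.trials)


class TestProbePhase:
    def test_structure_counts(self, dataset_v1):
        assert len(dataset_v1.learning_trials()) == 180
        assert len(dataset_v1.phase2_choice_trials()) == 120
        probes = dataset_v1.probe_events()
        assert len(probes) == 60
        assert (probes["probe_novel"] == 0).sum() == 50
        assert (probes["probe_novel"] == 1).sum() == 10
        dataset_v1.validate()

    def test_perfect_probe_recognition(self, walk_v1, schedule_v1):
        gp = GenerativeParams(
            agent=AgentParams(beta_rl=3.0), probe_recognition_accuracy=1.0
        )
        ds = simulate_agent(gp, walk_v1, schedule_v1, seed=9)
        probes = ds.probe_events()
        assert (probes.loc[probes["probe_novel"] == 0, "probe_response"] == "old").all()
        assert (probes.loc[probes["probe_novel"] == 1, "probe_response"] == "new").all()

    def test_null_bias_leaves_post_probe_choices_unbiased(self):
        """With zero probe-bias weights, the post-probe choice distribution
        matches the non-post-probe distribution (chi-square over 200 agents
        with independent schedules and walks)."""
        gp = GenerativeParams(agent=AgentParams(beta_rl=4.0, beta_sample=2.0))
        post = np.zeros(3)
        other = np.zeros(3)
        for seed in range(200):
            sched = build_schedule(1, seed=3000 + seed)
            walk = generate_reward_walk(RewardWalkConfig(), sched, seed=4000 + seed)
            ds = simulate_agent(gp, walk, sched, seed=1000 + seed)
            decks = ds.phase2_choice_trials()["deck"].to_numpy()
            mask = sched.post_probe_map() >= 0
            post += np.bincount(decks[mask], minlength=3)
            other += np.bincount(decks[~mask], minlength=3)
        table = np.vstack([post, other])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_item_bias_shifts_choices_toward_probed_deck(self, walk_v1, schedule_v1):
        gp0 = GenerativeParams(agent=AgentParams())
        gp1 = GenerativeParams(agent=AgentParams(), b_item=2.0)
        post_probe = schedule_v1.post_probe_map()
        match0 = match1 = n0 = n1 = 0
        for seed in range(60):
            for gp, acc in ((gp0, "0"), (gp1, "1")):
                ds = simulate_agent(gp, walk_v1, schedule_v1, seed=500 + seed)
                learning = ds.learning_trials().reset_index(drop=True)
                probes = ds.probe_events().reset_index(drop=True)
                decks = ds.phase2_choice_trials()["deck"].to_numpy()
                for j, k in enumerate(post_probe):
                    if k < 0 or probes.loc[k, "probe_novel"] == 1:
                        continue
                    probed_deck = learning.loc[probes.loc[k, "probe_ref"], "deck"]
                    hit = decks[j] == probed_deck
                    if acc == "0":
                        match0 += hit
                        n0 += 1
                    else:
                        match1 += hit
                        n1 += 1
        assert match1 / n1 > match0 / n0 + 0.05


class TestMST:
    def test_counts_and_thirds(self):
        m = simulate_mst(0.5, seed=0)
        assert m.n_study_items == 128
        assert m.n_test_items == 192
        assert set(m.condition_counts()) == {64}

    def test_precision_one_ldi_near_model_maximum(self):
        m = simulate_mst(1.0, seed=1)
        summary = compute_ldi(m)
        se = np.sqrt(0.8 * 0.2 / 64) + np.sqrt(0.1 * 0.9 / 64)
        assert abs(summary.ldi - expected_ldi(1.0)) < 3 * se

    def test_expected_ldi_zero_when_lure_equals_foil_rate(self):
        assert expected_ldi(0.0) == pytest.approx(0.0)

    def test_determinism(self):
        a = simulate_mst(0.7, seed=3)
        b = simulate_mst(0.7, seed=3)
        assert a.responses.equals(b.responses)

    def test_ldi_monotone_in_precision(self):
        """Realized LDI increases along a precision grid (large n)."""
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        ldis = [
            compute_ldi(simulate_mst(p, seed=11, n_test=3000)).ldi for p in grid
        ]
        assert all(b > a for a, b in zip(ldis, ldis[1:]))


class TestCohort:
    def test_empty_cohort(self):
        bundle = generate_cohort(CohortSpec(n=0, master_seed=1))
        assert bundle.datasets == [] and bundle.mst == []
        assert len(bundle.covariates) == 0

    def test_reproducible_from_master_seed(self):
        a = generate_cohort(CohortSpec(n=3, master_seed=7))
        b = generate_cohort(CohortSpec(n=3, master_seed=7))
        assert a.covariates.equals(b.covariates)
        for x, y in zip(a.datasets, b.datasets):
            assert x.trials.equals(y.trials)

    def test_precision_predicts_ldi(self):
        bundle = generate_cohort(CohortSpec(n=100, master_seed=13))
        ldi = [compute_ldi(m).ldi for m in bundle.mst]
        r = kendall_tau_b(bundle.covariates["precision"], ldi)
        assert r.tau_b > 0 and r.p < 0.05

    def test_covariate_directions_by_construction(self):
        bundle = generate_cohort(CohortSpec(n=200, master_seed=17))
        cov = bundle.covariates
        assert kendall_tau_b(cov["age"], cov["beta_rl"]).tau_b < 0
        assert kendall_tau_b(cov["age"], cov["beta_p"]).tau_b > 0
        assert kendall_tau_b(cov["precision"], cov["beta_sample"]).tau_b > 0

    def test_generative_likelihood_consistency(self):
        """Data is more likely under its generating parameters than under
        +/-50% perturbations (sign test over 50 agents)."""
        bundle = generate_cohort(CohortSpec(n=50, master_seed=19, b_item=0, b_ctx=0))
        rng = np.random.default_rng(23)
        better = 0
        for ds, (_, row) in zip(bundle.datasets, bundle.covariates.iterrows()):
            true = AgentParams(
                alpha_rl=row["alpha_rl"], alpha_sample=row["alpha_sample"],
                beta_rl=row["beta_rl"], beta_sample=row["beta_sample"],
                beta_p=row["beta_p"],
            )
            factor = 1.5 if rng.random() < 0.5 else 0.5
            pert = AgentParams(
                alpha_rl=min(1.0, true.alpha_rl * factor),
                alpha_sample=min(1.0, true.alpha_sample * factor),
                beta_rl=min(20.0, true.beta_rl * factor),
                beta_sample=min(20.0, true.beta_sample * factor),
                beta_p=max(-3.0, min(3.0, true.beta_p * factor)),
            )
            if sequence_log_likelihood(ds, true) > sequence_log_likelihood(ds, pert):
                better += 1
        # one-sided binomial: generating params win far more often than not
        assert stats.binomtest(better, 50, alternative="greater").pvalue < 0.01
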