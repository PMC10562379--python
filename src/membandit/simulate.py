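"""Synthetic-data generation: hybrid agents, MST responses, cohorts.

The generator is the study-conditions counterpart of the analysis code:
agents choose by the same hybrid policy the fitting stage assumes
(expectation-form sampler values), probe trials bias the following
choice additively in logit space (mirroring the linear form the intrusion
regression estimates), and the cohort layer wires age and a latent memory
precision into the generative parameters with the qualitative directions
the lifespan analyses probe (higher precision -> more memory sampling;
older age -> weaker RL influence, stronger perseveration, lower
precision).  Ground-truth parameters are retained so recovery can be
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .data import CHOICE_COLUMNS, ChoiceDataset, MSTResponseSet
from .hybrid import AgentParams, HybridState
from .regression import ec_table, gist_ec_table
from .task import (
    RewardSeries,
    RewardWalkConfig,
    TaskSchedule,
    assign_lure_opposed_walks,
    build_schedule,
    generate_reward_walk,
)

__all__ = [
    "GenerativeParams",
    "CohortSpec",
    "CohortBundle",
    "simulate_learning_phase",
    "simulate_probe_phase",
    "simulate_agent",
    "simulate_mst",
    "expected_ldi",
    "generate_cohort",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Agent parameters plus generative-only probe-bias weights.

    ``b_item`` scales the post-probe logit bonus for the probed trial's
    deck (doubled when that trial was rewarded, mirroring the EI + ER
    regressors); ``b_ctx`` scales the probed room's evoked context reward;
    ``b_gist`` scales the category-level (room + same-category foil) EC,
    meaningful only for experiment variant 2.
    ``probe_recognition_accuracy`` drives old/new probe responses.
    """

    agent: AgentParams = field(default_factory=AgentParams)
    b_item: float = 0.0
    b_ctx: float = 0.0
    b_gist: float = 0.0
    probe_recognition_accuracy: float = 0.9

    def __post_init__(self) -> None:
        for name in ("b_item", "b_ctx", "b_gist"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.probe_recognition_accuracy <= 1.0:
            raise ValueError("probe_recognition_accuracy must lie in [0, 1]")


def _empty_trials() -> dict[str, list]:
    return {c: [] for c in CHOICE_COLUMNS}


def _append_choice(rows, phase, event, choice_index, room, context, deck, reward):
    rows["phase"].append(phase)
    rows["event"].append(event)
    rows["kind"].append("choice")
    rows["choice_index"].append(choice_index)
    rows["room"].append(room)
    rows["context"].append(context)
    rows["deck"].append(deck)
    rows["reward"].append(reward)
    rows["probe_ref"].append(-1)
    rows["probe_novel"].append(-1)
    rows["probe_response"].append("")


def simulate_learning_phase(
    params: GenerativeParams,
    series: RewardSeries,
    schedule: TaskSchedule,
    seed: int,
    *,
    state: HybridState | None = None,
) -> ChoiceDataset:
    """Simulate the Phase-1 choice trials of one agent.

    Per trial the hybrid policy is evaluated, a deck drawn, and the reward
    drawn Bernoulli(payout/100); both learners then update.
    """
    rng = np.random.default_rng(seed)
    st = state if state is not None else HybridState(params.agent)
    rows = _empty_trials()
    for t in range(schedule.n_learning_trials):
        room = schedule.room_of_trial(t)
        p = st.probabilities()
        deck = int(rng.choice(3, p=p))
        reward = int(rng.random() < series.payout_prob[deck, t] / 100.0)
        st.update(deck, reward)
        _append_choice(
            rows, 1, t, t, room, int(schedule.context_ids[room]), deck, reward
        )
    ds = ChoiceDataset(
        trials=pd.DataFrame(rows),
        experiment_variant=schedule.experiment_variant,
        room_length=schedule.room_length,
    )
    return ds


def simulate_probe_phase(
    params: GenerativeParams,
    learning_data: ChoiceDataset,
    series: RewardSeries,
    schedule: TaskSchedule,
    seed: int,
    *,
    state: HybridState | None = None,
) -> ChoiceDataset:
    """Simulate Phase 2 and return the full (Phase 1 + 2) dataset.

    If ``state`` is omitted the learner state is rebuilt by replaying the
    learning-phase choices.  On the choice trial immediately after an old
    probe, deck logits gain ``b_item * (EI + ER)`` terms for the probed
    deck, ``b_ctx * EC`` of the probed room, and (variant 2)
    ``b_gist * EC`` pooled over the room's category pair.
    """
    rng = np.random.default_rng(seed)
    if state is None:
        state = HybridState(params.agent)
        choices, rewards = learning_data.learning_arrays()
        for c, r in zip(choices, rewards):
            if c >= 0:
                state.update(int(c), int(r))

    learning = learning_data.learning_trials().reset_index(drop=True)
    ec = ec_table(learning_data)
    gist = (
        gist_ec_table(learning_data, schedule)
        if schedule.experiment_variant == 2 and params.b_gist != 0.0
        else None
    )

    is_probe = schedule.phase2_event_kind()
    rows = _empty_trials()
    choice_idx = schedule.n_learning_trials
    probe_k = 0
    pending_bias: np.ndarray | None = None
    for ev in range(schedule.n_phase2_events):
        if is_probe[ev]:
            ref = int(schedule.probe_items[probe_k])
            novel = int(ref < 0)
            if novel:
                resp = "new" if rng.random() < params.probe_recognition_accuracy else "old"
                pending_bias = None
            else:
                resp = "old" if rng.random() < params.probe_recognition_accuracy else "new"
                probe_deck = int(learning.loc[ref, "deck"])
                probe_rew = int(learning.loc[ref, "reward"]) if probe_deck >= 0 else 0
                probe_room = int(learning.loc[ref, "room"])
                bias = np.zeros(3)
                if probe_deck >= 0:
                    bias[probe_deck] += params.b_item * (1.0 + probe_rew)
                bias += params.b_ctx * ec[probe_room]
                if gist is not None:
                    bias += params.b_gist * gist[probe_room]
                pending_bias = bias
            rows["phase"].append(2)
            rows["event"].append(ev)
            rows["kind"].append("probe")
            rows["choice_index"].append(-1)
            rows["room"].append(-1)
            rows["context"].append(-1)
            rows["deck"].append(-1)
            rows["reward"].append(-1)
            rows["probe_ref"].append(ref if not novel else -1)
            rows["probe_novel"].append(novel)
            rows["probe_response"].append(resp)
            probe_k += 1
        else:
            p = state.probabilities(bias=pending_bias)
            pending_bias = None
            deck = int(rng.choice(3, p=p))
            reward = int(rng.random() < series.payout_prob[deck, choice_idx] / 100.0)
            state.update(deck, reward)
            _append_choice(rows, 2, ev, choice_idx, -1, -1, deck, reward)
            choice_idx += 1

    full = pd.concat(
        [learning_data.trials, pd.DataFrame(rows)], ignore_index=True
    )
    ds = ChoiceDataset(
        trials=full,
        agent_id=learning_data.agent_id,
        experiment_variant=schedule.experiment_variant,
        room_length=schedule.room_length,
    )
    ds.validate()
    return ds


def simulate_agent(
    params: GenerativeParams,
    series: RewardSeries,
    schedule: TaskSchedule,
    seed: int,
) -> ChoiceDataset:
    """Simulate both phases with a single carried-over learner state."""
    state = HybridState(params.agent)
    learning = simulate_learning_phase(params, series, schedule, seed, state=state)
    return simulate_probe_phase(
        params, learning, series, schedule, seed + 1, state=state
    )


# --- MST response model ---------------------------------------------------
# Three-state confusion model with a single precision parameter in [0, 1]
# and fixed guessing rates:
#   foil:       p(similar) = 0.10, p(old) = 0.10, p(new) = 0.80
#   lure:       p(similar) = 0.10 + 0.70 * precision; the remainder splits
#               3:1 between "old" (lure mistaken for its studied original)
#               and "new"
#   repetition: p(old) = 0.55 + 0.40 * precision; remainder splits evenly
# Expected LDI = p(sim|lure) - p(sim|foil) = 0.70 * precision.
_FOIL_P = (0.10, 0.10, 0.80)  # (old, similar, new)


def expected_ldi(precision: float) -> float:
    """Closed-form expected lure discrimination index of the generator."""
    return 0.70 * precision


def _mst_probs(condition: str, precision: float) -> tuple[float, float, float]:
    if condition == "foil":
        return _FOIL_P
    if condition == "lure":
        p_sim = 0.10 + 0.70 * precision
        rest = 1.0 - p_sim
        return (0.75 * rest, p_sim, 0.25 * rest)
    if condition == "repetition":
        p_old = 0.55 + 0.40 * precision
        rest = 1.0 - p_old
        return (p_old, 0.5 * rest, 0.5 * rest)
    raise ValueError(f"unknown MST condition {condition!r}")


def simulate_mst(
    precision: float,
    seed: int,
    *,
    n_study: int = 128,
    n_test: int = 192,
    agent_id: str = "agent",
) -> MSTResponseSet:
    """Simulate test-phase responses; equal thirds per condition."""
    if not 0.0 <= precision <= 1.0:
        raise ValueError(f"precision={precision} outside [0, 1]")
    if n_test % 3 != 0:
        raise ValueError("n_test must be divisible by 3")
    rng = np.random.default_rng(seed)
    per = n_test // 3
    conditions = np.repeat(MSTResponseSet.CONDITIONS, per)
    responses = []
    for cond in conditions:
        p = _mst_probs(cond, precision)
        responses.append(MSTResponseSet.RESPONSES[rng.choice(3, p=p)])
    order = rng.permutation(n_test)
    df = pd.DataFrame(
        {"condition": conditions[order], "response": np.array(responses)[order]}
    )
    return MSTResponseSet(responses=df, agent_id=agent_id, n_study_items=n_study)


# --- cohort ---------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Lifespan cohort description.

    Ages are uniform integers over ``age_range``.  A latent memory
    precision declines linearly with age plus noise; generative parameters
    encode the qualitative directions the analyses assume: ``beta_sample``
    increases with precision, ``beta_rl`` decreases and ``beta_p``
    increases with age.
    """

    n: int = 100
    experiment_variant: int = 1
    master_seed: int = 0
    age_range: tuple[int, int] = (18, 77)
    b_item: float = 0.5
    b_ctx: float = 1.0
    b_gist: float = 0.0
    probe_recognition_accuracy: float = 0.9
    n_walks: int = 4  # pre-generated payoff series shared across agents

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be nonnegative")
        if self.experiment_variant not in (1, 2):
            raise ValueError("experiment_variant must be 1 or 2")
        if not 18 <= self.age_range[0] <= self.age_range[1] <= 77:
            raise ValueError("age_range must lie within [18, 77]")


@dataclass
class CohortBundle:
    """Everything one synthetic cohort produces."""

    spec: CohortSpec
    schedule: TaskSchedule
    series_pool: list[RewardSeries]
    datasets: list[ChoiceDataset]
    mst: list[MSTResponseSet]
    covariates: pd.DataFrame  # agent_id, age, precision, true params, walk


def _sample_generative_params(age: int, precision: float, rng: np.random.Generator,
                              spec: CohortSpec) -> GenerativeParams:
    a = age - 18
    beta_sample = float(np.clip(1.5 + 7.0 * precision + rng.normal(0, 0.8), 0, 20))
    beta_rl = float(np.clip(9.0 - 0.08 * a + rng.normal(0, 1.0), 0, 20))
    beta_p = float(np.clip(-0.7 + 0.022 * a + rng.normal(0, 0.3), -3, 3))
    agent = AgentParams(
        alpha_rl=float(rng.uniform(0.2, 0.8)),
        alpha_sample=float(rng.uniform(0.3, 0.9)),
        beta_rl=beta_rl,
        beta_sample=beta_sample,
        beta_p=beta_p,
    )
    return GenerativeParams(
        agent=agent,
        b_item=spec.b_item,
        b_ctx=spec.b_ctx,
        b_gist=spec.b_gist,
        probe_recognition_accuracy=spec.probe_recognition_accuracy,
    )


def generate_cohort(
    spec: CohortSpec,
    walk_config: RewardWalkConfig | None = None,
) -> CohortBundle:
    """Generate a full synthetic cohort, reproducible from the master seed."""
    spec.validate()
    rng = np.random.default_rng(spec.master_seed)
    schedule = build_schedule(
        spec.experiment_variant, seed=int(rng.integers(2**31))
    )
    cfg = walk_config if walk_config is not None else RewardWalkConfig()
    series_pool = []
    for _ in range(max(spec.n_walks, 1)):
        s = generate_reward_walk(cfg, schedule, seed=int(rng.integers(2**31)))
        if spec.experiment_variant == 2:
            s = assign_lure_opposed_walks(s, schedule)
        series_pool.append(s)

    datasets: list[ChoiceDataset] = []
    msts: list[MSTResponseSet] = []
    cov_rows = []
    for i in range(spec.n):
        agent_id = f"agent{i:04d}"
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        precision = float(
            np.clip(0.95 - 0.0085 * (age - 18) + rng.normal(0, 0.12), 0.05, 0.98)
        )
        gp = _sample_generative_params(age, precision, rng, spec)
        walk_idx = int(rng.integers(len(series_pool)))
        ds = simulate_agent(
            gp, series_pool[walk_idx], schedule, seed=int(rng.integers(2**31))
        )
        ds.agent_id = agent_id
        mst = simulate_mst(
            precision, seed=int(rng.integers(2**31)), agent_id=agent_id
        )
        datasets.append(ds)
        msts.append(mst)
        cov_rows.append(
            {
                "agent_id": agent_id,
                "age": age,
                "precision": precision,
                "walk": walk_idx,
                "alpha_rl": gp.agent.alpha_rl,
                "alpha_sample": gp.agent.alpha_sample,
                "beta_rl": gp.agent.beta_rl,
                "beta_sample": gp.agent.beta_sample,
                "beta_p": gp.agent.beta_p,
                "b_item": gp.b_item,
                "b_ctx": gp.b_ctx,
                "b_gist": gp.b_gist,
            }
        )
    covariates = pd.DataFrame(
        cov_rows,
        columns=[
            "agent_id", "age", "precision", "walk",
            "alpha_rl", "alpha_sample", "beta_rl", "beta_sample", "beta_p",
            "b_item", "b_ctx", "b_gist",
        ],
    )
    return CohortBundle(
        spec=spec,
        schedule=schedule,
        series_pool=series_pool,
        datasets=datasets,
        mst=msts,
        covariates=covariates,
    )
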