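import numpy as np
import pytest

from membandit import (
    AgentParams,
    GenerativeParams,
    RewardWalkConfig,
    build_schedule,
    generate_reward_walk,
    simulate_agent,
)


@pytest.fixture(scope="session")
def schedule_v1():
    return build_schedule(1, seed=11)


@pytest.fixture(scope="session")
def schedule_v2():
    return build_schedule(2, seed=12)


@pytest.fixture(scope="session")
def walk_v1(schedule_v1):
    return generate_reward_walk(RewardWalkConfig(), schedule_v1, seed=21)


@pytest.fixture(scope="session")
def walk_v2(schedule_v2):
    return generate_reward_walk(RewardWalkConfig(), schedule_v2, seed=22)


@pytest.fixture(scope="session")
def value_guided_params():
    return GenerativeParams(
        agent=AgentParams(
            alpha_rl=0.4, alpha_sample=0.6, beta_rl=6.0, beta_sample=4.0, beta_p=0.3
        ),
        b_item=0.5,
        b_ctx=1.0,
    )


@pytest.fixture(scope="session")
def dataset_v1(value_guided_params, walk_v1, schedule_v1):
    return simulate_agent(value_guided_params, walk_v1, schedule_v1, seed=31)


# --- independent oracles ---------------------------------------------------

def brute_force_sampler_weights(indices, alpha, t):
    """Direct evaluation of the recency kernel, normalised over history."""
    idx = np.asarray(indices, dtype=float)
    if alpha == 0.0:
        return np.full(idx.size, 1.0 / idx.size)
    w = alpha * (1.0 - alpha) ** (t - idx)
    return w / w.sum()


def brute_force_sampler_value(indices, rewards, alpha, t):
    if len(indices) == 0:
        return 0.0
    w = brute_force_sampler_weights(indices, alpha, t)
    return float(w @ np.asarray(rewards, dtype=float))


def brute_force_log_likelihood(choices, rewards, params: AgentParams):
    """From-scratch likelihood recomputing every sampler expectation by
    direct kernel enumeration on each trial."""
    history = {d: ([], []) for d in range(3)}
    v_rl = np.zeros(3)
    prev = None
    ll = 0.0
    t = 0
    for c, r in zip(choices, rewards):
        if c < 0:
            prev = None  # a missing response clears perseveration
            continue
        v_s = np.array(
            [
                brute_force_sampler_value(*history[d], params.alpha_sample, t)
                for d in range(3)
            ]
        )
        logits = params.beta_rl * v_rl + params.beta_sample * v_s
        if prev is not None:
            logits[prev] += params.beta_p
        logits -= logits.max()
        ll += logits[c] - np.log(np.exp(logits).sum())
        v_rl[c] += params.alpha_rl * (r - v_rl[c])
        history[c][0].append(t)
        history[c][1].append(r)
        prev = c
        t += 1
    return ll


def brute_force_tau_b(x, y):
    """All-pairs concordance count with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom


def _tie_term(v):
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())
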