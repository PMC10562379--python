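"""Hybrid memory-sampling + reinforcement-learning choice model.

Two valuation processes run side by side over the learning-phase choice
sequence:

* *Temporal-difference RL* keeps a cached expected value per deck,
  ``V_rl[x] <- V_rl[x] + alpha_rl * (R - V_rl[x])``, updated only for the
  chosen deck and initialised at zero.

* *Memory sampling* values a deck by a recency-weighted expectation over
  that deck's own past outcomes.  The probability that the sample comes
  from the choice made at past trial ``i`` (current trial ``t``) is
  proportional to ``alpha_sample * (1 - alpha_sample) ** (t - i)``; the
  kernel is renormalised over the deck's finite history so the value is a
  proper expectation.  A deck never chosen has sampler value 0, matching
  the RL initialisation.

Choice follows a softmax over ``beta_p * I(x == previous choice) +
beta_sample * V_sample[x] + beta_rl * V_rl[x]``.

Because the normalised kernel depends only on gaps between successive
choices of the same deck, the sampler expectation admits an exact O(1)
per-trial update (numerator/denominator pair rescaled by
``(1 - alpha_sample) ** gap`` at each new sample); the brute-force kernel
functions below are the reference definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "PARAM_BOUNDS",
    "PARAM_NAMES",
    "AgentParams",
    "EmptySamplerHistoryError",
    "HybridState",
    "rl_update",
    "sampler_weights",
    "sampler_value",
    "choice_probabilities",
    "sequence_log_likelihood",
    "chance_log_likelihood",
]

PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_rl": (0.0, 1.0),
    "alpha_sample": (0.0, 1.0),
    "beta_rl": (0.0, 20.0),
    "beta_sample": (0.0, 20.0),
    "beta_p": (-3.0, 3.0),
}
PARAM_NAMES = tuple(PARAM_BOUNDS)


class EmptySamplerHistoryError(ValueError):
    """Sampler weights are undefined for a deck with no choice history."""


@dataclass(frozen=True)
class AgentParams:
    """The five fitted parameters of the hybrid model.

    ``alpha_rl``: RL learning rate in [0, 1].  ``alpha_sample``: sampler
    recency decay in [0, 1].  ``beta_rl``, ``beta_sample``: softmax inverse
    temperatures in [0, 20].  ``beta_p``: perseveration weight in [-3, 3].
    """

    alpha_rl: float = 0.5
    alpha_sample: float = 0.5
    beta_rl: float = 0.0
    beta_sample: float = 0.0
    beta_p: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = PARAM_BOUNDS[f.name]
            v = getattr(self, f.name)
            if not lo <= v <= hi:
                raise ValueError(f"{f.name}={v} outside [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "AgentParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, arr))))


def rl_update(values: np.ndarray, chosen_deck: int, reward: float, alpha_rl: float) -> np.ndarray:
    """One TD update; only the chosen deck moves toward the reward."""
    values = np.asarray(values, dtype=float)
    if not 0 <= chosen_deck < len(values):
        raise IndexError(f"deck index {chosen_deck} out of range")
    if not 0.0 <= alpha_rl <= 1.0:
        raise ValueError(f"alpha_rl={alpha_rl} outside [0, 1]")
    out = values.copy()
    out[chosen_deck] += alpha_rl * (reward - out[chosen_deck])
    return out


def sampler_weights(trial_indices: np.ndarray, alpha_sample: float, t: int) -> np.ndarray:
    """Normalised recency kernel over one deck's past choice trials.

    ``trial_indices`` are the strictly increasing trial numbers at which
    the deck was chosen, all < ``t``.  The unnormalised kernel is
    ``alpha_sample * (1 - alpha_sample) ** (t - i)``; weights are returned
    renormalised to sum to 1 over the history.  ``alpha_sample == 0`` is
    treated as its uniform-weight limit.
    """
    idx = np.asarray(trial_indices, dtype=float)
    if idx.size == 0:
        raise EmptySamplerHistoryError("deck has no choice history")
    if np.any(idx >= t):
        raise ValueError("all history indices must precede the current trial")
    if not 0.0 <= alpha_sample <= 1.0:
        raise ValueError(f"alpha_sample={alpha_sample} outside [0, 1]")
    if alpha_sample == 0.0:
        return np.full(idx.size, 1.0 / idx.size)
    # Rescale relative to the most recent sample for numerical safety.
    rel = (1.0 - alpha_sample) ** (idx.max() - idx)
    w = rel / rel.sum()
    # alpha_sample == 1: all mass on the most recent sample (0**0 == 1).
    return w


def sampler_value(
    trial_indices: np.ndarray,
    rewards: np.ndarray,
    alpha_sample: float,
    t: int,
) -> float:
    """Expectation-weighted sampler value for one deck; 0 if never chosen."""
    idx = np.asarray(trial_indices)
    if idx.size == 0:
        return 0.0
    r = np.asarray(rewards, dtype=float)
    if r.shape != idx.shape:
        raise ValueError("trial_indices and rewards must align")
    w = sampler_weights(idx, alpha_sample, t)
    return float(w @ r)


def choice_probabilities(
    v_rl: np.ndarray,
    v_sample: np.ndarray,
    prev_choice: int | None,
    params: AgentParams,
) -> np.ndarray:
    """Softmax policy over the three decks (max-logit-shifted)."""
    v_rl = np.asarray(v_rl, dtype=float)
    v_sample = np.asarray(v_sample, dtype=float)
    logits = params.beta_rl * v_rl + params.beta_sample * v_sample
    if prev_choice is not None and prev_choice >= 0:
        logits = logits.copy()
        logits[prev_choice] += params.beta_p
    logits = logits - logits.max()
    p = np.exp(logits)
    return p / p.sum()


class HybridState:
    """Incremental learner state shared by the simulator and the likelihood.

    Tracks the RL values and the sampler's numerator/denominator pair per
    deck.  Missing-response trials must simply not be passed to
    :meth:`update`; they advance nothing.
    """

    def __init__(self, params: AgentParams, n_decks: int = 3) -> None:
        self.params = params
        self.v_rl = np.zeros(n_decks)
        self._num = np.zeros(n_decks)
        self._den = np.zeros(n_decks)
        self._last = np.zeros(n_decks, dtype=int)
        self._counter = 0
        self.prev_choice: int | None = None

    @property
    def v_sample(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            v = np.where(self._den > 0, self._num / np.where(self._den > 0, self._den, 1.0), 0.0)
        return v

    def probabilities(self, bias: np.ndarray | None = None) -> np.ndarray:
        p = self.params
        logits = p.beta_rl * self.v_rl + p.beta_sample * self.v_sample
        if self.prev_choice is not None:
            logits = logits.copy()
            logits[self.prev_choice] += p.beta_p
        if bias is not None:
            logits = logits + bias
        logits = logits - logits.max()
        e = np.exp(logits)
        return e / e.sum()

    def update(self, choice: int, reward: float) -> None:
        p = self.params
        self.v_rl[choice] += p.alpha_rl * (reward - self.v_rl[choice])
        if self._den[choice] > 0:
            decay = (1.0 - p.alpha_sample) ** (self._counter - self._last[choice])
        else:
            decay = 0.0
        self._num[choice] = reward + decay * self._num[choice]
        self._den[choice] = 1.0 + decay * self._den[choice]
        self._last[choice] = self._counter
        self._counter += 1
        self.prev_choice = choice


def _loglik_core(
    choices: np.ndarray,
    rewards: np.ndarray,
    alpha_rl: float,
    alpha_sample: float,
    beta_rl: float,
    beta_sample: float,
    beta_p: float,
) -> float:
    v_rl = np.zeros(3)
    num = np.zeros(3)
    den = np.zeros(3)
    last = np.zeros(3, dtype=np.int64)
    counter = 0
    prev = -1
    ll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            # Missing response: no likelihood term, no learning, and no
            # perseveration carry-over onto the next trial.
            prev = -1
            continue
        m = -1e300
        l0 = 0.0
        l1 = 0.0
        l2 = 0.0
        for x in range(3):
            vs = num[x] / den[x] if den[x] > 0.0 else 0.0
            lx = beta_rl * v_rl[x] + beta_sample * vs
            if x == prev:
                lx += beta_p
            if x == 0:
                l0 = lx
            elif x == 1:
                l1 = lx
            else:
                l2 = lx
            if lx > m:
                m = lx
        lse = m + math.log(math.exp(l0 - m) + math.exp(l1 - m) + math.exp(l2 - m))
        lc = l0 if c == 0 else (l1 if c == 1 else l2)
        ll += lc - lse
        r = float(rewards[t])
        v_rl[c] += alpha_rl * (r - v_rl[c])
        if den[c] > 0.0:
            decay = (1.0 - alpha_sample) ** (counter - last[c])
        else:
            decay = 0.0
        num[c] = r + decay * num[c]
        den[c] = 1.0 + decay * den[c]
        last[c] = counter
        counter += 1
        prev = c
    return ll


try:  # optional JIT; the pure-Python path is the same function body
    from numba import njit as _njit

    _loglik_core = _njit(cache=False)(_loglik_core)  # type: ignore[assignment]
except ImportError:  # pragma: no cover
    pass


def sequence_log_likelihood(dataset, params: AgentParams) -> float:
    """Summed log probability of the learning-phase choice sequence.

    ``dataset`` is a :class:`~membandit.data.ChoiceDataset` (or any object
    with ``learning_arrays()`` returning choices/rewards int arrays, with
    -1 marking missing responses).  Missing-response trials contribute
    nothing and advance neither learner.
    """
    choices, rewards = dataset.learning_arrays()
    return float(
        _loglik_core(
            np.ascontiguousarray(choices, dtype=np.int64),
            np.ascontiguousarray(rewards, dtype=np.int64),
            params.alpha_rl,
            params.alpha_sample,
            params.beta_rl,
            params.beta_sample,
            params.beta_p,
        )
    )


def chance_log_likelihood(n_trials: int, n_decks: int = 3) -> float:
    """Log likelihood of the fixed uniform-choice model."""
    return n_trials * math.log(1.0 / n_decks)
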