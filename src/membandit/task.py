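"""Restless three-armed bandit environment.

The task has two phases. In Phase 1 ("learning"), the agent makes 180
choices among three card decks across six consecutive casino "rooms" of 30
trials; each room shows a distinct background context. In Phase 2
("probe"), 120 further choice trials are interleaved with 60 memory-probe
trials (50 showing an item from a Phase-1 trial, 10 novel); no room context
is shown.

Each deck's payout probability follows a decaying Gaussian random walk
with reflecting bounds, centred on a target probability:

    pi[i, t+1] = lam * pi[i, t] + (1 - lam) * theta[i] + noise

The three target centers are a fixed set (by default {60, 30, 10} percent)
assigned randomly to decks at the start, then rotated cyclically after the
first 10 trials of each 30-trial block so the highest-paying deck always
changes; rotation continues through Phase 2. To signal that the decks carry
over between rooms, the stickiness is raised for the first three trials of
every room (or, under an alternative convention, the best deck pays out
with certainty there).
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

__all__ = [
    "ConfigError",
    "RewardWalkConfig",
    "RewardSeries",
    "TaskSchedule",
    "ExperimentConfig",
    "build_schedule",
    "generate_reward_walk",
    "assign_lure_opposed_walks",
]

CATEGORY_NAMES = ("beach", "forest", "mountain")

# Foil-room category order relative to the first three rooms: the unique
# derangement of (0, 1, 2) that never re-uses room 3's (0-based index 2)
# category in room 4 (index 3).
_FOIL_ORDER = (1, 2, 0)


class ConfigError(ValueError):
    """Invalid task/walk configuration; message names the offending field."""


@dataclass(frozen=True)
class RewardWalkConfig:
    """Parameters of the decaying Gaussian random walk over deck payouts.

    Units: payout probabilities and bounds are percent; ``noise_sd`` is in
    percentage points.
    """

    stickiness: float = 0.6
    boost_stickiness: float = 0.95
    noise_sd: float = 8.0
    lower_bound: float = 5.0
    upper_bound: float = 95.0
    initial_targets: tuple[float, float, float] = (60.0, 30.0, 10.0)
    rotation_first_trial: int = 10
    rotation_period: int = 30
    boost_trials: int = 3
    # Alternative room-start convention: pin the best deck to 100% payout
    # for the first ``boost_trials`` of each room instead of boosting the
    # stickiness.  Off by default.
    room_start_full_payout: bool = False

    def validate(self) -> None:
        if not 0.0 < self.stickiness < 1.0:
            raise ConfigError(f"stickiness must lie in (0, 1), got {self.stickiness}")
        if not 0.0 < self.boost_stickiness < 1.0:
            raise ConfigError(
                f"boost_stickiness must lie in (0, 1), got {self.boost_stickiness}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if not 0.0 <= self.lower_bound < self.upper_bound <= 100.0:
            raise ConfigError(
                "bounds must satisfy 0 <= lower_bound < upper_bound <= 100, got "
                f"lower_bound={self.lower_bound}, upper_bound={self.upper_bound}"
            )
        if len(self.initial_targets) != 3 or len(set(self.initial_targets)) != 3:
            raise ConfigError(
                f"initial_targets must be three distinct values, got {self.initial_targets}"
            )
        if self.rotation_period <= 0:
            raise ConfigError(
                f"rotation_period must be positive, got {self.rotation_period}"
            )
        if self.rotation_first_trial < 0:
            raise ConfigError(
                f"rotation_first_trial must be nonnegative, got {self.rotation_first_trial}"
            )


@dataclass
class TaskSchedule:
    """Room/context layout and probe placement for one task run.

    Phase 2 is an ordered sequence of ``n_probe_phase_choice_trials +
    n_probes`` events; ``probe_positions`` gives the (0-based) indices of
    the probe events within that sequence.  ``probe_items[k]`` is the
    0-based Phase-1 trial referenced by probe ``k``, or -1 for a novel
    probe.
    """

    experiment_variant: int
    n_learning_trials: int
    n_probe_phase_choice_trials: int
    room_length: int
    context_ids: np.ndarray          # per room, int
    context_category: np.ndarray | None  # per room, int (variant 2) or None
    probe_positions: np.ndarray      # sorted event indices of probes
    probe_items: np.ndarray          # learning-trial index or -1 (novel)

    @property
    def n_rooms(self) -> int:
        return self.n_learning_trials // self.room_length

    @property
    def n_probes(self) -> int:
        return len(self.probe_positions)

    @property
    def n_phase2_events(self) -> int:
        return self.n_probe_phase_choice_trials + self.n_probes

    @property
    def total_choice_trials(self) -> int:
        return self.n_learning_trials + self.n_probe_phase_choice_trials

    def room_of_trial(self, trial: int) -> int:
        """Room index of a Phase-1 trial."""
        if not 0 <= trial < self.n_learning_trials:
            raise ValueError(f"trial {trial} outside learning phase")
        return trial // self.room_length

    def category_pairs(self) -> list[tuple[int, int]]:
        """Variant-2 room pairs sharing a scene category, (first, foil)."""
        if self.context_category is None:
            raise ValueError("category pairs only defined for experiment variant 2")
        pairs = []
        for cat in np.unique(self.context_category):
            rooms = np.flatnonzero(self.context_category == cat)
            if len(rooms) != 2:
                raise ValueError(f"category {cat} does not appear in exactly 2 rooms")
            pairs.append((int(rooms[0]), int(rooms[1])))
        return pairs

    def paired_room(self, room: int) -> int:
        """The same-category foil room of ``room`` (variant 2)."""
        for a, b in self.category_pairs():
            if room == a:
                return b
            if room == b:
                return a
        raise ValueError(f"room {room} not in any category pair")

    def phase2_event_kind(self) -> np.ndarray:
        """Array over Phase-2 events: True where the event is a probe."""
        kind = np.zeros(self.n_phase2_events, dtype=bool)
        kind[self.probe_positions] = True
        return kind

    def post_probe_map(self) -> np.ndarray:
        """For each Phase-2 *choice* trial, index of the probe immediately
        preceding it in the event sequence, or -1."""
        is_probe = self.phase2_event_kind()
        out = np.full(self.n_probe_phase_choice_trials, -1, dtype=int)
        choice_idx = 0
        prev_probe = -1
        for ev in range(self.n_phase2_events):
            if is_probe[ev]:
                prev_probe = int(np.searchsorted(self.probe_positions, ev))
                continue
            out[choice_idx] = prev_probe
            prev_probe = -1
            choice_idx += 1
        return out

    def validate(self) -> None:
        if self.experiment_variant not in (1, 2):
            raise ConfigError(
                f"experiment_variant must be 1 or 2, got {self.experiment_variant}"
            )
        if self.n_learning_trials % self.room_length != 0:
            raise ConfigError(
                "n_learning_trials must be a multiple of room_length, got "
                f"{self.n_learning_trials} / {self.room_length}"
            )
        if len(self.context_ids) != self.n_rooms:
            raise ConfigError("context_ids must have one entry per room")
        if len(np.unique(self.context_ids)) != self.n_rooms:
            raise ConfigError("context_ids must be distinct across rooms")
        pos = np.asarray(self.probe_positions)
        if np.any(pos[1:] - pos[:-1] < 2):
            raise ConfigError("probe_positions must not be adjacent")
        if pos.size and pos[-1] >= self.n_phase2_events - 1:
            raise ConfigError("a probe cannot occupy the final phase-2 event")
        old = self.probe_items[self.probe_items >= 0]
        if np.any(old % self.room_length >= 10):
            raise ConfigError(
                "old probes must reference the first ten trials of a room"
            )
        if self.experiment_variant == 2:
            if self.context_category is None:
                raise ConfigError("variant 2 requires context_category")
            cats = np.asarray(self.context_category)
            half = self.n_rooms // 2
            if sorted(cats[:half]) != sorted(cats[half:]):
                raise ConfigError(
                    "variant 2: foil rooms must reuse the first rooms' categories"
                )
            if cats[half - 1] == cats[half]:
                raise ConfigError(
                    "variant 2: rooms at the phase midpoint must differ in category"
                )


@dataclass(frozen=True)
class ExperimentConfig:
    """Top-level reproducible description of one simulated task run."""

    experiment_variant: int = 1
    seed: int = 0
    walk: RewardWalkConfig = field(default_factory=RewardWalkConfig)
    lure_opposed: bool = False

    def validate(self) -> None:
        if self.experiment_variant not in (1, 2):
            raise ConfigError(
                f"experiment_variant must be 1 or 2, got {self.experiment_variant}"
            )
        if self.lure_opposed and self.experiment_variant != 2:
            raise ConfigError("lure_opposed requires experiment_variant=2")
        self.walk.validate()


@dataclass
class RewardSeries:
    """Per-deck payout-probability trajectories (percent), plus the target
    center assigned to each deck at each trial."""

    payout_prob: np.ndarray    # (3, total_trials)
    target_center: np.ndarray  # (3, total_trials)
    config: RewardWalkConfig

    @property
    def n_trials(self) -> int:
        return self.payout_prob.shape[1]

    def modal_top_deck(self, trials: slice) -> int:
        """Deck holding the highest target center for most of ``trials``."""
        top = np.argmax(self.target_center[:, trials], axis=0)
        return int(np.bincount(top, minlength=3).argmax())

    def validate(self) -> None:
        cfg = self.config
        lo, hi = cfg.lower_bound, cfg.upper_bound
        if not cfg.room_start_full_payout:
            if self.payout_prob.min() < lo - 1e-9 or self.payout_prob.max() > hi + 1e-9:
                raise ValueError("payout probabilities violate reflecting bounds")
        targets = np.sort(np.asarray(cfg.initial_targets))
        for t in range(self.n_trials):
            if not np.array_equal(np.sort(self.target_center[:, t]), targets):
                raise ValueError(f"centers at trial {t} are not a permutation of targets")


def build_schedule(
    experiment_variant: int,
    seed: int,
    *,
    n_learning_trials: int = 180,
    room_length: int = 30,
    n_probe_phase_choice_trials: int = 120,
    n_old_probes: int = 50,
    n_novel_probes: int = 10,
    probe_source_window: int = 10,
) -> TaskSchedule:
    """Build the room/context layout and the pseudorandom probe placement.

    Probes are placed uniformly at random among the Phase-2 event slots
    subject to two constraints: no two probes are adjacent and no probe
    occupies the final slot, so every probe is followed by a choice trial.
    Old probes are drawn, as evenly as possible across rooms, from each
    room's first ``probe_source_window`` trials.
    """
    if experiment_variant not in (1, 2):
        raise ConfigError(f"experiment_variant must be 1 or 2, got {experiment_variant}")
    if n_learning_trials % room_length != 0:
        raise ConfigError(
            f"n_learning_trials={n_learning_trials} not a multiple of room_length={room_length}"
        )
    rng = np.random.default_rng(seed)
    n_rooms = n_learning_trials // room_length

    if experiment_variant == 1:
        context_ids = rng.permutation(n_rooms)
        context_category = None
    else:
        if n_rooms != 6:
            raise ConfigError("experiment variant 2 requires exactly 6 rooms")
        first = rng.permutation(3)
        cats = np.concatenate([first, first[list(_FOIL_ORDER)]])
        context_category = cats
        # context id = 2*category + occurrence (0 = first room of the
        # category, 1 = its foil), giving 6 distinct ids.
        seen: dict[int, int] = {}
        ids = []
        for c in cats:
            occ = seen.get(int(c), 0)
            ids.append(2 * int(c) + occ)
            seen[int(c)] = occ + 1
        context_ids = np.array(ids)

    n_probes = n_old_probes + n_novel_probes
    n_events = n_probe_phase_choice_trials + n_probes
    # Non-adjacent positions excluding the final slot: bijection between
    # sorted k-subsets with gaps >= 2 in [0, n_events-2] and plain
    # k-subsets of a shrunken range.
    if n_probes > 0:
        m = (n_events - 1) - (n_probes - 1)
        if n_probes > m:
            raise ConfigError("too many probes for the phase-2 slot constraints")
        base = np.sort(rng.choice(m, size=n_probes, replace=False))
        probe_positions = base + np.arange(n_probes)
    else:
        probe_positions = np.empty(0, dtype=int)

    # Allocate old probes across rooms as evenly as possible.
    per_room = np.full(n_rooms, n_old_probes // n_rooms)
    extra = rng.choice(n_rooms, size=n_old_probes % n_rooms, replace=False)
    per_room[extra] += 1
    window = min(probe_source_window, room_length)
    if np.any(per_room > window):
        raise ConfigError("more old probes per room than probe-source trials")
    items = []
    for room in range(n_rooms):
        pool = room * room_length + np.arange(window)
        items.extend(rng.choice(pool, size=per_room[room], replace=False).tolist())
    items.extend([-1] * n_novel_probes)
    probe_items = np.array(items)
    rng.shuffle(probe_items)

    sched = TaskSchedule(
        experiment_variant=experiment_variant,
        n_learning_trials=n_learning_trials,
        n_probe_phase_choice_trials=n_probe_phase_choice_trials,
        room_length=room_length,
        context_ids=context_ids,
        context_category=context_category,
        probe_positions=probe_positions,
        probe_items=probe_items,
    )
    sched.validate()
    return sched


def _reflect(x: float, lo: float, hi: float) -> float:
    # Reflecting bounds; loop handles overshoot beyond a full band width.
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        else:
            x = 2.0 * hi - x
    return x


def generate_reward_walk(
    config: RewardWalkConfig, schedule: TaskSchedule, seed: int
) -> RewardSeries:
    """Generate payout-probability random walks for all choice trials.

    The walk runs over Phase-1 and Phase-2 choice trials (probes consume no
    walk step).  Target centers start as a random assignment of
    ``initial_targets`` to decks and rotate cyclically at trial
    ``rotation_first_trial`` and every ``rotation_period`` thereafter, so
    the highest-paying deck changes at every rotation.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    total = schedule.total_choice_trials
    lo, hi = config.lower_bound, config.upper_bound

    centers = np.empty((3, total))
    assignment = rng.permutation(np.asarray(config.initial_targets, dtype=float))
    next_rotation = config.rotation_first_trial
    for t in range(total):
        if t == next_rotation:
            assignment = np.roll(assignment, 1)
            next_rotation += config.rotation_period
        centers[:, t] = assignment

    payout = np.empty((3, total))
    payout[:, 0] = centers[:, 0]
    for t in range(1, total):
        in_phase1 = t < schedule.n_learning_trials
        room_trial = t % schedule.room_length
        boosted = in_phase1 and room_trial < config.boost_trials and t >= schedule.room_length
        lam = config.boost_stickiness if boosted else config.stickiness
        for i in range(3):
            step = (
                lam * payout[i, t - 1]
                + (1.0 - lam) * centers[i, t]
                + rng.normal(0.0, config.noise_sd)
            )
            payout[i, t] = _reflect(step, lo, hi)

    if config.room_start_full_payout:
        for t in range(total):
            if t < schedule.n_learning_trials and t % schedule.room_length < config.boost_trials:
                payout[int(np.argmax(centers[:, t])), t] = 100.0

    return RewardSeries(payout_prob=payout, target_center=centers, config=config)


def assign_lure_opposed_walks(
    series: RewardSeries, schedule: TaskSchedule
) -> RewardSeries:
    """Verify the variant-2 payoff opposition between same-category rooms.

    For every category pair, the deck holding the highest target center for
    most of the first room must differ from that of its foil room.  With
    the default cyclic rotation and foil-room ordering this holds by
    construction; the check is on centers, so it is meaningful even for
    degenerate zero-noise walks.
    """
    if schedule.experiment_variant != 2:
        raise ValueError(
            "assign_lure_opposed_walks requires an experiment-variant-2 schedule"
        )
    L = schedule.room_length
    for room_a, room_b in schedule.category_pairs():
        top_a = series.modal_top_deck(slice(room_a * L, (room_a + 1) * L))
        top_b = series.modal_top_deck(slice(room_b * L, (room_b + 1) * L))
        if top_a == top_b:
            raise ConfigError(
                f"category pair (rooms {room_a}, {room_b}) shares modal top deck "
                f"{top_a}; use the default cyclic rotation schedule"
            )
    return series
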