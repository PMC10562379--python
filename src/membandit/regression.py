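"""Probe-triggered memory-intrusion regression.

Phase-2 choices are modelled with a three-part logistic regression, one
part per deck, stacked into a single design matrix (default 3 decks x 120
choice trials = 360 rows, 7 columns):

* ``DI``   — deck chosen on the previous choice trial (0/1);
* ``DR1..DR3`` — deck chosen *and rewarded* 1..3 choice trials back (0/1),
  with lags crossing into the final learning-phase trials;
* ``EI``   — on trials immediately following an old memory probe, whether
  this deck was the one chosen on the probed learning trial (0/1);
* ``ER``   — same, and the probed trial was rewarded (0/1);
* ``EC``   — evoked context reward: this deck's (wins - losses) / times
  chosen within the room the probe recalls, in [-1, 1], 0 if the deck was
  never chosen there.

An optional eighth "gist" column carries the EC computed over the probed
room pooled with its same-category foil room, serially orthogonalised
against the target EC column (projection removal, no centering or
rescaling).  Probe columns are zero on trials not immediately following an
old probe; coefficients are shared across the three deck parts and
reported as log relative choice odds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .data import ChoiceDataset
from .task import TaskSchedule

__all__ = [
    "PROBE_COLUMNS",
    "ProbeDesignMatrix",
    "RegressionResult",
    "ProbeChoiceRegression",
    "evoked_context_reward",
    "ec_table",
    "gist_ec_table",
    "build_design_matrix",
    "orthogonalize_serial",
    "fit_probe_regression",
    "population_test",
]

PROBE_COLUMNS = ["DI", "DR1", "DR2", "DR3", "EI", "ER", "EC"]
GIST_COLUMN = "EC_gist"


def _room_counts(learning: pd.DataFrame, room_length: int) -> tuple[np.ndarray, np.ndarray]:
    """(n_rooms, 3) win and choice counts per room/deck."""
    n_rooms = int(learning["room"].max()) + 1
    wins = np.zeros((n_rooms, 3))
    picks = np.zeros((n_rooms, 3))
    resp = learning[learning["deck"] >= 0]
    for room, deck, reward in zip(resp["room"], resp["deck"], resp["reward"]):
        picks[room, deck] += 1
        wins[room, deck] += reward
    return wins, picks


def evoked_context_reward(learning_data: ChoiceDataset, room: int, deck: int) -> float:
    """Eq.-style net reward rate of ``deck`` in ``room``: (wins - losses) /
    times chosen, in [-1, 1]; 0 for a deck never chosen there."""
    if deck not in (0, 1, 2):
        raise ValueError(f"deck index {deck} out of range")
    learning = learning_data.learning_trials()
    n_rooms = int(learning["room"].max()) + 1
    if not 0 <= room < n_rooms:
        raise ValueError(f"room {room} out of range")
    wins, picks = _room_counts(learning, learning_data.room_length)
    if picks[room, deck] == 0:
        return 0.0
    w = wins[room, deck]
    n = picks[room, deck]
    return float((w - (n - w)) / n)


def ec_table(learning_data: ChoiceDataset) -> np.ndarray:
    """(n_rooms, 3) evoked-context-reward table; 0 where never chosen."""
    learning = learning_data.learning_trials()
    wins, picks = _room_counts(learning, learning_data.room_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        ec = np.where(picks > 0, (2.0 * wins - picks) / np.where(picks > 0, picks, 1.0), 0.0)
    return ec


def gist_ec_table(learning_data: ChoiceDataset, schedule: TaskSchedule) -> np.ndarray:
    """(n_rooms, 3) EC over each room pooled with its same-category foil."""
    if schedule.experiment_variant != 2:
        raise ValueError("gist EC requires an experiment-variant-2 schedule")
    learning = learning_data.learning_trials()
    wins, picks = _room_counts(learning, learning_data.room_length)
    out = np.zeros_like(wins)
    for room in range(wins.shape[0]):
        other = schedule.paired_room(room)
        w = wins[room] + wins[other]
        n = picks[room] + picks[other]
        with np.errstate(invalid="ignore", divide="ignore"):
            out[room] = np.where(n > 0, (2.0 * w - n) / np.where(n > 0, n, 1.0), 0.0)
    return out


def orthogonalize_serial(target_col: np.ndarray, gist_col: np.ndarray) -> np.ndarray:
    """Remove from ``gist_col`` its projection onto ``target_col``.

    Serial Gram-Schmidt step: no mean-centering, target left untouched.
    A zero-norm target returns the gist column unchanged with a warning.
    """
    target = np.asarray(target_col, dtype=float)
    gist = np.asarray(gist_col, dtype=float)
    denom = target @ target
    if denom == 0.0:
        warnings.warn("orthogonalisation target has zero norm; gist left unchanged")
        return gist.copy()
    return gist - target * ((target @ gist) / denom)


@dataclass
class ProbeDesignMatrix:
    """Stacked per-deck design matrix and response vector.

    ``X`` rows are ordered (trial, deck); ``y[i] = 1`` iff that row's deck
    was chosen on that row's trial.  Missing-response trials contribute no
    rows.
    """

    X: pd.DataFrame
    y: np.ndarray
    trial: np.ndarray  # phase-2 choice-trial index per row
    deck: np.ndarray   # deck per row

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def build_design_matrix(
    dataset: ChoiceDataset,
    schedule: TaskSchedule,
    include_gist: bool = False,
) -> ProbeDesignMatrix:
    """Assemble the probe regression design matrix for one agent.

    Probe columns (EI/ER/EC, and the gist column) are populated only on
    the choice trial immediately following an old probe; trials after
    novel probes, and all other trials, carry zeros there.  DI/DR lags
    that reach before the first Phase-2 choice trial use the final
    learning-phase trials.
    """
    dataset.validate()
    learning = dataset.learning_trials().reset_index(drop=True)
    p2_choice = dataset.phase2_choice_trials().reset_index(drop=True)
    probes = dataset.probe_events().reset_index(drop=True)
    post_probe = schedule.post_probe_map()
    if len(p2_choice) != len(post_probe):
        raise ValueError("dataset phase-2 choice trials do not match schedule")

    ec = ec_table(dataset)
    gist = gist_ec_table(dataset, schedule) if include_gist else None

    # Choice/reward history in walk order (phase 1 then phase 2).
    hist_deck = np.concatenate([learning["deck"].to_numpy(), p2_choice["deck"].to_numpy()])
    hist_rew = np.concatenate([learning["reward"].to_numpy(), p2_choice["reward"].to_numpy()])
    n_learn = len(learning)

    rows: list[list[float]] = []
    ys: list[int] = []
    trials: list[int] = []
    decks: list[int] = []
    for j in range(len(p2_choice)):
        chosen = int(p2_choice.loc[j, "deck"])
        if chosen < 0:
            continue  # missing response: C_{i,t} undefined
        g = n_learn + j  # global choice-trial index
        probe_k = post_probe[j]
        probe_deck = -1
        probe_rew = 0
        probe_room = -1
        if probe_k >= 0:
            ref = int(probes.loc[probe_k, "probe_ref"])
            if int(probes.loc[probe_k, "probe_novel"]) == 0:
                if not 0 <= ref < n_learn:
                    raise ValueError(f"probe {probe_k} references invalid trial {ref}")
                probe_deck = int(learning.loc[ref, "deck"])
                probe_rew = int(learning.loc[ref, "reward"]) if probe_deck >= 0 else 0
                probe_room = int(learning.loc[ref, "room"])
        for deck in range(3):
            di = 1.0 if hist_deck[g - 1] == deck else 0.0
            dr = [
                1.0 if (g - k >= 0 and hist_deck[g - k] == deck and hist_rew[g - k] == 1) else 0.0
                for k in (1, 2, 3)
            ]
            if probe_room >= 0 and probe_deck >= 0:
                ei = 1.0 if probe_deck == deck else 0.0
                er = ei if probe_rew == 1 else 0.0
                ecv = float(ec[probe_room, deck])
                gv = float(gist[probe_room, deck]) if gist is not None else 0.0
            else:
                ei = er = ecv = gv = 0.0
            row = [di, *dr, ei, er, ecv]
            if include_gist:
                row.append(gv)
            rows.append(row)
            ys.append(1 if chosen == deck else 0)
            trials.append(j)
            decks.append(deck)

    cols = PROBE_COLUMNS + ([GIST_COLUMN] if include_gist else [])
    X = pd.DataFrame(rows, columns=cols)
    if include_gist:
        X[GIST_COLUMN] = orthogonalize_serial(
            X["EC"].to_numpy(), X[GIST_COLUMN].to_numpy()
        )
    return ProbeDesignMatrix(
        X=X, y=np.array(ys), trial=np.array(trials), deck=np.array(decks)
    )


@dataclass
class RegressionResult:
    """Per-participant probe-regression coefficients (log relative choice
    odds), with convergence/separation diagnostics."""

    coefficients: dict[str, float]
    intercept: float
    converged: bool
    separation: bool


class ProbeChoiceRegression(BaseEstimator):
    """Maximum-likelihood logistic fit of the stacked probe design matrix.

    Coefficients are shared across the three deck parts (``shared_parts=
    True``, matching the single stacked 360-row matrix); a per-deck
    variant averaging three separate fits is available with
    ``shared_parts=False``.  An unpenalised fit is attempted first; on
    perfect separation or non-convergence a weakly L2-penalised fallback
    is used and flagged via ``separation_``.

    Attributes set by :meth:`fit`: ``coef_``, ``intercept_``,
    ``feature_names_``, ``converged_``, ``separation_``.
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        shared_parts: bool = True,
        fallback_alpha: float = 1.0,
        max_iter: int = 100,
    ) -> None:
        self.fit_intercept = fit_intercept
        self.shared_parts = shared_parts
        self.fallback_alpha = fallback_alpha
        self.max_iter = max_iter

    def _fit_one(self, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool, bool]:
        import statsmodels.api as sm

        design = sm.add_constant(X, has_constant="add") if self.fit_intercept else X
        converged = True
        separation = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=self.max_iter)
            params = np.asarray(res.params)
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged or not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 30:
                raise RuntimeError("suspect separation / non-convergence")
        except Exception:
            # Weakly L2-penalised fallback on standardised columns, so the
            # shrinkage is scale-equivariant (a low-variance regressor such
            # as the orthogonalised gist column is not penalised harder).
            separation = True
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd_safe = np.where(sd > 0, sd, 1.0)
            Xs = (X - mu) / sd_safe
            lr = LogisticRegression(
                C=1.0 / self.fallback_alpha,
                fit_intercept=self.fit_intercept,
                max_iter=max(500, self.max_iter),
            ).fit(Xs, y)
            coef = lr.coef_.ravel() / sd_safe
            icpt = (
                float(lr.intercept_[0]) - float(coef @ mu)
                if self.fit_intercept
                else 0.0
            )
            return coef, icpt, True, separation
        if self.fit_intercept:
            return params[1:], float(params[0]), converged, separation
        return params, 0.0, converged, separation

    def fit(self, X, y=None) -> "ProbeChoiceRegression":
        """Fit from a :class:`ProbeDesignMatrix`, or from (X, y) arrays."""
        if isinstance(X, ProbeDesignMatrix):
            dm = X
            Xa = dm.X.to_numpy(dtype=float)
            ya = np.asarray(dm.y)
            names = list(dm.X.columns)
            decks = dm.deck
        else:
            if y is None:
                raise ValueError("y is required when X is an array")
            Xa = np.asarray(X, dtype=float)
            ya = np.asarray(y)
            names = (
                list(X.columns)
                if isinstance(X, pd.DataFrame)
                else [f"x{i}" for i in range(Xa.shape[1])]
            )
            decks = None
        if Xa.size == 0 or ya.sum() == 0:
            raise ValueError("empty design matrix or all-zero response")

        if self.shared_parts or decks is None:
            coef, icpt, conv, sep = self._fit_one(Xa, ya)
        else:
            parts = [self._fit_one(Xa[decks == d], ya[decks == d]) for d in range(3)]
            coef = np.mean([p[0] for p in parts], axis=0)
            icpt = float(np.mean([p[1] for p in parts]))
            conv = all(p[2] for p in parts)
            sep = any(p[3] for p in parts)

        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = icpt
        self.feature_names_ = names
        self.converged_ = conv
        self.separation_ = sep
        return self

    def result(self) -> RegressionResult:
        return RegressionResult(
            coefficients=dict(zip(self.feature_names_, map(float, self.coef_))),
            intercept=self.intercept_,
            converged=self.converged_,
            separation=self.separation_,
        )


def fit_probe_regression(dm: ProbeDesignMatrix, **kwargs) -> RegressionResult:
    """Convenience wrapper around :class:`ProbeChoiceRegression`."""
    return ProbeChoiceRegression(**kwargs).fit(dm).result()


def population_test(coefficients: np.ndarray) -> tuple[float, float]:
    """Two-tailed one-sample t-test of per-participant coefficients vs 0."""
    vals = np.asarray(coefficients, dtype=float)
    if len(vals) < 2:
        raise ValueError("population test requires at least 2 participants")
    if np.allclose(vals.std(ddof=1), 0.0):
        raise ValueError("zero variance across participants")
    t, p = stats.ttest_1samp(vals, 0.0)
    return float(t), float(p)
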