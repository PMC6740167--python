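"""Mixture of constrained hidden Markov chains for daily engagement sequences.

Each user contributes one binary sequence: "did the user touch the platform
on day *t*?".  The generative model is a finite mixture of first-order
hidden Markov chains over three latent states — high engagement, low
engagement, and disengaged — with

* a fixed initial state: every user starts in ``high`` (new users are, by
  construction of the cohort, active right after signing up);
* an absorbing ``disengaged`` state: once a user disengages they never
  return, and the probability of an active day while disengaged is exactly 0;
* Bernoulli emissions shared across mixture components, so that components
  differ only through their transition matrices.  Clusters therefore
  separate users by *how they move between engagement states*, not by what
  an engaged day looks like.

Fitting is by expectation–maximization with scaled (underflow-safe)
forward–backward recursions.  The estimator follows the scikit-learn
conventions (``fit`` / ``predict`` / ``predict_proba``, fitted attributes
with a trailing underscore) and composes with sklearn model-selection
utilities.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "STATES",
    "N_STATES",
    "EngagementSeries",
    "BinarySequence",
    "MarkovChainMixture",
    "ElbowSelection",
    "binarize",
    "binarize_frame",
    "sequence_loglik",
    "assign_clusters",
    "select_k_elbow",
    "summarize_clusters",
    "expected_absorption_time",
    "expected_engaged_days",
]

#: Latent engagement states, in canonical order.
STATES = ("high", "low", "disengaged")
N_STATES = 3

#: The seven daily activity measures captured by the platform.
MEASURES = (
    "pages_viewed",
    "clicks",
    "groups_followed",
    "users_followed",
    "posts_liked",
    "comments",
    "posts",
)


class DataError(ValueError):
    """Raised when an input series violates the data contract."""


@dataclasses.dataclass
class EngagementSeries:
    """One user's daily counts of the seven platform activity measures.

    ``counts`` is a DataFrame indexed by day (1..horizon_days, no gaps;
    absent days are zero rows) with one column per measure.
    """

    user_id: str
    counts: pd.DataFrame
    horizon_days: int

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            day = int(self.counts.index[(self.counts < 0).any(axis=1)][0])
            raise DataError(
                f"negative activity count for user {self.user_id!r} on day {day}"
            )
        expected = np.arange(1, self.horizon_days + 1)
        if len(self.counts) != self.horizon_days or not np.array_equal(
            np.asarray(self.counts.index), expected
        ):
            raise DataError(
                f"user {self.user_id!r}: day index must be 1..{self.horizon_days} with no gaps"
            )


@dataclasses.dataclass
class BinarySequence:
    """Per-day engaged/not-engaged flags for one user."""

    user_id: str
    engaged: np.ndarray  # bool, shape (horizon_days,)


def binarize(series: EngagementSeries) -> BinarySequence:
    """Flag each day as engaged iff any activity count on that day is nonzero."""
    series.validate()
    engaged = series.counts.values.sum(axis=1) > 0
    return BinarySequence(user_id=series.user_id, engaged=engaged)


def binarize_frame(series_list: Sequence[EngagementSeries]) -> tuple[list, np.ndarray]:
    """Binarize a list of series into a (n_users, horizon) boolean matrix.

    Returns the user ids (row order) and the matrix.
    """
    if not series_list:
        return [], np.zeros((0, 0), dtype=bool)
    horizons = {s.horizon_days for s in series_list}
    if len(horizons) > 1:
        raise DataError(f"series have mixed horizons: {sorted(horizons)}")
    seqs = [binarize(s) for s in series_list]
    X = np.stack([s.engaged for s in seqs])
    return [s.user_id for s in seqs], X


# ---------------------------------------------------------------------------
# scaled forward / backward machinery
#
# The recursions run in linear space with per-day normalization (the
# classical scaling trick): the scaled forward variables sum to 1 each day
# and the log-likelihood accumulates as the sum of log scaling factors, so
# sequences of any length are underflow-safe.  Structural zeros (the
# absorbing row, the zero disengaged emission) need no special casing.
# Everything is vectorized over users and mixture components at once.
#
# Day 1 is special: eligibility for the cohort requires activity right
# after signup, so day 1 is engaged by construction (deterministically, in
# both the generator and the real recruitment rule).  It therefore carries
# no emission factor — the recursion starts from "state high, engaged" with
# probability 1, and a sequence whose first day is not engaged has
# log-likelihood -inf.  Treating day 1 as a Bernoulli draw instead would
# bias the engaged-day emission upward, since the data contain no
# non-engaged first days.
# ---------------------------------------------------------------------------


def _emissions_lin(X: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-user, per-day, per-state observation probabilities (n, T, 3)."""
    return np.where(X[:, :, None], b, 1.0 - b)


def _forward_all(X: np.ndarray, e: np.ndarray, A: np.ndarray):
    """Scaled forward pass for all components at once.

    X: bool (n, T) engaged flags; e: (n, T, 3) observation probabilities;
    A: (K, 3, 3) transitions.  Returns scaled alphas (T, n, K, 3), scaling
    factors c (T, n, K) and per-user per-component log-likelihoods (n, K).
    A user impossible under a component gets -inf log-likelihood (its
    alphas collapse to zero).
    """
    n, T, S = e.shape
    K = A.shape[0]
    alphas = np.empty((T, n, K, S))
    cs = np.empty((T, n, K))
    ll = np.zeros((n, K))
    a = np.zeros((n, K, S))
    # day 1: state "high", engaged with probability 1 (eligibility rule)
    a[:, :, 0] = X[:, 0].astype(float)[:, None]
    for t in range(T):
        if t > 0:
            a = np.einsum("nkr,krs->nks", a, A) * e[:, t, None, :]
        c = a.sum(axis=2)
        with np.errstate(divide="ignore"):
            ll += np.log(c)
        a = a / np.where(c > 0.0, c, 1.0)[:, :, None]
        alphas[t] = a
        cs[t] = c
    return alphas, cs, ll


def _backward_stats(e, A, X, alphas, cs):
    """Backward pass accumulating the EM sufficient statistics.

    Returns per-user expected state occupancies ``occ`` (n, K, 3), engaged-day
    occupancies ``occ_eng`` (n, K, 3) and summed transition counts ``xi``
    (n, K, 3, 3), all conditional on each component.
    """
    n, T, S = e.shape
    K = A.shape[0]
    beta = np.ones((n, K, S))
    occ = np.zeros((n, K, S))
    occ_eng = np.zeros((n, K, S))
    if T > 1:  # day 1 carries no emission, so no occupancy statistics
        g = alphas[T - 1] * beta
        occ += g
        occ_eng += g * X[:, T - 1, None, None]
    xi = np.zeros((n, K, S, S))
    for t in range(T - 2, -1, -1):
        c_next = np.where(cs[t + 1] > 0.0, cs[t + 1], 1.0)[:, :, None]
        eb = e[:, t + 1, None, :] * beta  # (n, K, S)
        xi += (
            alphas[t][:, :, :, None]
            * A[None]
            * (eb / c_next)[:, :, None, :]
        )
        beta = np.einsum("krs,nks->nkr", A, eb) / c_next
        if t > 0:
            g = alphas[t] * beta
            occ += g
            occ_eng += g * X[:, t, None, None]
    return occ, occ_eng, xi


try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _estep_core(X, A, w, b):  # pragma: no cover - exercised via the estimator
    """One EM E-step: responsibilities and pooled sufficient statistics.

    X: uint8 (n, T); A: (K, 3, 3); w: (K,); b: (3,).
    Returns (resp (n,K), comp_ll (n,K), total_ll, trans_counts (K,3,3),
    emis_num (3,), emis_den (3,)).  Scaled forward-backward per user.
    """
    n, T = X.shape
    K = A.shape[0]
    S = 3
    resp = np.empty((n, K))
    comp_ll = np.empty((n, K))
    trans = np.zeros((K, S, S))
    num = np.zeros(S)
    den = np.zeros(S)
    total_ll = 0.0
    alphas = np.empty((K, T, S))
    css = np.empty((K, T))
    beta = np.empty(S)
    beta_new = np.empty(S)
    ebc = np.empty(S)
    for i in range(n):
        for k in range(K):
            # day 1: state "high", engaged with probability 1 (eligibility)
            c = 0.0
            for s in range(S):
                a0 = (1.0 if X[i, 0] else 0.0) if s == 0 else 0.0
                alphas[k, 0, s] = a0
                c += a0
            css[k, 0] = c
            ll = np.log(c) if c > 0.0 else -np.inf
            if c > 0.0:
                for s in range(S):
                    alphas[k, 0, s] /= c
            for t in range(1, T):
                c = 0.0
                for s in range(S):
                    acc = 0.0
                    for r in range(S):
                        acc += alphas[k, t - 1, r] * A[k, r, s]
                    e = b[s] if X[i, t] else 1.0 - b[s]
                    acc *= e
                    alphas[k, t, s] = acc
                    c += acc
                css[k, t] = c
                ll += np.log(c) if c > 0.0 else -np.inf
                if c > 0.0:
                    for s in range(S):
                        alphas[k, t, s] /= c
            comp_ll[i, k] = ll
        # responsibilities via log-sum-exp over components
        m = -np.inf
        for k in range(K):
            v = np.log(w[k]) + comp_ll[i, k] if w[k] > 0.0 else -np.inf
            resp[i, k] = v
            if v > m:
                m = v
        if not np.isfinite(m):
            total_ll = -np.inf
            continue
        acc = 0.0
        for k in range(K):
            acc += np.exp(resp[i, k] - m)
        lse = m + np.log(acc)
        total_ll += lse
        for k in range(K):
            resp[i, k] = np.exp(resp[i, k] - lse)
        # backward per component, accumulating responsibility-weighted stats
        for k in range(K):
            rk = resp[i, k]
            if rk == 0.0:
                continue
            for s in range(S):
                beta[s] = 1.0
                if T > 1:  # day 1 carries no emission statistics
                    g = alphas[k, T - 1, s]
                    den[s] += rk * g
                    if X[i, T - 1]:
                        num[s] += rk * g
            for t in range(T - 2, -1, -1):
                cn = css[k, t + 1] if css[k, t + 1] > 0.0 else 1.0
                for s in range(S):
                    e = b[s] if X[i, t + 1] else 1.0 - b[s]
                    ebc[s] = e * beta[s] / cn
                for r in range(S):
                    acc = 0.0
                    for s in range(S):
                        v = A[k, r, s] * ebc[s]
                        trans[k, r, s] += rk * alphas[k, t, r] * v
                        acc += v
                    beta_new[r] = acc
                for s in range(S):
                    beta[s] = beta_new[s]
                    if t > 0:
                        g = alphas[k, t, s] * beta[s]
                        den[s] += rk * g
                        if X[i, t]:
                            num[s] += rk * g
    return resp, comp_ll, total_ll, trans, num, den


def sequence_loglik(engaged: np.ndarray, transition: np.ndarray, emissions: np.ndarray) -> float:
    """log P(binary sequence | one mixture component) by the forward recursion.

    The initial state is fixed at "high" and day 1 is engaged with
    probability 1 (the cohort eligibility rule), so a sequence whose first
    day is not engaged — or that is otherwise impossible under the
    component — returns -inf.  ``transition`` is the component's 3x3
    row-stochastic matrix with absorbing third row; ``emissions`` the
    per-state probabilities of an engaged day (third entry 0).
    """
    engaged = np.asarray(engaged, dtype=bool)[None, :]
    e = _emissions_lin(engaged, np.asarray(emissions, dtype=float))
    A = np.asarray(transition, dtype=float)[None]
    _, _, ll = _forward_all(engaged, e, A)
    return float(ll[0, 0])


def expected_absorption_time(transition: np.ndarray) -> float:
    """Expected number of days before entering "disengaged", starting at "high".

    Computed from the fundamental matrix N = (I - Q)^-1 of the absorbing
    chain, where Q is the transient (high, low) block.  Infinite when the
    transient block is (numerically) closed.
    """
    Q = np.asarray(transition, dtype=float)[:2, :2]
    try:
        t = np.linalg.solve(np.eye(2) - Q, np.ones(2))
    except np.linalg.LinAlgError:
        return np.inf
    if not np.all(np.isfinite(t)) or t[0] <= 0:
        return np.inf
    return float(t[0])


def expected_engaged_days(
    transition: np.ndarray, emission_probs: Sequence[float], horizon_days: int = 91
) -> float:
    """Expected engaged-day count under one component, day 1 forced engaged.

    Direct expectation from matrix powers of the transition matrix: the
    state-occupancy distribution at day t is the initial distribution times
    A^(t-1); each subsequent day contributes its state's emission
    probability.
    """
    A = np.asarray(transition, dtype=float)
    b = np.asarray(emission_probs, dtype=float)
    p = np.array([1.0, 0.0, 0.0])
    total = 1.0  # day 1 engaged by eligibility
    for _ in range(1, horizon_days):
        p = p @ A
        total += float(p @ b)
    return total


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class MarkovChainMixture(BaseEstimator):
    """EM-fitted mixture of K constrained 3-state hidden Markov chains.

    Parameters
    ----------
    n_components : int
        Number of mixture components (engagement clusters).
    tol : float
        EM stops when the relative change in total log-likelihood drops
        below this value.
    max_iter : int
        Maximum EM iterations per restart.
    n_init : int
        Number of random restarts; the restart with the best final
        log-likelihood is kept.
    emission_init : tuple of float
        Initial Bernoulli emission probabilities for (high, low).  The
        disengaged emission is structurally 0 and never estimated.
    transition_floor : float
        Lower floor applied to estimable transition entries before row
        renormalization, preventing -inf log-likelihood lock-in.
    random_state : int or None
        Seed for the restart initializations; fits are bit-reproducible
        for a fixed seed.
    keep_history : bool
        When True, per-iteration parameter snapshots of the winning restart
        are stored in ``history_``.

    Attributes
    ----------
    weights_ : ndarray (K,)            mixing proportions
    transitions_ : ndarray (K, 3, 3)   per-component transition matrices
    emissions_ : ndarray (3,)          shared engaged-day probabilities
    responsibilities_ : ndarray (n, K) posterior component memberships
    labels_ : ndarray (n,)             hard cluster of each training user
    loglik_trace_ : ndarray            total log-likelihood per EM iteration
    n_iter_ : int                      iterations run by the winning restart
    converged_ : bool                  tolerance reached before max_iter
    lower_bound_ : float               final total log-likelihood

    Components are relabelled after fitting in order of increasing expected
    time to disengagement, so cluster 0 is always the "low engagers" end.
    """

    def __init__(
        self,
        n_components: int = 4,
        *,
        tol: float = 1e-8,
        max_iter: int = 500,
        n_init: int = 10,
        emission_init: tuple[float, float] = (0.8, 0.3),
        transition_floor: float = 1e-9,
        random_state: int | None = None,
        keep_history: bool = False,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.emission_init = emission_init
        self.transition_floor = transition_floor
        self.random_state = random_state
        self.keep_history = keep_history

    # -- helpers ------------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (n_users, horizon) array of flags")
        if X.dtype != bool:
            vals = np.unique(X)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("X must contain only 0/1 engaged-day flags")
            X = X.astype(bool)
        return X

    def _init_params(self, rng: np.random.Generator, X: np.ndarray, restart: int):
        """Moment-matched initialization with per-restart jitter.

        Users are split into K quantile groups by engaged-day count; each
        group seeds one component: its disengagement hazard from the mean
        last-active day, its high/low mix from the group's engagement
        density relative to the initial emission probabilities.  The first
        restart uses the moment estimates as-is; later restarts blend them
        with random simplex draws so the restarts explore distinct basins.
        """
        K = self.n_components
        n, T = X.shape
        weights = np.full(K, 1.0 / K)
        emissions = np.array([*self.emission_init, 0.0], dtype=float)
        days = X.sum(axis=1)
        last = T - 1 - np.argmax(X[:, ::-1], axis=1)  # index of last engaged day
        order = np.argsort(days, kind="stable")
        groups = np.array_split(order, K)
        transitions = np.zeros((K, N_STATES, N_STATES))
        for k, g in enumerate(groups):
            if len(g) == 0:
                transitions[k, :2] = rng.dirichlet(np.ones(N_STATES), size=2)
                continue
            span = last[g] + 1.0
            # hazard ~ 1/lifetime; near-immortal groups get a small floor
            hazard = float(np.clip(1.0 / max(span.mean(), 1.0), 1e-3, 0.5))
            if span.mean() > 0.9 * T:
                hazard = 1e-3
            dens = float(days[g].sum() / span.sum())
            frac_high = float(
                np.clip(
                    (dens - emissions[1]) / max(emissions[0] - emissions[1], 1e-6),
                    0.0,
                    1.0,
                )
            )
            switch = 0.4  # moderate mixing between the transient states
            p_hl = switch * (1.0 - frac_high)
            p_lh = switch * frac_high
            transitions[k, 0] = (1.0 - p_hl - hazard, p_hl, hazard)
            transitions[k, 1] = (p_lh, 1.0 - p_lh - hazard, hazard)
        transitions[:, 2] = (0.0, 0.0, 1.0)
        if restart > 0:
            lam = rng.uniform(0.3, 0.9)
            noise = rng.dirichlet(np.ones(N_STATES), size=(K, 2))
            transitions[:, :2] = (1.0 - lam) * transitions[:, :2] + lam * noise
        return weights, self._project_transitions(transitions), emissions

    def _project_transitions(self, transitions: np.ndarray) -> np.ndarray:
        """Impose structural constraints: floor, renormalize, absorbing row."""
        out = transitions.copy()
        out[:, :2] = np.maximum(out[:, :2], self.transition_floor)
        out[:, :2] /= out[:, :2].sum(axis=2, keepdims=True)
        out[:, 2] = (0.0, 0.0, 1.0)
        return out

    def _e_step(self, X, weights, transitions, emissions, iteration):
        """Posterior responsibilities plus pooled expected sufficient statistics."""
        if _HAVE_NUMBA:
            resp, _, total_ll, trans_counts, num, den = _estep_core(
                X.astype(np.uint8), transitions, weights, emissions
            )
            if not np.isfinite(total_ll):
                raise FloatingPointError(
                    f"non-finite sequence likelihood in EM iteration {iteration}"
                )
            return resp, float(total_ll), trans_counts, num, den
        e = _emissions_lin(X, emissions)
        alphas, cs, comp_ll = _forward_all(X, e, transitions)
        with np.errstate(divide="ignore"):
            logr = np.log(weights)[None, :] + comp_ll
        total_ll = logsumexp(logr, axis=1)
        if not np.all(np.isfinite(total_ll)):
            raise FloatingPointError(
                f"non-finite sequence likelihood in EM iteration {iteration}"
            )
        resp = np.exp(logr - total_ll[:, None])
        occ, occ_eng, xi = _backward_stats(e, transitions, X, alphas, cs)
        trans_counts = np.einsum("nk,nkrs->krs", resp, xi)
        num = np.einsum("nk,nks->s", resp, occ_eng)
        den = np.einsum("nk,nks->s", resp, occ)
        return resp, float(total_ll.sum()), trans_counts, num, den

    def _m_step(self, resp, trans_counts, emis_num, emis_den, transitions, emissions):
        K = resp.shape[1]
        weights = resp.mean(axis=0)
        weights /= weights.sum()
        new_trans = transitions.copy()
        for k in range(K):
            rows = trans_counts[k, :2]
            tot = rows.sum(axis=1, keepdims=True)
            # keep previous row where a state was never visited
            upd = np.divide(rows, tot, out=transitions[k, :2].copy(), where=tot > 0)
            new_trans[k, :2] = upd
        new_trans = self._project_transitions(new_trans)
        # shared emissions, pooled over components weighted by responsibility
        num = emis_num[:2]
        den = emis_den[:2]
        b = emissions.copy()
        mask = den > 1e-300
        b[:2][mask] = num[mask] / den[mask]
        b[2] = 0.0
        if b[0] < b[1]:  # swap-and-relabel states to keep b_high >= b_low
            b = b[[1, 0, 2]]
            perm = [1, 0, 2]
            new_trans = new_trans[:, perm][:, :, perm]
        np.clip(b[:2], 0.0, 1.0, out=b[:2])
        return weights, new_trans, b

    def _fit_once(self, X, rng_seed, restart=0):
        rng = np.random.default_rng(rng_seed)
        weights, transitions, emissions = self._init_params(rng, X, restart)
        trace = []
        history = [] if self.keep_history else None
        prev_ll = -np.inf
        converged = False
        n_iter = 0
        resp = None
        for it in range(1, self.max_iter + 1):
            resp, total_ll, tc, emis_num, emis_den = self._e_step(
                X, weights, transitions, emissions, it
            )
            trace.append(total_ll)
            n_iter = it
            if history is not None:
                history.append(
                    {
                        "weights": weights.copy(),
                        "transitions": transitions.copy(),
                        "emissions": emissions.copy(),
                        "loglik": total_ll,
                    }
                )
            if np.isfinite(prev_ll) and abs(total_ll - prev_ll) < self.tol * abs(prev_ll):
                converged = True
                break
            prev_ll = total_ll
            weights, transitions, emissions = self._m_step(
                resp, tc, emis_num, emis_den, transitions, emissions
            )
        return {
            "weights": weights,
            "transitions": transitions,
            "emissions": emissions,
            "resp": resp,
            "trace": np.asarray(trace),
            "n_iter": n_iter,
            "converged": converged,
            "history": history,
        }

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the mixture to a (n_users, horizon) matrix of engaged-day flags."""
        X = self._validate_X(X)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if X.shape[0] < self.n_components:
            raise ValueError(
                f"need at least n_components={self.n_components} sequences, "
                f"got {X.shape[0]}"
            )
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_init)
        best = None
        for restart, seed in enumerate(seeds):
            run = self._fit_once(X, seed, restart)
            if best is None or run["trace"][-1] > best["trace"][-1]:
                best = run
        # canonical labels: ascending expected engaged days over the training
        # horizon, so cluster 0 is "low engagers" and the top cluster "very
        # high" regardless of the restart that won
        order = np.argsort(
            [
                expected_engaged_days(A, best["emissions"], X.shape[1])
                for A in best["transitions"]
            ],
            kind="stable",
        )
        self.weights_ = best["weights"][order]
        self.transitions_ = best["transitions"][order]
        self.emissions_ = best["emissions"]
        self.responsibilities_ = best["resp"][:, order]
        self.labels_ = np.argmax(self.responsibilities_, axis=1)
        self.loglik_trace_ = best["trace"]
        self.n_iter_ = best["n_iter"]
        self.converged_ = best["converged"]
        self.lower_bound_ = float(best["trace"][-1])
        if best["history"] is not None:
            self.history_ = [
                {
                    "weights": h["weights"][order],
                    "transitions": h["transitions"][order],
                    "emissions": h["emissions"],
                    "loglik": h["loglik"],
                }
                for h in best["history"]
            ]
        return self

    def _posterior(self, X):
        X = self._validate_X(X)
        e = _emissions_lin(X, self.emissions_)
        _, _, comp_ll = _forward_all(X, e, self.transitions_)
        with np.errstate(divide="ignore"):
            logr = np.log(self.weights_)[None, :] + comp_ll
        total = logsumexp(logr, axis=1)
        return np.exp(logr - total[:, None]), total

    def predict_proba(self, X):
        """Posterior component membership for each sequence."""
        return self._posterior(X)[0]

    def predict(self, X):
        """Hard cluster labels (argmax responsibility, ties to lowest index)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def score(self, X, y=None):
        """Total log-likelihood of X under the fitted mixture."""
        return float(self._posterior(X)[1].sum())


def assign_clusters(responsibilities: np.ndarray, user_ids=None) -> pd.DataFrame:
    """Hard assignments from a responsibility matrix.

    Cluster = index of the maximal responsibility; ties break toward the
    lowest index.  Returns a DataFrame (user_id, cluster, max_responsibility).
    """
    responsibilities = np.asarray(responsibilities, dtype=float)
    labels = np.argmax(responsibilities, axis=1)
    if user_ids is None:
        user_ids = np.arange(len(labels))
    return pd.DataFrame(
        {
            "user_id": list(user_ids),
            "cluster": labels,
            "max_responsibility": responsibilities[np.arange(len(labels)), labels],
        }
    )


@dataclasses.dataclass
class ElbowSelection:
    """Audit record of elbow-method model-order selection."""

    candidate_K: list
    logliks: list
    chosen_K: int


def select_k_elbow(
    X,
    candidate_K: Sequence[int],
    *,
    plateau_frac: float = 0.02,
    curve_tol: float = 1e-6,
    **mixture_kwargs,
) -> ElbowSelection:
    """Choose the number of components at the elbow of the log-likelihood curve.

    Fits the mixture for each candidate K and locates the plateau of the
    fit-versus-complexity curve: the chosen K is the smallest interior
    candidate after which every marginal log-likelihood gain falls below
    ``plateau_frac`` of the curve's total rise.  On mixture data the raw
    gains decay roughly geometrically, so the point of maximal absolute
    curvature always sits at the first interior candidate regardless of the
    true order; the plateau criterion instead finds the order beyond which
    additional components stop explaining anything.  A curve with no
    plateau (e.g. perfectly linear) falls back to the smallest interior
    candidate.  Candidates must be sorted ascending with at least three
    entries.
    """
    candidate_K = list(candidate_K)
    if len(candidate_K) < 3:
        raise ValueError("need at least 3 candidate K values")
    if candidate_K != sorted(candidate_K):
        raise ValueError("candidate_K must be sorted ascending")
    logliks = []
    for K in candidate_K:
        est = MarkovChainMixture(n_components=K, **mixture_kwargs)
        est.fit(X)
        logliks.append(est.lower_bound_)
    ll = np.asarray(logliks)
    drops = np.diff(ll)
    if np.any(drops < -curve_tol * np.maximum(1.0, np.abs(ll[:-1]))):
        warnings.warn(
            "log-likelihood not monotone across candidate K; "
            "elbow selection proceeds on the observed curve",
            RuntimeWarning,
            stacklevel=2,
        )
    total_rise = max(float(ll[-1] - ll[0]), 1e-12)
    rel_gains = drops / total_rise
    chosen = candidate_K[1]  # fallback: no plateau detected
    for i in range(1, len(candidate_K) - 1):
        if np.all(rel_gains[i:] < plateau_frac):
            chosen = candidate_K[i]
            break
    return ElbowSelection(candidate_K=candidate_K, logliks=logliks, chosen_K=chosen)


def summarize_clusters(labels, X, n_clusters: int | None = None) -> pd.DataFrame:
    """Per-cluster summary of engaged-day counts.

    Returns one row per cluster with n, percent of users, mean, SD (sample
    SD; 0 for singleton clusters), median and IQR of the number of engaged
    days.  Empty clusters appear with n=0 and null statistics.
    """
    labels = np.asarray(labels)
    X = np.asarray(X).astype(bool)
    days = X.sum(axis=1)
    if n_clusters is None:
        n_clusters = int(labels.max()) + 1 if len(labels) else 0
    rows = []
    total = len(labels)
    for k in range(n_clusters):
        d = days[labels == k]
        if len(d) == 0:
            rows.append(
                dict(cluster=k, n=0, percent=0.0, mean=np.nan, sd=np.nan,
                     median=np.nan, iqr=np.nan)
            )
            continue
        sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
        q25, q75 = np.percentile(d, [25, 75])
        rows.append(
            dict(
                cluster=k,
                n=int(len(d)),
                percent=round(100.0 * len(d) / total, 1),
                mean=float(np.mean(d)),
                sd=sd,
                median=float(np.median(d)),
                iqr=float(q75 - q25),
            )
        )
    return pd.DataFrame(rows)
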