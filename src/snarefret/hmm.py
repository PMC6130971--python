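"""Per-molecule Gaussian-emission hidden Markov idealization.

Each molecule's FRET-efficiency trace is fitted independently by
Baum–Welch expectation-maximization with Gaussian emissions per state
(scaled forward-backward recursions, so underflow cannot occur on long
traces), then idealized by Viterbi decoding.  The fitted state means are
the molecule's FRET efficiencies; the per-frame transition matrix can be
converted to rates via ``k = -frame_rate * ln(p_stay)`` for reporting.

States are always reported sorted by fitted mean, so results are
invariant to permutations of the initial guesses.  A sigma floor keeps
EM from collapsing a state onto noiseless data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_LOG_2PI = float(np.log(2.0 * np.pi))


class InsufficientDataError(ValueError):
    """Trace has fewer analyzable frames than the configured minimum."""


@dataclass
class HmmFit:
    """Maximum-likelihood HMM fit for one molecule."""

    n_states: int
    means: np.ndarray
    sigmas: np.ndarray
    trans: np.ndarray          # row-stochastic per-frame transition matrix
    initial_probs: np.ndarray
    log_likelihood: float
    viterbi_path: np.ndarray   # per analyzable frame
    converged: bool
    n_iterations: int
    degenerate_states: list[int] = field(default_factory=list)
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def flagged(self) -> bool:
        return bool(self.degenerate_states) or not self.converged

    def occupancy(self) -> np.ndarray:
        """Fraction of frames the Viterbi path assigns to each state."""
        counts = np.bincount(self.viterbi_path, minlength=self.n_states)
        return counts / max(self.viterbi_path.size, 1)


def _emission_logprob(x: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """(T, K) Gaussian log-densities."""
    z = (x[:, None] - means[None, :]) / sigmas[None, :]
    return -0.5 * (z ** 2) - np.log(sigmas)[None, :] - 0.5 * _LOG_2PI


def _forward_backward(b: np.ndarray, trans: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward (Rabiner).  ``b`` is the (T, K) emission
    likelihood matrix, rescaled per frame by its max to avoid underflow
    before scaling kicks in.

    Returns (log_likelihood, gamma, xi_sum) where gamma[t] are posterior
    state probabilities and xi_sum[i, j] the expected transition counts.
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)

    a0 = pi * b[0]
    c[0] = a0.sum()
    alpha[0] = a0 / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ trans) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (trans @ (b[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    # expected transition counts: sum_t alpha[t] A b[t+1] beta[t+1] / c[t+1]
    w = b[1:] * beta[1:] / c[1:, None]
    xi_sum = trans * (alpha[:-1].T @ w)

    log_likelihood = float(np.sum(np.log(c)))
    return log_likelihood, gamma, xi_sum


def fit_hmm(efficiencies: np.ndarray, n_states: int,
            init_means: Sequence[float], *,
            tol: float = 1e-6, max_iter: int = 500,
            sigma_floor: float = 1e-3, min_frames: int = 20) -> HmmFit:
    """Baum–Welch fit of a Gaussian-emission HMM to one E trace.

    NaN frames (invalid/post-bleach) are dropped before fitting.  The
    initial transition matrix uses 0.95 self-transition probability with
    uniform off-diagonals and uniform initial state probabilities; sigmas
    start at the sample SD of the trace.  Iteration stops when the
    relative log-likelihood improvement falls below ``tol``.  The
    log-likelihood is non-decreasing by construction (EM).

    Raises :class:`InsufficientDataError` when fewer than ``min_frames``
    frames are available.  A state that captures (almost) no frames is
    reported in ``degenerate_states`` and the fit flagged, not raised.
    """
    x = np.asarray(efficiencies, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_frames:
        raise InsufficientDataError(
            f"{x.size} analyzable frames < minimum {min_frames}")
    if len(init_means) != n_states:
        raise ValueError("init_means length must equal n_states")

    K = n_states
    means = np.asarray(init_means, dtype=float).copy()
    sigmas = np.full(K, max(float(np.std(x)), sigma_floor))
    trans = np.full((K, K), 0.05 / max(K - 1, 1))
    np.fill_diagonal(trans, 0.95)
    pi = np.full(K, 1.0 / K)

    ll_prev = -np.inf
    ll_history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logb = _emission_logprob(x, means, sigmas)
        # per-frame rescaling keeps b in range; the constant cancels in
        # gamma/xi and is restored in the log-likelihood below
        shift = logb.max(axis=1, keepdims=True)
        b = np.exp(logb - shift)
        ll, gamma, xi_sum = _forward_backward(b, trans, pi)
        ll += float(shift.sum())
        ll_history.append(ll)

        # M-step
        occ = gamma.sum(axis=0)
        safe = np.maximum(occ, 1e-12)
        means_new = (gamma * x[:, None]).sum(axis=0) / safe
        var = (gamma * (x[:, None] - means_new[None, :]) ** 2).sum(axis=0) / safe
        sigmas_new = np.maximum(np.sqrt(var), sigma_floor)
        trans_new = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
        # a state with no expected transitions keeps its previous row
        empty_rows = xi_sum.sum(axis=1) < 1e-12
        trans_new[empty_rows] = trans[empty_rows]
        pi_new = gamma[0] / gamma[0].sum()

        means, sigmas, trans, pi = means_new, sigmas_new, trans_new, pi_new
        if np.isfinite(ll_prev):
            rel = (ll - ll_prev) / max(abs(ll_prev), 1.0)
            if abs(rel) < tol:
                converged = True
                ll_prev = ll
                break
        ll_prev = ll

    # sort states by fitted mean (resolves label switching)
    order = np.argsort(means)
    means, sigmas, pi = means[order], sigmas[order], pi[order]
    trans = trans[np.ix_(order, order)]

    path = viterbi(x, means, sigmas, trans, pi)
    counts = np.bincount(path, minlength=K)
    degenerate = [int(k) for k in range(K) if counts[k] == 0]
    if degenerate:
        warnings.warn(
            f"HMM fit has {len(degenerate)} unoccupied state(s); flagged")

    return HmmFit(K, means, sigmas, trans, pi, float(ll_prev), path,
                  converged, n_iter, degenerate, np.asarray(ll_history))


def viterbi(x: np.ndarray, means: np.ndarray, sigmas: np.ndarray,
            trans: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Most probable state sequence (log-space dynamic program)."""
    x = np.asarray(x, dtype=float)
    logb = _emission_logprob(x, np.asarray(means), np.asarray(sigmas))
    with np.errstate(divide="ignore"):
        log_a = np.log(np.asarray(trans, dtype=float))
        log_pi = np.log(np.asarray(pi, dtype=float))
    T, K = logb.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=int)
    delta[0] = log_pi + logb[0]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_a
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta[T - 1]))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def viterbi_decode(fit: HmmFit, efficiencies: np.ndarray) -> np.ndarray:
    """Decode an E trace under an existing fit (NaN frames dropped)."""
    x = np.asarray(efficiencies, dtype=float)
    x = x[np.isfinite(x)]
    return viterbi(x, fit.means, fit.sigmas, fit.trans, fit.initial_probs)


def loglik(x: np.ndarray, means, sigmas, trans, pi) -> float:
    """Observation log-likelihood under fixed parameters (scaled
    forward pass only); used for monotonicity checks."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    logb = _emission_logprob(x, np.asarray(means), np.asarray(sigmas))
    shift = logb.max(axis=1, keepdims=True)
    b = np.exp(logb - shift)
    ll, _, _ = _forward_backward(b, np.asarray(trans, dtype=float),
                                 np.asarray(pi, dtype=float))
    return ll + float(shift.sum())


def path_dwell_records(path: np.ndarray, means: np.ndarray,
                       frame_rate: float) -> list[tuple[float, float]]:
    """(fitted state E, dwell seconds) for every run in a Viterbi path."""
    out = []
    if path.size == 0:
        return out
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [path.size]])
    for a, b in zip(starts, stops):
        out.append((float(means[path[a]]), (b - a) / frame_rate))
    return out


def fitted_fret_distribution(fits: Sequence[HmmFit], frame_rate: float,
                             bins: int | np.ndarray = 50,
                             range_: tuple[float, float] = (-0.2, 1.2),
                             ) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Probability density of fitted state FRET values, weighted by frames
    occupied, plus the paired (fitted E, dwell time) scatter records.

    Mirrors the summary view of an HMM analysis: where the fitted states
    sit, and how long each visit lasted.
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged fits supplied")
    values, weights, records = [], [], []
    for f in good:
        occ = np.bincount(f.viterbi_path, minlength=f.n_states)
        for k in range(f.n_states):
            if occ[k] > 0:
                values.append(f.means[k])
                weights.append(occ[k])
        records.extend(path_dwell_records(f.viterbi_path, f.means, frame_rate))
    density, edges = np.histogram(values, bins=bins, range=range_,
                                  weights=weights, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density, records
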