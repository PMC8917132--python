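"""Hidden Markov model with independent Poisson emissions per neuron.

Each SWR contributes one observation sequence: spikes from N pyramidal
cells binned into non-overlapping 15-ms bins give a T x N count matrix.
The network is assumed to occupy one of M latent states per bin, with
first-order Markov transitions (initial distribution ``pi``, transition
matrix ``A``) and, within a state m, independent Poisson spike counts with
means ``Lambda[:, m]`` (one expected count per neuron per bin).

Fitting is by EM over multiple sequences; per-sequence log-likelihoods are
computed with the forward algorithm in log space (exact, no underflow),
and the sequence-similarity test compares normalized log-likelihoods of
held-out quintiles against refitted shuffled groupings.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io import validate_spikes

__all__ = [
    "PoissonHMMParams",
    "BinnedSequence",
    "HMMFit",
    "bin_swr_spikes",
    "poisson_log_emissions",
    "fit_poisson_hmm",
    "sequence_loglik",
    "loglik_brute_force",
    "CrossQuintileResult",
    "cross_quintile_hmm_test",
    "cv_select_states",
]

RATE_FLOOR = 1e-4
DEFAULT_BIN_MS = 15.0
DEFAULT_STATES = 15


@dataclass(frozen=True)
class PoissonHMMParams:
    """(pi, A, Lambda): initial probs (M,), transitions (M, M), expected
    counts per neuron and state (N, M)."""

    pi: np.ndarray
    A: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        A = np.asarray(self.A, dtype=float)
        lam = np.asarray(self.lam, dtype=float)
        M = pi.size
        if A.shape != (M, M) or lam.shape[1] != M:
            raise ValueError("inconsistent parameter shapes")
        if abs(pi.sum() - 1) > 1e-8 or np.any(np.abs(A.sum(1) - 1) > 1e-8):
            raise ValueError("pi and rows of A must sum to 1")
        if np.any(lam <= 0):
            raise ValueError("Lambda must be positive (rate floor)")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "lam", lam)

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def n_cells(self) -> int:
        return self.lam.shape[0]


@dataclass(frozen=True)
class BinnedSequence:
    """T x N spike counts for one SWR in ``bin_ms`` bins."""

    counts: np.ndarray
    bin_ms: float = DEFAULT_BIN_MS
    swr_id: object = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 1:
            raise ValueError("counts must be T x N with T >= 1")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.min() < 0:
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)


def bin_swr_spikes(spikes: pd.DataFrame, event, bin_ms: float = DEFAULT_BIN_MS,
                   cell_ids=None) -> BinnedSequence:
    """Bin one SWR's pyramidal spikes into 15-ms count vectors.

    ``T = ceil(duration / bin)`` bins cover [onset, onset + T * bin); all
    spikes in that span are conserved in the counts.
    """
    validate_spikes(spikes)
    pyr = spikes[spikes["cell_class"] == "pyr"]
    if cell_ids is None:
        cell_ids = sorted(pyr["cell_id"].unique())
    onset, offset = float(event["onset_s"]), float(event["offset_s"])
    bin_s = bin_ms / 1000.0
    T = max(int(np.ceil((offset - onset) / bin_s - 1e-9)), 1)
    edges = onset + np.arange(T + 1) * bin_s
    counts = np.zeros((T, len(cell_ids)), dtype=np.int64)
    for j, cell in enumerate(cell_ids):
        t = pyr.loc[pyr["cell_id"] == cell, "spike_time_s"].to_numpy()
        counts[:, j] = np.histogram(t, bins=edges)[0]
    return BinnedSequence(counts=counts, bin_ms=bin_ms,
                          swr_id=event.get("event_id"))


def poisson_log_emissions(counts: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """log P(y_t | state m) for every bin and state; shape (..., T, M)."""
    counts = np.asarray(counts, dtype=float)
    log_lam = np.log(lam)                           # N x M
    const = gammaln(counts + 1.0).sum(axis=-1)      # ...T
    return counts @ log_lam - lam.sum(axis=0) - const[..., None]


def _as_count_arrays(sequences) -> list[np.ndarray]:
    out = []
    for s in sequences:
        out.append(s.counts if isinstance(s, BinnedSequence) else
                   np.asarray(s, dtype=np.int64))
    return out


def _group_by_length(arrays):
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(arrays):
        groups.setdefault(a.shape[0], []).append(i)
    return groups


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


def _forward_backward_batch(loge: np.ndarray, log_pi: np.ndarray,
                            log_A: np.ndarray):
    """Batched log-space forward-backward for S sequences of equal length.

    ``loge`` is (S, T, M).  Returns (log_alpha, log_beta, ll) with
    ``ll`` shape (S,).
    """
    S, T, M = loge.shape
    la = np.empty((S, T, M))
    lb = np.zeros((S, T, M))
    la[:, 0] = log_pi + loge[:, 0]
    for t in range(1, T):
        la[:, t] = _lse(la[:, t - 1][:, :, None] + log_A[None], axis=1) \
            + loge[:, t]
    for t in range(T - 2, -1, -1):
        lb[:, t] = _lse(log_A[None] + (loge[:, t + 1] + lb[:, t + 1])[:, None, :],
                        axis=2)
    ll = _lse(la[:, -1], axis=1)
    return la, lb, ll


def sequence_loglik(seq, params: PoissonHMMParams) -> float:
    """Per-bin normalized log-likelihood log P(counts | params) / T."""
    counts = _as_count_arrays([seq])[0]
    loge = poisson_log_emissions(counts, params.lam)[None]
    _, _, ll = _forward_backward_batch(
        loge, np.log(params.pi), np.log(params.A))
    return float(ll[0]) / counts.shape[0]


def loglik_brute_force(seq, params: PoissonHMMParams) -> float:
    """Normalized log-likelihood by exhaustive state-path enumeration.

    Independent oracle for the forward algorithm; feasible for
    ``M ** T <= ~1e5``.
    """
    counts = _as_count_arrays([seq])[0]
    T, _ = counts.shape
    M = params.n_states
    loge = poisson_log_emissions(counts, params.lam)
    log_pi, log_A = np.log(params.pi), np.log(params.A)
    terms = []
    for path in product(range(M), repeat=T):
        lp = log_pi[path[0]] + loge[0, path[0]]
        for t in range(1, T):
            lp += log_A[path[t - 1], path[t]] + loge[t, path[t]]
        terms.append(lp)
    return float(logsumexp(terms)) / T


@dataclass(frozen=True)
class HMMFit:
    params: PoissonHMMParams
    loglik: float                # total LL over all training sequences
    ll_history: np.ndarray       # per-iteration LL of the winning restart
    n_iter: int
    converged: bool


def _init_params(arrays, M, rng) -> PoissonHMMParams:
    """Lambda from a random assignment of bins to states plus jitter;
    A near-uniform with a slight self-transition bias."""
    all_bins = np.concatenate(arrays, axis=0).astype(float)
    N = all_bins.shape[1]
    assign = rng.integers(0, M, size=all_bins.shape[0])
    global_mean = all_bins.mean(axis=0)
    lam = np.empty((N, M))
    for m in range(M):
        sel = all_bins[assign == m]
        mean = sel.mean(axis=0) if len(sel) else global_mean
        lam[:, m] = mean * (1.0 + 0.25 * rng.standard_normal(N))
    lam = np.maximum(np.abs(lam), RATE_FLOOR)
    self_bias = 0.1
    A = (1 - self_bias) * np.full((M, M), 1.0 / M) + self_bias * np.eye(M)
    pi = np.full(M, 1.0 / M)
    return PoissonHMMParams(pi=pi, A=A, lam=lam)


def _em_once(arrays, groups, M, init: PoissonHMMParams, tol, max_iter):
    pi, A, lam = init.pi.copy(), init.A.copy(), init.lam.copy()
    N = arrays[0].shape[1]
    history = []
    prev_ll = -np.inf
    converged = False
    stacked = {T: np.stack([arrays[i] for i in idx]).astype(float)
               for T, idx in groups.items()}
    for it in range(max_iter):
        log_pi, log_A = np.log(pi), np.log(A)
        pi_acc = np.zeros(M)
        A_num = np.zeros((M, M))
        lam_num = np.zeros((N, M))
        lam_den = np.zeros(M)
        total_ll = 0.0
        for T, batch in stacked.items():
            loge = poisson_log_emissions(batch, lam)
            la, lb, ll = _forward_backward_batch(loge, log_pi, log_A)
            total_ll += float(ll.sum())
            gamma = np.exp(la + lb - ll[:, None, None])     # S x T x M
            pi_acc += gamma[:, 0].sum(axis=0)
            if T > 1:
                xi = np.exp(la[:, :-1, :, None] + log_A[None, None] +
                            (loge + lb)[:, 1:, None, :] -
                            ll[:, None, None, None])
                A_num += xi.sum(axis=(0, 1))
            lam_num += np.einsum("stn,stm->nm", batch, gamma)
            lam_den += gamma.sum(axis=(0, 1))
        history.append(total_ll)

        pi = pi_acc / pi_acc.sum()
        row = A_num.sum(axis=1, keepdims=True)
        A = np.where(row > 0, A_num / np.where(row > 0, row, 1.0),
                     1.0 / M)
        lam = np.maximum(lam_num / np.maximum(lam_den, 1e-300), RATE_FLOOR)

        if it > 0 and abs(total_ll - prev_ll) < tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = total_ll
    params = PoissonHMMParams(pi=pi, A=A, lam=lam)
    # final LL under the updated parameters
    final_ll = sum(
        float(_forward_backward_batch(
            poisson_log_emissions(batch, lam), np.log(pi), np.log(A)
        )[2].sum()) for batch in stacked.values())
    history.append(final_ll)
    return params, np.asarray(history), converged


def fit_poisson_hmm(sequences, M: int = DEFAULT_STATES, n_restarts: int = 5,
                    tol: float = 1e-6, max_iter: int = 500,
                    seed=None) -> HMMFit:
    """EM fit over multiple binned sequences; best of ``n_restarts``.

    The log-likelihood is non-decreasing over iterations (a property of
    EM, asserted in the test suite to 1e-8 relative tolerance).
    Deterministic for a fixed seed and data.
    """
    arrays = _as_count_arrays(sequences)
    if not arrays:
        raise ValueError("need at least one sequence")
    groups = _group_by_length(arrays)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        init = _init_params(arrays, M, rng)
        params, history, converged = _em_once(arrays, groups, M, init,
                                              tol, max_iter)
        if best is None or history[-1] > best.loglik:
            best = HMMFit(params=params, loglik=float(history[-1]),
                          ll_history=history, n_iter=len(history) - 1,
                          converged=converged)
    return best


def mean_normalized_loglik(sequences, params: PoissonHMMParams) -> float:
    """Mean per-bin log-likelihood across sequences."""
    return float(np.mean([sequence_loglik(s, params) for s in sequences]))


@dataclass(frozen=True)
class CrossQuintileResult:
    observed: np.ndarray     # [LL(Q5|m1)-LL(Q1|m1), LL(Q1|m5)-LL(Q5|m5)]
    shuffled: np.ndarray     # n_shuffles x 2
    p_one_sided: float       # P(shuffled mean <= observed mean)


def cross_quintile_hmm_test(q1_seqs, q5_seqs, M: int = DEFAULT_STATES,
                            n_shuffles: int = 100, seed=None,
                            n_restarts: int = 2, tol: float = 1e-5,
                            max_iter: int = 200) -> CrossQuintileResult:
    """Sequence-similarity test between high- and low-inhibition quintiles.

    Fits an HMM to each quintile and evaluates the difference of mean
    normalized log-likelihoods LL(Q_test) - LL(Q_train) in both directions;
    a negative value means the model captures its own training quintile
    better.  The control refits after randomly reassigning SWRs to groups
    (sizes preserved), and the one-sided p-value asks whether the observed
    mean difference is lower than expected under shuffling.
    """
    q1 = _as_count_arrays(q1_seqs)
    q5 = _as_count_arrays(q5_seqs)
    if len(q1) < 2 or len(q5) < 2:
        raise ValueError("each quintile needs at least 2 sequences")
    rng = np.random.default_rng(seed)

    def _pair_diffs(group_a, group_b, fit_seed):
        fa = fit_poisson_hmm(group_a, M=M, n_restarts=n_restarts, tol=tol,
                             max_iter=max_iter, seed=fit_seed)
        fb = fit_poisson_hmm(group_b, M=M, n_restarts=n_restarts, tol=tol,
                             max_iter=max_iter, seed=fit_seed + 1)
        d_ab = mean_normalized_loglik(group_b, fa.params) - \
            mean_normalized_loglik(group_a, fa.params)
        d_ba = mean_normalized_loglik(group_a, fb.params) - \
            mean_normalized_loglik(group_b, fb.params)
        return np.array([d_ab, d_ba])

    observed = _pair_diffs(q1, q5, int(rng.integers(2 ** 31)))
    pooled = q1 + q5
    shuffled = np.empty((n_shuffles, 2))
    for s in range(n_shuffles):
        perm = rng.permutation(len(pooled))
        ga = [pooled[i] for i in perm[:len(q1)]]
        gb = [pooled[i] for i in perm[len(q1):]]
        shuffled[s] = _pair_diffs(ga, gb, int(rng.integers(2 ** 31)))

    obs_mean = observed.mean()
    shuf_means = shuffled.mean(axis=1)
    p = (1 + np.sum(shuf_means <= obs_mean)) / (n_shuffles + 1)
    return CrossQuintileResult(observed=observed, shuffled=shuffled,
                               p_one_sided=float(p))


def cv_select_states(sequences, M_grid=(5, 10, 15, 20), n_folds: int = 2,
                     seed=None, **fit_kw) -> tuple[int, pd.Series]:
    """Twofold (by default) cross-validation over the number of states.

    Returns the M with the highest mean held-out normalized log-likelihood
    and the full curve.  Provided as an optional helper; downstream
    analyses fix M = 15.
    """
    arrays = _as_count_arrays(sequences)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(arrays))
    folds = np.array_split(perm, n_folds)
    scores = {}
    for M in M_grid:
        vals = []
        for f in range(n_folds):
            test_idx = set(folds[f].tolist())
            train = [arrays[i] for i in perm if i not in test_idx]
            test = [arrays[i] for i in sorted(test_idx)]
            fit = fit_poisson_hmm(train, M=M,
                                  seed=int(rng.integers(2 ** 31)), **fit_kw)
            vals.append(mean_normalized_loglik(test, fit.params))
        scores[M] = float(np.mean(vals))
    curve = pd.Series(scores, name="mean_test_loglik")
    return int(curve.idxmax()), curve
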