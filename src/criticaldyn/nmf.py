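"""Non-negative matrix factorization of network stimulation responses.

Per-trial line-length responses of all channels are stacked into a
nonnegative matrix V (channels x stimulations) and factorized as
V ~ W H with multiplicative updates for the Frobenius objective.  Columns
of W are sub-networks of channels that respond together; rows of H carry
the per-stimulation activation of each sub-network.  The factorization
rank is chosen by a stability analysis over random restarts; components
whose activation increases with stimulation intensity are the responsive
sub-networks, and their mean activation per intensity yields a network
input-output curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .probing import InputOutputCurve, evoked_response, input_output_curve
from .synthetic import Recording

_EPS = 1e-12


@dataclass
class ResponseMatrix:
    V: NDArray[np.float64]  # channels x stimulations, LL values
    intensity: NDArray[np.float64]  # per column
    session: NDArray  # per column
    condition: NDArray  # per column
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if np.any(self.V < 0):
            raise ValueError("response matrix must be nonnegative")
        if self.V.shape[1] != len(self.intensity):
            raise ValueError("column metadata must match stimulation count")


@dataclass
class NMFDecomposition:
    W: NDArray[np.float64]  # channels x rank, columns sum to 1
    H: NDArray[np.float64]  # rank x stimulations
    rank: int
    reconstruction_error: float
    error_trace: NDArray[np.float64]
    n_restarts: int
    seed: int


def build_response_matrix(
    recordings: Sequence[Recording], site: str = "S1",
    screen_mask: bool = True,
) -> ResponseMatrix:
    """Stack per-channel 250 ms LL responses of single-pulse trials."""
    from .probing import response_screen_mask

    cols, inten, sess, cond = [], [], [], []
    labels = None
    for s_idx, rec in enumerate(recordings):
        events = [e for e in rec.events if e.site == site]
        if labels is None:
            labels = list(rec.channel_labels)
        elif labels != list(rec.channel_labels):
            raise ValueError("channel sets differ across recordings")
        for e in events:
            cols.append([evoked_response(rec, e, c)
                         for c in range(rec.n_channels)])
            inten.append(e.intensity)
            sess.append(s_idx)
            cond.append(rec.condition)
    if not cols:
        raise ValueError(f"no stimulation events for site {site!r}")
    V = np.array(cols).T
    inten_a = np.array(inten, dtype=float)
    sess_a, cond_a = np.array(sess), np.array(cond)
    if screen_mask:
        keep = np.ones(V.shape[1], dtype=bool)
        mean_ll = V.mean(axis=0)
        for s in np.unique(sess_a):
            for v in np.unique(inten_a):
                grp = (sess_a == s) & (inten_a == v)
                keep[grp] &= response_screen_mask(mean_ll[grp])
        V, inten_a = V[:, keep], inten_a[keep]
        sess_a, cond_a = sess_a[keep], cond_a[keep]
    return ResponseMatrix(V, inten_a, sess_a, cond_a, labels)


def _mu_factorize(
    V: NDArray[np.float64], rank: int, rng: np.random.Generator,
    max_iter: int = 1000, tol: float = 1e-6,
) -> tuple[NDArray, NDArray, NDArray]:
    """Lee-Seung multiplicative updates for ||V - WH||_F from one init."""
    n, m = V.shape
    scale = np.sqrt(V.mean() / max(rank, 1))
    W = rng.uniform(0.1, 1.0, size=(n, rank)) * scale
    H = rng.uniform(0.1, 1.0, size=(rank, m)) * scale
    errs = []
    prev = None
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        err = float(np.linalg.norm(V - W @ H))
        errs.append(err)
        if prev is not None and prev - err < tol * max(prev, _EPS):
            break
        prev = err
    return W, H, np.array(errs)


def nmf_decompose(
    V: NDArray[np.float64], rank: int, n_restarts: int = 20, seed: int = 0,
    max_iter: int = 1000, tol: float = 1e-6,
) -> NMFDecomposition:
    """Best-of-restarts multiplicative-update NMF.

    Dead (all-zero) channels are removed before factorization and
    reinstated as zero weight rows.  W columns are normalized to unit sum
    so H carries the amplitude; per-iteration Frobenius error is monotone
    non-increasing and recorded in ``error_trace``.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("NMF input must be nonnegative")
    alive = V.sum(axis=1) > 0
    Va = V[alive]
    if rank > min(Va.shape):
        raise ValueError(f"rank {rank} exceeds matrix dimensions {Va.shape}")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        W, H, errs = _mu_factorize(Va, rank, rng, max_iter, tol)
        if best is None or errs[-1] < best[2][-1]:
            best = (W, H, errs)
    W, H, errs = best
    # scale-invariance: push column scales of W into H
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    H = H * colsum[:, None]
    W_full = np.zeros((V.shape[0], rank))
    W_full[alive] = W
    return NMFDecomposition(
        W=W_full, H=H, rank=rank,
        reconstruction_error=float(errs[-1]), error_trace=errs,
        n_restarts=n_restarts, seed=seed,
    )


def _matched_similarities(Wa: NDArray, Wb: NDArray) -> NDArray:
    """Cosine similarities of optimally paired columns of Wa, Wb."""
    A = Wa / (np.linalg.norm(Wa, axis=0, keepdims=True) + _EPS)
    B = Wb / (np.linalg.norm(Wb, axis=0, keepdims=True) + _EPS)
    S = A.T @ B
    ri, ci = linear_sum_assignment(-S)
    return S[ri, ci]


def _best_match_similarity(Wa: NDArray, Wb: NDArray) -> float:
    """Mean cosine similarity of optimally paired columns of Wa, Wb."""
    return float(_matched_similarities(Wa, Wb).mean())


def select_rank_stability(
    V: NDArray[np.float64], rank_range: Sequence[int] = range(2, 9),
    n_restarts: int = 10, seed: int = 0, threshold: float = 0.9,
) -> tuple[int, dict[int, float]]:
    """Largest rank whose restart-to-restart W similarity exceeds threshold.

    Stability per rank is the cosine similarity of the *worst* optimally
    matched W column, averaged across pairs of independently initialized
    factorizations.  The worst column is the sharp statistic: beyond the
    true rank at least one column fits noise and varies across restarts,
    while the mean stays deceptively high for sparse nonnegative blocks.
    Returns (rank, per-rank scores); rank 1 with a warning when no
    candidate is stable.
    """
    import logging

    V = np.asarray(V, dtype=float)
    ss = np.random.SeedSequence(seed)
    scores: dict[int, float] = {}
    for rank in rank_range:
        if rank > min(V.shape):
            break
        Ws = []
        for child in ss.spawn(n_restarts):
            rng = np.random.default_rng(child)
            W, _, _ = _mu_factorize(V, rank, rng)
            Ws.append(W)
        sims = [
            float(_matched_similarities(Ws[i], Ws[j]).min())
            for i in range(len(Ws)) for j in range(i + 1, len(Ws))
        ]
        scores[rank] = float(np.mean(sims))
    stable = [r for r, s in scores.items() if s > threshold]
    if not stable:
        logging.getLogger(__name__).warning(
            "no rank in %s passes stability %.2f; falling back to rank 1",
            list(scores), threshold)
        return 1, scores
    return max(stable), scores


def select_responsive_subnetworks(
    decomp: NMFDecomposition, intensities: NDArray[np.float64],
    alpha: float = 0.05,
) -> list[int]:
    """Components whose mean activation increases with intensity.

    One-sided Spearman rank test of mean H per intensity level against the
    level; components failing the test are background.
    """
    intensities = np.asarray(intensities, dtype=float)
    levels = np.unique(intensities)
    keep = []
    for k in range(decomp.rank):
        means = np.array([decomp.H[k, intensities == v].mean() for v in levels])
        if np.allclose(means, means[0]):
            continue
        rho, p_two = stats.spearmanr(levels, means)
        p_one = p_two / 2 if rho > 0 else 1 - p_two / 2
        if rho > 0 and p_one < alpha:
            keep.append(k)
    return keep


def network_ioc(
    decomp: NMFDecomposition,
    component: int,
    intensities: NDArray[np.float64],
    mask: NDArray[np.bool_] | None = None,
    normalization: float | str = "max",
) -> InputOutputCurve:
    """Input-output curve of one sub-network's H activation."""
    intensities = np.asarray(intensities, dtype=float)
    h = decomp.H[component]
    if mask is not None:
        h, intensities = h[mask], intensities[mask]
    return input_output_curve(intensities, h, site=f"component{component}",
                              normalization=normalization)
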