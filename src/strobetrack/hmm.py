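"""Hidden-Markov diffusion-state inference on displacement sequences.

Each trajectory contributes a sequence of frame-to-frame displacement
vectors (dx, dy).  Conditional on the hidden state k, a displacement is
isotropic Gaussian with per-axis variance 2 D_k dt; states evolve by a
per-frame transition matrix A.  Parameters (D, A, pi) are estimated by
maximum-likelihood EM (scaled forward-backward) over 1-3 state models,
with multiple seeded restarts, and the state count is chosen by BIC.

Bridged detection gaps contribute no emission: the chain is propagated
across a gap by powering A with the gap length.  Expected transition
counts for the A update are accumulated over unit-frame transitions
only (the exact E-step for compound transitions is not needed at the
gap rates this pipeline produces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track import Trajectory

__all__ = ["HMMResult", "displacement_sequences", "hmm_fit", "select_K", "occupancy"]


@dataclass
class HMMResult:
    """Fitted K-state displacement HMM (states sorted by D)."""

    K: int
    D: np.ndarray  # um^2/s, ascending
    A: np.ndarray  # K x K per-frame transition matrix
    pi: np.ndarray  # initial distribution
    occupancy: np.ndarray  # mean posterior state fraction over steps
    log_likelihood: float
    bic: float
    n_steps: int

    def stationary_distribution(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.A.T)
        i = np.argmin(np.abs(vals - 1.0))
        p = np.real(vecs[:, i])
        return p / p.sum()


def displacement_sequences(
    trajs: list[Trajectory], pixel_size_nm: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-trajectory (displacements um, frame gaps) for the HMM.

    Displacements spanning bridged gaps are dropped as emissions; the
    returned gap array gives, per kept displacement, the number of frames
    since the previous kept displacement (1 = consecutive).
    """
    px = pixel_size_nm / 1000.0
    out = []
    for t in trajs:
        df = np.diff(t.frames)
        d = np.column_stack([np.diff(t.x), np.diff(t.y)]) * px
        keep = df == 1
        if not keep.any():
            continue
        idx = np.nonzero(keep)[0]
        gaps = np.empty(len(idx), dtype=int)
        gaps[0] = 1
        ends = t.frames[1:][idx]
        gaps[1:] = np.diff(ends)
        out.append((d[idx], gaps))
    return out


def _pack(seqs: list[tuple[np.ndarray, np.ndarray]]):
    S = len(seqs)
    T = max(len(d) for d, _ in seqs)
    r2 = np.zeros((S, T))
    gaps = np.ones((S, T), dtype=int)
    mask = np.zeros((S, T), dtype=bool)
    for i, (d, g) in enumerate(seqs):
        n = len(d)
        r2[i, :n] = (d**2).sum(axis=1)
        gaps[i, :n] = g
        mask[i, :n] = True
    return r2, gaps, mask


def _log_emissions(r2: np.ndarray, D: np.ndarray, dt: float) -> np.ndarray:
    # (S, T, K): isotropic 2D Gaussian displacement density
    v = 2.0 * D * dt  # per-axis variance
    return -r2[..., None] / (2.0 * v) - np.log(2.0 * np.pi * v)


def _forward_backward(r2, gaps, mask, D, A, pi, dt):
    """Scaled forward-backward over a padded batch.

    Returns log-likelihood, posteriors gamma (S,T,K) and expected
    unit-transition counts xi_sum (K,K).
    """
    S, T = r2.shape
    K = len(D)
    logB = _log_emissions(r2, D, dt)
    Bmax = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - Bmax)  # scaled emissions
    max_g = int(gaps[mask].max()) if mask.any() else 1
    A_pows = [None, A.copy()]
    for g in range(2, max_g + 1):
        A_pows.append(A_pows[-1] @ A)
    alpha = np.zeros((S, T, K))
    c = np.ones((S, T))
    a = pi[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0:1]
    for t in range(1, T):
        trans = np.empty((S, K, K))
        gt = gaps[:, t]
        for g in np.unique(gt):
            trans[gt == g] = A_pows[g]
        pred = np.einsum("sk,skj->sj", alpha[:, t - 1], trans)
        a = np.where(mask[:, t : t + 1], pred * B[:, t, :], alpha[:, t - 1])
        tot = a.sum(axis=1)
        tot = np.where(mask[:, t], tot, 1.0)
        c[:, t] = tot
        alpha[:, t] = a / tot[:, None]
    loglik = float((np.log(c)[mask] + Bmax[..., 0][mask]).sum())

    beta = np.zeros((S, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        nxt = beta[:, t + 1] * B[:, t + 1, :]
        trans = np.empty((S, K, K))
        gt = gaps[:, t + 1]
        for g in np.unique(gt):
            trans[gt == g] = A_pows[g]
        val = np.einsum("skj,sj->sk", trans, nxt) / c[:, t + 1 : t + 2]
        live = mask[:, t + 1]
        beta[:, t] = np.where(live[:, None], val, beta[:, t + 1])
        # unit-gap expected transition counts
        u = live & (gaps[:, t + 1] == 1)
        if u.any():
            xi = (
                alpha[u, t, :, None]
                * A[None, :, :]
                * (B[u, t + 1, None, :] * beta[u, t + 1, None, :])
                / c[u, t + 1, None, None]
            )
            xi_sum += xi.sum(axis=0)
    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=2, keepdims=True), 1e-300)
    gamma[~mask] = 0.0
    return loglik, gamma, xi_sum


def hmm_fit(
    seqs: list[tuple[np.ndarray, np.ndarray]] | list[np.ndarray],
    dt: float,
    K: int,
    n_starts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-7,
    rng: np.random.Generator | int = 0,
    loc_error_um: float = 0.0,
) -> HMMResult:
    """EM fit of the K-state displacement HMM; best of ``n_starts`` restarts.

    ``seqs`` holds per-trajectory displacement arrays (n_i, 2) in um,
    optionally paired with frame-gap arrays.  D is initialized from
    quantiles of r^2/(4 dt), A sticky (0.9 diagonal); restarts jitter the
    initialization.  With ``loc_error_um`` set, 2 sigma^2 is added to the
    emission variance (the reported D is corrected back).
    """
    if not 1 <= K <= 3:
        raise ValueError("K must be between 1 and 3")
    norm: list[tuple[np.ndarray, np.ndarray]] = []
    for s in seqs:
        if isinstance(s, tuple):
            norm.append((np.asarray(s[0], dtype=float), np.asarray(s[1], dtype=int)))
        else:
            d = np.asarray(s, dtype=float)
            norm.append((d, np.ones(len(d), dtype=int)))
    if not norm or any(len(d) < 1 for d, _ in norm):
        raise ValueError("every sequence must contain at least one displacement")
    rng = np.random.default_rng(rng)
    r2, gaps, mask = _pack(norm)
    n_steps = int(mask.sum())
    d_eq = r2[mask] / (4.0 * dt)
    qs = np.quantile(d_eq, np.linspace(0.2, 0.85, K))
    qs = np.maximum(qs, 1e-6)
    shift = 2.0 * loc_error_um**2 / (2.0 * dt)  # emission-variance offset as D

    best = None
    for start in range(n_starts):
        D = qs * np.exp(rng.normal(0.0, 0.4 if start else 0.0, K))
        A = np.full((K, K), 0.1 / max(K - 1, 1))
        np.fill_diagonal(A, 0.9)
        if K == 1:
            A = np.ones((1, 1))
        pi = np.full(K, 1.0 / K)
        prev = -np.inf
        for _ in range(max_iter):
            loglik, gamma, xi = _forward_backward(r2, gaps, mask, D + shift, A, pi, dt)
            # M-step
            g = gamma[mask]  # (n_steps, K)
            wsum = g.sum(axis=0)
            D_new = (g * r2[mask][:, None]).sum(axis=0) / (4.0 * dt * np.maximum(wsum, 1e-300))
            D = np.maximum(D_new - shift, 1e-6)
            if K > 1:
                rows = xi.sum(axis=1, keepdims=True)
                A = np.where(rows > 1e-300, xi / np.maximum(rows, 1e-300), 1.0 / K)
                A /= A.sum(axis=1, keepdims=True)
            pi = gamma[:, 0, :].mean(axis=0)
            pi = pi / pi.sum()
            if abs(loglik - prev) < tol * max(abs(loglik), 1.0):
                break
            prev = loglik
        loglik, gamma, _ = _forward_backward(r2, gaps, mask, D + shift, A, pi, dt)
        if best is None or loglik > best[0]:
            best = (loglik, D.copy(), A.copy(), pi.copy(), gamma.copy())
    loglik, D, A, pi, gamma = best
    order = np.argsort(D)
    D, pi = D[order], pi[order]
    A = A[np.ix_(order, order)]
    occ = gamma[mask][:, order].mean(axis=0)
    p = (K - 1) + K * (K - 1) + K
    bic = -2.0 * loglik + p * np.log(n_steps)
    return HMMResult(
        K=K,
        D=D,
        A=A,
        pi=pi,
        occupancy=occ,
        log_likelihood=loglik,
        bic=float(bic),
        n_steps=n_steps,
    )


def select_K(results: dict[int, HMMResult] | list[HMMResult]) -> int:
    """Choose the state count with minimal BIC (ties -> smallest K)."""
    if isinstance(results, dict):
        items = sorted(results.items())
    else:
        items = sorted((r.K, r) for r in results)
    best_k, best_bic = items[0][0], items[0][1].bic
    for k, r in items[1:]:
        if r.bic < best_bic - 1e-12:
            best_k, best_bic = k, r.bic
    return best_k


def occupancy(result: HMMResult) -> np.ndarray:
    """Per-state expected fraction of steps (posterior gamma average)."""
    return result.occupancy
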