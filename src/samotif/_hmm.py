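"""Gaussian hidden-Markov machinery used by the alphabet module.

Implements the classic scaled forward–backward recursions, batched over
sequences of equal length so that expectation–maximisation on corpora
of ~1e5 observations stays fast in numpy.  Emissions are full-covariance
multivariate Gaussians with a ridge term ``reg * I`` added to every
covariance at each M-step.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.cluster import KMeans


class EmptyStateError(RuntimeError):
    """A state lost all responsibility mass (empty cluster) during EM."""


def log_gaussian_density(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log N(x | mean_k, cov_k) for all points and states -> (N, K)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, D = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        try:
            c, low = cho_factor(covs[k], lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise EmptyStateError(f"singular covariance for state {k}") from exc
        diff = X - means[k]
        sol = cho_solve((c, low), diff.T)
        maha = np.einsum("ij,ji->i", diff, sol)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        out[:, k] = -0.5 * (D * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _group_by_length(seqs: list[np.ndarray]) -> dict[int, np.ndarray]:
    groups: dict[int, list[np.ndarray]] = {}
    for s in seqs:
        groups.setdefault(len(s), []).append(np.asarray(s, dtype=float))
    return {T: np.stack(g) for T, g in groups.items() if T > 0}


def _forward_backward_batch(logb: np.ndarray, trans: np.ndarray, init: np.ndarray):
    """Scaled forward–backward for a (B, T, K) batch of emission log-densities.

    Returns (loglik_total, gamma (B,T,K), xi_sum (K,K) summed over batch
    and time, gamma0_sum (K,)).
    """
    B, T, K = logb.shape
    # shift emissions per (b, t) to avoid underflow; the shift folds into loglik
    shift = logb.max(axis=2, keepdims=True)
    b = np.exp(logb - shift)

    alpha = np.empty((B, T, K))
    c = np.empty((B, T))
    a = init[None, :] * b[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ trans) * b[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    if not np.all(c > 0):
        raise EmptyStateError("zero forward mass (numerical underflow)")
    loglik = float(np.sum(np.log(c)) + np.sum(shift))

    beta = np.empty((B, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        nxt = b[:, t + 1] * beta[:, t + 1]
        # xi(b, i, j) ∝ alpha[t,i] trans[i,j] nxt[j] / c[t+1]
        w = nxt / c[:, t + 1, None]
        xi_sum += trans * (alpha[:, t].T @ w)
        beta[:, t] = (w @ trans.T)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return loglik, gamma, xi_sum, gamma[:, 0].sum(axis=0)


def em_fit(
    seqs: list[np.ndarray],
    K: int,
    seed: int,
    reg: float = 1e-6,
    n_iter: int = 200,
    tol: float = 1e-6,
):
    """One Baum–Welch run from a k-means start.

    Returns ``(means, covs, trans, init, loglik_history)``.  The
    log-likelihood is asserted non-decreasing across iterations (up to
    a tiny relative slack for floating point).
    Raises :class:`EmptyStateError` when a state collapses.
    """
    rng = np.random.default_rng(seed)
    X = np.concatenate([np.asarray(s, dtype=float) for s in seqs], axis=0)
    N, D = X.shape
    if N < K:
        raise ValueError("fewer observations than states")

    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(X)
    means = km.cluster_centers_.copy()
    covs = np.empty((K, D, D))
    pooled = np.cov(X.T) + reg * np.eye(D)
    for k in range(K):
        pts = X[labels == k]
        if len(pts) > D + 1:
            covs[k] = np.cov(pts.T) + reg * np.eye(D)
        else:
            covs[k] = pooled
    trans = np.full((K, K), 1.0 / K) + 0.05 * rng.dirichlet(np.ones(K), size=K)
    trans /= trans.sum(axis=1, keepdims=True)
    init = np.full(K, 1.0 / K)

    batches = _group_by_length(seqs)
    history: list[float] = []
    for _ in range(n_iter):
        ll = 0.0
        g_sum = np.zeros(K)
        g0_sum = np.zeros(K)
        xi_tot = np.zeros((K, K))
        gx = np.zeros((K, D))
        gxx = np.zeros((K, D, D))
        for T, batch in batches.items():
            B = batch.shape[0]
            flat = batch.reshape(B * T, D)
            logb = log_gaussian_density(flat, means, covs).reshape(B, T, K)
            ll_b, gamma, xi, g0 = _forward_backward_batch(logb, trans, init)
            ll += ll_b
            gflat = gamma.reshape(B * T, K)
            g_sum += gflat.sum(axis=0)
            g0_sum += g0
            xi_tot += xi
            gx += gflat.T @ flat
            gxx += np.einsum("nk,ni,nj->kij", gflat, flat, flat)
        if history:
            assert ll >= history[-1] - 1e-8 * max(1.0, abs(history[-1])), (
                "EM log-likelihood decreased"
            )
        converged = bool(history) and (ll - history[-1]) < tol * max(1.0, abs(ll))
        history.append(ll)

        if np.any(g_sum < 1e-10 * len(X)):
            raise EmptyStateError("state with (near-)zero responsibility")
        means = gx / g_sum[:, None]
        for k in range(K):
            cov = gxx[k] / g_sum[k] - np.outer(means[k], means[k])
            covs[k] = 0.5 * (cov + cov.T) + reg * np.eye(D)
            try:
                np.linalg.cholesky(covs[k])
            except np.linalg.LinAlgError as exc:
                raise EmptyStateError("singular covariance in M-step") from exc
        rows = xi_tot.sum(axis=1)
        if np.any(rows <= 0):
            raise EmptyStateError("state never left in E-step")
        trans = xi_tot / rows[:, None]
        init = g0_sum / g0_sum.sum()
        if converged:
            break
    return means, covs, trans, init, history


def total_loglik(
    seqs: list[np.ndarray],
    means: np.ndarray,
    covs: np.ndarray,
    trans: np.ndarray,
    init: np.ndarray,
) -> float:
    ll = 0.0
    for T, batch in _group_by_length(seqs).items():
        B = batch.shape[0]
        D = batch.shape[2]
        logb = log_gaussian_density(batch.reshape(B * T, D), means, covs).reshape(B, T, K := len(init))
        ll += _forward_backward_batch(logb, trans, init)[0]
    return ll


def viterbi_path(logb: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray) -> np.ndarray:
    """Joint-MAP state path; ties broken toward the lowest state index
    (``argmax`` keeps the first maximum)."""
    T, K = logb.shape
    delta = log_init + logb[0]
    psi = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path
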