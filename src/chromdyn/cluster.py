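"""Temporal archetype clustering of dynamic accessibility profiles.

Peaks passing an inclusive likelihood-ratio cut and lying outside promoter
windows are clustered with a Gaussian-process mixture: each cluster has a
latent mean trajectory with a squared-exponential GP prior, observations
are the replicate-averaged normalised profiles with i.i.d. Gaussian noise,
and assignments are estimated by EM on the penalised likelihood (the GP
prior acts as a smoothness penalty on cluster means). The objective is
monotone over EM iterations by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._normalize import transform_times

__all__ = ["GaussianProcessMixture", "prefilter_for_clustering", "cluster_profiles"]


def prefilter_for_clustering(
    calls: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    lr_threshold: float = 1.0,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 500,
) -> list[str]:
    """Select peaks for clustering: inclusive LR cut, promoters excluded.

    A peak is retained iff its dynamic-over-static improvement satisfies
    ``lr > lr_threshold`` (more inclusive than the chi-square cut) and its
    interval does not intersect any gene's strand-aware promoter window
    ([TSS - upstream, TSS + downstream] on the gene's strand).
    """
    if not {"+", "-"}.issuperset(set(genes["strand"])):
        bad = sorted(set(genes["strand"]) - {"+", "-"})
        raise ValueError(f"unknown gene strand(s): {bad}")
    wins = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            wins.append((g["chrom"], g["tss"] - promoter_upstream, g["tss"] + promoter_downstream))
        else:
            wins.append((g["chrom"], g["tss"] - promoter_downstream, g["tss"] + promoter_upstream))
    retained = []
    lr = calls["lr"]
    for _, pk in peaks.iterrows():
        pid = pk["peak_id"]
        if pid not in lr.index or not lr.loc[pid] > lr_threshold:
            continue
        hits_promoter = any(
            c == pk["chrom"] and pk["start"] < e and s < pk["end"] for c, s, e in wins
        )
        if not hits_promoter:
            retained.append(pid)
    return retained


class GaussianProcessMixture:
    """Mixture of Gaussian-process mean trajectories, fitted by EM.

    Parameters
    ----------
    n_components : int
        Number of temporal archetypes K.
    length_scale : float or None
        Lengthscale of the squared-exponential prior on cluster means, on
        the transformed time axis; ``None`` uses 0.3x the axis span.
    signal_variance : float
        Prior amplitude of cluster-mean trajectories.
    max_iter, tol : EM stopping rule (relative objective change).
    random_state : seed for the k-means initialisation.

    Attributes (after ``fit``)
    --------------------------
    responsibilities_ : (N, K) array, rows sum to 1.
    cluster_means_ : (K, T) latent mean per cluster on the time grid.
    labels_ : argmax assignments; weights_ : mixing proportions;
    noise_variance_ : fitted observation noise; converged_ : bool;
    objective_trace_ : per-iteration penalised log-likelihood.
    """

    def __init__(self, n_components: int = 6, length_scale: float | None = None,
                 signal_variance: float = 1.0, max_iter: int = 500, tol: float = 1e-6,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.length_scale = length_scale
        self.signal_variance = signal_variance
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_components": self.n_components, "length_scale": self.length_scale,
            "signal_variance": self.signal_variance, "max_iter": self.max_iter,
            "tol": self.tol, "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # --- EM internals --------------------------------------------------
    def _prior(self, t_axis: np.ndarray) -> np.ndarray:
        span = float(t_axis.max() - t_axis.min()) or 1.0
        ell = self.length_scale if self.length_scale is not None else 0.3 * span
        d2 = (t_axis[:, None] - t_axis[None, :]) ** 2
        return self.signal_variance * np.exp(-0.5 * d2 / ell**2) + 1e-8 * np.eye(len(t_axis))

    def _objective(self, X, F, R, pi, s2, Kp_inv, logdet_Kp):
        N, T = X.shape
        # E_q[log p(X, Z | F)] + H(q) + log p(F)
        log_lik = np.zeros((N, self.n_components))
        for k in range(self.n_components):
            resid = X - F[k]
            log_lik[:, k] = (
                np.log(pi[k] + 1e-300)
                - 0.5 * np.sum(resid**2, axis=1) / s2
                - 0.5 * T * np.log(2 * np.pi * s2)
            )
        ent = -np.sum(R * np.log(R + 1e-300))
        prior = sum(
            -0.5 * float(F[k] @ Kp_inv @ F[k]) - 0.5 * logdet_Kp - 0.5 * F.shape[1] * np.log(2 * np.pi)
            for k in range(self.n_components)
        )
        return float(np.sum(R * log_lik) + ent + prior)

    def fit(self, X: np.ndarray, times=None):
        """Fit on N x T profile matrix (normalised, replicate-averaged)."""
        X = np.asarray(X, dtype=float)
        N, T = X.shape
        K = self.n_components
        if K < 1 or K > N:
            raise ValueError("n_components must be in [1, n_profiles]")
        t_axis = (
            transform_times(np.asarray(times, dtype=float))
            if times is not None
            else np.arange(T, dtype=float)
        )
        Kp = self._prior(t_axis)
        Kp_inv = np.linalg.inv(Kp)
        logdet_Kp = float(np.linalg.slogdet(Kp)[1])

        if K == 1:
            labels = np.zeros(N, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=10, random_state=self.random_state)
            labels = km.fit_predict(X)
        R = np.zeros((N, K))
        R[np.arange(N), labels] = 1.0
        pi = R.mean(axis=0)
        s2 = max(float(np.var(X)) / 4.0, 1e-6)
        F = np.zeros((K, T))

        trace = []
        self.converged_ = False
        for it in range(self.max_iter):
            # M-step: cluster means (GP-posterior ridge), mixing, noise
            Rk = R.sum(axis=0)
            for k in range(K):
                if Rk[k] < 1e-12:
                    F[k] = 0.0
                    continue
                ybar = (R[:, k] @ X) / Rk[k]
                A = Kp + (s2 / Rk[k]) * np.eye(T)
                F[k] = Kp @ np.linalg.solve(A, ybar)
            pi = np.maximum(Rk / N, 1e-12)
            pi = pi / pi.sum()
            sq = np.zeros((N, K))
            for k in range(K):
                sq[:, k] = np.sum((X - F[k]) ** 2, axis=1)
            s2 = max(float(np.sum(R * sq)) / (N * T), 1e-6)
            # E-step
            logp = np.log(pi)[None, :] - 0.5 * sq / s2 - 0.5 * T * np.log(2 * np.pi * s2)
            logp -= logp.max(axis=1, keepdims=True)
            R = np.exp(logp)
            R /= R.sum(axis=1, keepdims=True)

            obj = self._objective(X, F, R, pi, s2, Kp_inv, logdet_Kp)
            trace.append(obj)
            if it > 0 and abs(obj - trace[-2]) <= self.tol * (1.0 + abs(trace[-2])):
                self.converged_ = True
                break

        self.responsibilities_ = R
        self.cluster_means_ = F
        self.weights_ = pi
        self.noise_variance_ = s2
        self.labels_ = np.argmax(R, axis=1)  # ties -> lowest cluster index
        self.objective_trace_ = np.array(trace)
        self.final_objective_ = trace[-1]
        self.times_ = t_axis
        return self

    def fit_predict(self, X, times=None) -> np.ndarray:
        return self.fit(X, times=times).labels_

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_means_"):
            raise AttributeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        sq = np.stack(
            [np.sum((X - f) ** 2, axis=1) for f in self.cluster_means_], axis=1
        )
        logp = np.log(self.weights_)[None, :] - 0.5 * sq / self.noise_variance_
        return np.argmax(logp, axis=1)


def cluster_profiles(profiles: pd.DataFrame, K: int = 6, seed: int = 0,
                     times=None, **kwargs) -> GaussianProcessMixture:
    """Cluster a features x time-points profile table into K archetypes.

    ``profiles`` must already be normalised and replicate-averaged (rows are
    features, columns time points in minutes). Returns the fitted
    :class:`GaussianProcessMixture`; assignments are in ``.labels_`` aligned
    with ``profiles.index``.
    """
    if times is None and hasattr(profiles, "columns"):
        times = np.asarray(profiles.columns, dtype=float)
    X = np.asarray(profiles, dtype=float)
    model = GaussianProcessMixture(n_components=K, random_state=seed, **kwargs)
    return model.fit(X, times=times)
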