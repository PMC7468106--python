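"""Dynamic-versus-static classification of time-course profiles.

Each feature's counts over the stimulation time course are fitted with two
zero-mean Gaussian-process regression models on the transformed time axis:

* **dynamic** — squared-exponential (RBF) kernel plus white noise, three
  hyperparameters (signal variance sigma_f^2, lengthscale ell, noise
  variance sigma_n^2);
* **static** — pure white noise, one hyperparameter (sigma_n^2), whose
  marginal-likelihood maximiser is available in closed form.

Model selection uses BIC = k ln(n) - 2 ln(L-hat), favouring the smaller
value, and a more stringent likelihood-ratio test LR = 2 (ln L-hat_RBF -
ln L-hat_STATIC) referred to chi-square with one degree of freedom.
Replicate observations enter the fit jointly (n = replicates x time points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from ._normalize import log2p1, normalize_counts, transform_times

__all__ = [
    "GPFit",
    "DynamicsCall",
    "bic",
    "fit_gp_models",
    "classify_dynamics",
    "classify_profiles",
    "GPDynamicsClassifier",
]

# Hyperparameter bounds (natural scale). The signal variance is allowed to
# collapse to ~0 so the static model is an attainable boundary case of the
# dynamic one; noise variances are floored to keep covariances well posed.
SIGNAL_VAR_BOUNDS = (1e-12, 1e4)
NOISE_VAR_BOUNDS = (1e-4, 1e4)
LENGTHSCALE_SPAN_FACTORS = (0.1, 10.0)


@dataclass(frozen=True)
class GPFit:
    """Result of maximising one GP model's marginal likelihood."""

    model: str  # "dynamic" | "static"
    log_marginal_likelihood: float
    hyperparams: dict
    k: int
    n: int
    bic: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "bic", bic(self.k, self.n, self.log_marginal_likelihood))


@dataclass(frozen=True)
class DynamicsCall:
    """Per-feature model-selection outcome."""

    feature_id: str
    bic_dynamic: float
    bic_static: float
    lr: float
    p_value: float
    dynamic_by_bic: bool
    dynamic_by_lr: bool


def bic(k: int, n: int, loglik: float) -> float:
    """Bayesian information criterion, k ln(n) - 2 loglik (smaller is better)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return k * math.log(n) - 2.0 * loglik


def _static_mle(y: np.ndarray) -> tuple[float, float]:
    """Closed-form white-noise fit on centred data: returns (loglik, sigma_n^2)."""
    n = y.size
    s2 = float(np.mean(y**2))
    s2 = min(max(s2, NOISE_VAR_BOUNDS[0]), NOISE_VAR_BOUNDS[1])
    ll = -0.5 * float(y @ y) / s2 - 0.5 * n * math.log(2.0 * math.pi * s2)
    return ll, s2


def _lml_and_grad(theta: np.ndarray, y: np.ndarray, d2: np.ndarray):
    """Log marginal likelihood of the RBF+white GP and its gradient.

    ``theta`` holds log(sigma_f^2), log(ell), log(sigma_n^2); ``d2`` is the
    matrix of squared time distances.
    """
    sf2, ell, sn2 = np.exp(theta)
    n = y.size
    R = np.exp(-0.5 * d2 / (ell * ell))
    K = sf2 * R + sn2 * np.eye(n)  # sn2 >= 1e-4 keeps K well conditioned
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(3)
    alpha = cho_solve((c, low), y)
    lml = (
        -0.5 * float(y @ alpha)
        - float(np.sum(np.log(np.diag(c))))
        - 0.5 * n * math.log(2.0 * math.pi)
    )
    Kinv = cho_solve((c, low), np.eye(n))
    A = np.outer(alpha, alpha) - Kinv
    dK_dsf = sf2 * R
    dK_dl = sf2 * R * (d2 / (ell * ell))
    grad = np.array(
        [
            0.5 * float(np.sum(A * dK_dsf)),
            0.5 * float(np.sum(A * dK_dl)),
            0.5 * sn2 * float(np.trace(A)),
        ]
    )
    return lml, grad


def _fit_dynamic(y: np.ndarray, t: np.ndarray, seed: int = 0) -> tuple[float, dict]:
    """Multi-start bounded quasi-Newton maximisation of the RBF+white LML."""
    n = y.size
    d2 = (t[:, None] - t[None, :]) ** 2
    span = float(t.max() - t.min())
    if span <= 0:
        span = 1.0
    lo = np.log([SIGNAL_VAR_BOUNDS[0], LENGTHSCALE_SPAN_FACTORS[0] * span, NOISE_VAR_BOUNDS[0]])
    hi = np.log([SIGNAL_VAR_BOUNDS[1], LENGTHSCALE_SPAN_FACTORS[1] * span, NOISE_VAR_BOUNDS[1]])
    bounds = list(zip(lo, hi))

    ll_static, s2_static = _static_mle(y)
    var_y = max(float(np.var(y)), NOISE_VAR_BOUNDS[0])
    starts = [
        # boundary start: static solution with the signal switched off
        np.array([lo[0], math.log(span / 3.0), math.log(s2_static)]),
        # data-driven starts
        np.array([math.log(var_y), math.log(span / 3.0), math.log(max(var_y / 10, 1e-4))]),
        np.array([math.log(var_y), math.log(span), math.log(max(var_y / 2, 1e-4))]),
    ]
    rng = np.random.default_rng(seed)
    for _ in range(3):
        u = rng.uniform(size=3)
        starts.append(lo + u * (hi - lo))

    def neg(theta):
        lml, g = _lml_and_grad(theta, y, d2)
        return -lml, -g

    best_lml, best_theta = -np.inf, starts[0]
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B", bounds=bounds)
        lml, _ = _lml_and_grad(res.x, y, d2)
        if lml > best_lml:
            best_lml, best_theta = lml, res.x
    sf2, ell, sn2 = np.exp(best_theta)
    return best_lml, {"signal_variance": sf2, "lengthscale": ell, "noise_variance": sn2}


def _default_normalizer(counts: np.ndarray) -> np.ndarray:
    """Single-profile default: log2(x + 1) then mean-centre."""
    z = log2p1(counts)
    return z - z.mean()


def fit_gp_models(profile, time_transform="log2", normalizer=_default_normalizer, seed: int = 0):
    """Fit the dynamic and static GP models to one profile.

    Parameters
    ----------
    profile : TimeCourseProfile or (times, counts) pair
        ``times`` in minutes (strictly increasing, >= 3 points); ``counts``
        a replicates x time-points array.
    time_transform : str or callable
        ``"log2"`` (default), ``"hours"``, or a callable on minutes.
    normalizer : callable or None
        Applied to the raw count matrix; ``None`` uses the values as given
        apart from mean-centring. The default is log2(x+1) + centring.

    Returns
    -------
    (GPFit, GPFit)
        Dynamic fit then static fit, on the same n observations.
    """
    times, counts = _coerce_profile(profile)
    times = np.asarray(times, dtype=float)
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if times.size < 3 or np.any(np.diff(times) <= 0):
        raise ValueError("need >= 3 strictly increasing time points")
    if counts.shape[1] != times.size:
        raise ValueError("counts must be replicates x time points")
    if normalizer is _default_normalizer and np.any(counts < 0):
        # raw counts path; pre-normalised inputs may legitimately be negative
        raise ValueError("counts must be non-negative")

    t1 = transform_times(times, time_transform) if isinstance(time_transform, str) else np.asarray(
        time_transform(times), dtype=float
    )
    z = normalizer(counts) if normalizer is not None else counts - counts.mean()
    z = np.atleast_2d(np.asarray(z, dtype=float))
    # stack replicates: repeated time coordinates, joint fit
    y = z.ravel()
    t = np.tile(t1, z.shape[0])
    n = y.size

    ll_s, s2 = _static_mle(y)
    fit_static = GPFit("static", ll_s, {"noise_variance": s2}, k=1, n=n)
    ll_d, hp = _fit_dynamic(y, t, seed=seed)
    fit_dynamic = GPFit("dynamic", ll_d, hp, k=3, n=n)
    return fit_dynamic, fit_static


def _coerce_profile(profile):
    if hasattr(profile, "times") and hasattr(profile, "counts"):
        return profile.times, profile.counts
    times, counts = profile
    return times, counts


def classify_dynamics(fit_dynamic: GPFit, fit_static: GPFit, alpha: float = 0.05,
                      feature_id: str = "") -> DynamicsCall:
    """Combine the two fits into BIC and chi-square(1) LR calls."""
    if fit_dynamic.n != fit_static.n:
        raise ValueError("fits computed on different observation counts")
    lr = max(0.0, 2.0 * (fit_dynamic.log_marginal_likelihood - fit_static.log_marginal_likelihood))
    p = float(stats.chi2.sf(lr, df=1))
    return DynamicsCall(
        feature_id=feature_id,
        bic_dynamic=fit_dynamic.bic,
        bic_static=fit_static.bic,
        lr=lr,
        p_value=p,
        dynamic_by_bic=fit_dynamic.bic < fit_static.bic,
        dynamic_by_lr=p < alpha,
    )


def classify_profiles(counts: pd.DataFrame, alpha: float = 0.05,
                      time_transform: str = "log2", seed: int = 0) -> pd.DataFrame:
    """Classify every feature in a (replicate, time) count table.

    Counts are CPM-normalised per sample across all features (so rescaling
    the whole table leaves calls unchanged), log2(x+1)-transformed and
    mean-centred per feature before fitting.

    Returns a DataFrame indexed by feature id with columns ``bic_dynamic``,
    ``bic_static``, ``lr``, ``p_value``, ``dynamic_by_bic``, ``dynamic_by_lr``.
    """
    if not isinstance(counts.columns, pd.MultiIndex):
        raise ValueError("counts must have (replicate, time) MultiIndex columns")
    norm = normalize_counts(counts)
    reps = sorted(set(counts.columns.get_level_values(0)))
    times = np.array(sorted(set(counts.columns.get_level_values(1))), dtype=float)
    # reorder columns rep-major, time-minor
    norm = norm[[(r, t) for r in reps for t in times]]
    rows = []
    for fid, row in zip(norm.index, norm.to_numpy()):
        mat = row.reshape(len(reps), len(times))
        mat = mat - mat.mean()
        fd, fs = fit_gp_models((times, mat), time_transform=time_transform,
                               normalizer=None, seed=seed)
        call = classify_dynamics(fd, fs, alpha=alpha, feature_id=str(fid))
        rows.append(
            (fid, call.bic_dynamic, call.bic_static, call.lr, call.p_value,
             call.dynamic_by_bic, call.dynamic_by_lr)
        )
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "bic_dynamic", "bic_static", "lr", "p_value",
                 "dynamic_by_bic", "dynamic_by_lr"],
    ).set_index("feature_id")
    return out


class GPDynamicsClassifier:
    """sklearn-style wrapper around :func:`classify_profiles`.

    ``fit(X)`` expects a (replicate, time) MultiIndex count DataFrame; after
    fitting, per-feature calls are available as ``calls_`` and ``predict``
    returns the boolean LR-based dynamic labels.
    """

    def __init__(self, alpha: float = 0.05, time_transform: str = "log2", seed: int = 0):
        self.alpha = alpha
        self.time_transform = time_transform
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "time_transform": self.time_transform, "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        self.calls_ = classify_profiles(
            X, alpha=self.alpha, time_transform=self.time_transform, seed=self.seed
        )
        return self

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        if not hasattr(self, "calls_"):
            raise AttributeError("classifier is not fitted")
        if X is not None:
            return classify_profiles(
                X, alpha=self.alpha, time_transform=self.time_transform, seed=self.seed
            )["dynamic_by_lr"].to_numpy()
        return self.calls_["dynamic_by_lr"].to_numpy()
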