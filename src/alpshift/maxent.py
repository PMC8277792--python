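"""Maximum-entropy presence-background distribution model.

Fits the Gibbs distribution over background points whose expected feature
values match the presence sample, with an L1 penalty — the penalized
log-likelihood

    L(lambda) = mean_presence[lambda . f(x)] - log sum_background exp(lambda . f(x))
                - sum_j beta_j |lambda_j|

with per-feature penalty beta_j = beta * s_j / sqrt(m) (s_j the presence
standard deviation of feature j, m the presence count, floored to avoid zero
penalties).  Feature classes are linear, quadratic and product terms of the
environmental axes, each min-max scaled to [0, 1] over the background.  The
optimizer is accelerated proximal gradient ascent (FISTA with restart and
backtracking); only the objective of the reference Java tool is replicated,
not its sequential update algorithm.

Raw output is the normalized Gibbs density over the training background;
the cloglog transform 1 - exp(-e^H * raw), with H the entropy of the fitted
distribution, maps it to an interpretable 0-1 occurrence scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import Grid


@dataclass
class FeatureMap:
    """Feature expansion + background min-max scaling for the env axes."""

    axes: list[str]
    features: list[tuple[str, int, int]]   # (kind, i, j); j = -1 except products
    lo: np.ndarray
    hi: np.ndarray

    @property
    def names(self) -> list[str]:
        out = []
        for kind, i, j in self.features:
            if kind == "linear":
                out.append(self.axes[i])
            elif kind == "quadratic":
                out.append(f"{self.axes[i]}^2")
            else:
                out.append(f"{self.axes[i]}*{self.axes[j]}")
        return out

    def raw_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = []
        for kind, i, j in self.features:
            if kind == "linear":
                cols.append(X[:, i])
            elif kind == "quadratic":
                cols.append(X[:, i] ** 2)
            else:
                cols.append(X[:, i] * X[:, j])
        return np.stack(cols, axis=1) if cols else np.empty((X.shape[0], 0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Features scaled to [0, 1] by background bounds; values clamped."""
        F = self.raw_features(X)
        span = self.hi - self.lo
        return np.clip((F - self.lo) / span, 0.0, 1.0)


def build_features(
    background_env: np.ndarray,
    axes: list[str] | None = None,
    classes: tuple[str, ...] = ("linear", "quadratic", "product"),
) -> FeatureMap:
    """Build linear/quadratic/product features scaled over the background.

    For d axes this yields d linear, d quadratic and d(d-1)/2 product
    features.  Axes constant over the background are dropped with a warning.
    """
    X = np.asarray(background_env, dtype=float)
    d = X.shape[1]
    if axes is None:
        axes = [f"pc{i+1}" for i in range(d)]
    keep = [i for i in range(d) if X[:, i].max() > X[:, i].min()]
    if len(keep) < d:
        dropped = [axes[i] for i in range(d) if i not in keep]
        warnings.warn(f"dropping constant axes: {dropped}")
    features: list[tuple[str, int, int]] = []
    if "linear" in classes:
        features += [("linear", i, -1) for i in keep]
    if "quadratic" in classes:
        features += [("quadratic", i, -1) for i in keep]
    if "product" in classes:
        features += [
            ("product", keep[a], keep[b])
            for a in range(len(keep))
            for b in range(a + 1, len(keep))
        ]
    fm = FeatureMap(axes=list(axes), features=features, lo=np.empty(0), hi=np.empty(0))
    F = fm.raw_features(X)
    fm.lo = F.min(axis=0) if F.size else np.empty(0)
    fm.hi = F.max(axis=0) if F.size else np.empty(0)
    return fm


@dataclass
class MaxentModel:
    """Fitted model: feature weights, background normalizer and entropy."""

    feature_map: FeatureMap
    lambdas: np.ndarray
    log_z: float
    entropy: float          # nats, over the training background
    beta: float
    converged: bool = True
    n_background: int = 0

    def raw(self, env: np.ndarray) -> np.ndarray:
        """Gibbs density relative to the training-background normalizer."""
        F = self.feature_map.transform(env)
        return np.exp(F @ self.lambdas - self.log_z)

    def to_json(self) -> str:
        fm = self.feature_map
        return json.dumps(
            {
                "axes": fm.axes,
                "features": fm.features,
                "lo": fm.lo.tolist(),
                "hi": fm.hi.tolist(),
                "lambdas": self.lambdas.tolist(),
                "log_z": self.log_z,
                "entropy": self.entropy,
                "beta": self.beta,
                "converged": self.converged,
                "n_background": self.n_background,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        fm = FeatureMap(
            axes=d["axes"],
            features=[tuple(f) for f in d["features"]],
            lo=np.asarray(d["lo"]),
            hi=np.asarray(d["hi"]),
        )
        return cls(
            feature_map=fm,
            lambdas=np.asarray(d["lambdas"]),
            log_z=d["log_z"],
            entropy=d["entropy"],
            beta=d["beta"],
            converged=d["converged"],
            n_background=d["n_background"],
        )


def penalized_objective(
    lambdas: np.ndarray, Fp: np.ndarray, Fb: np.ndarray, betas: np.ndarray
) -> float:
    """The penalized presence log-likelihood at the given weights."""
    return float(
        Fp.mean(axis=0) @ lambdas
        - logsumexp(Fb @ lambdas)
        - np.abs(lambdas) @ betas
    )


def feature_betas(Fp: np.ndarray, beta: float, sd_floor: float = 1e-4) -> np.ndarray:
    """Per-feature L1 penalty: beta * s_j / sqrt(m), presence s.d. floored."""
    m = Fp.shape[0]
    s = Fp.std(axis=0, ddof=1) if m > 1 else np.zeros(Fp.shape[1])
    return beta * np.maximum(s, sd_floor) / np.sqrt(m)


def fit_maxent(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    fm: FeatureMap,
    beta: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 5000,
    sd_floor: float = 1e-4,
) -> MaxentModel:
    """Fit the penalized maximum-entropy model.

    FISTA with adaptive restart and backtracking line search on the smooth
    part; the L1 term is handled by soft-thresholding.  Convergence when the
    objective improves by less than ``tol``; otherwise the model is returned
    with ``converged=False``.
    """
    presence_env = np.atleast_2d(np.asarray(presence_env, dtype=float))
    background_env = np.atleast_2d(np.asarray(background_env, dtype=float))
    if presence_env.shape[0] < 2:
        raise ValueError("need at least 2 presence points")
    if background_env.shape[0] < 2:
        raise ValueError("need at least 2 background points")
    Fp = fm.transform(presence_env)
    Fb = fm.transform(background_env)
    n_bg, k = Fb.shape

    if k == 0:
        lam = np.zeros(k)
        log_z = float(np.log(n_bg))
        return MaxentModel(fm, lam, log_z, float(np.log(n_bg)), beta, True, n_bg)
    if np.allclose(Fp, Fp[0], atol=0, rtol=0):
        warnings.warn(
            "degenerate presence sample (all feature rows identical); "
            "the fit is driven by the penalty floor alone"
        )

    betas = feature_betas(Fp, beta, sd_floor)
    mean_p = Fp.mean(axis=0)

    def smooth_neg(lam: np.ndarray) -> tuple[float, np.ndarray]:
        """-(smooth part) and its gradient."""
        logits = Fb @ lam
        lse = logsumexp(logits)
        p = np.exp(logits - lse)
        g = lse - mean_p @ lam
        grad = Fb.T @ p - mean_p
        return float(g), grad

    def prox_step(point: np.ndarray, step: float) -> tuple[np.ndarray, float]:
        """Backtracking proximal gradient step from ``point``."""
        g0, grad = smooth_neg(point)
        while True:
            cand = point - step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * betas, 0.0)
            diff = cand - point
            g_c, _ = smooth_neg(cand)
            if g_c <= g0 + grad @ diff + diff @ diff / (2 * step) + 1e-12:
                return cand, step
            step *= 0.5
            if step < 1e-14:
                return point, step

    lam = np.zeros(k)
    ylam = lam.copy()
    t_momentum = 1.0
    step = 1.0
    obj = penalized_objective(lam, Fp, Fb, betas)
    converged = False
    for _ in range(max_iter):
        cand, step = prox_step(ylam, step)
        new_obj = penalized_objective(cand, Fp, Fb, betas)
        if new_obj < obj:
            # adaptive restart: drop momentum, take a monotone step from lam
            t_momentum = 1.0
            cand, step = prox_step(lam, step)
            new_obj = penalized_objective(cand, Fp, Fb, betas)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2)) / 2.0
        ylam = cand + ((t_momentum - 1.0) / t_new) * (cand - lam)
        lam = cand
        t_momentum = t_new
        step = min(step * 2.0, 1e8)     # let the step length grow back
        if abs(new_obj - obj) < tol and new_obj >= obj:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged:
        warnings.warn("maxent fit did not converge within max_iter")

    log_z = float(logsumexp(Fb @ lam))
    p_bg = np.exp(Fb @ lam - log_z)
    entropy = float(-np.sum(p_bg * np.log(np.clip(p_bg, 1e-300, None))))
    return MaxentModel(fm, lam, log_z, entropy, beta, converged, n_bg)


def predict_cloglog(model: MaxentModel, env: np.ndarray) -> np.ndarray:
    """cloglog output: 1 - exp(-e^H * raw); monotone in the raw density."""
    return 1.0 - np.exp(-np.exp(model.entropy) * model.raw(env))


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC of presence vs background scores; ties 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("need non-empty score sets")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def omission_threshold(training_scores, rate: float = 0.10) -> float:
    """Training omission threshold: the sorted score at index floor(rate * n).

    Exactly the presences scoring strictly below the returned value are
    omitted.
    """
    s = np.sort(np.asarray(training_scores, dtype=float))
    if s.size == 0:
        raise ValueError("no training scores")
    idx = min(int(np.floor(rate * s.size)), s.size - 1)
    return float(s[idx])


@dataclass
class EvalResult:
    """Bootstrap evaluation: per-replicate AUCs and the mean omission threshold."""

    auc_training: np.ndarray
    auc_test: np.ndarray
    omission_threshold_mean: float
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))


def bootstrap_evaluate(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    fm: FeatureMap,
    beta: float = 1.0,
    n_rep: int = 100,
    train_frac: float = 0.8,
    omission_rate: float = 0.10,
    seed: int = 0,
    **fit_kwargs,
) -> EvalResult:
    """Repeated random 80/20 presence splits: fit, AUC, omission threshold.

    The background is not resplit: each replicate is evaluated against the
    full pooled background.
    """
    rng = np.random.default_rng(seed)
    presence_env = np.asarray(presence_env, dtype=float)
    m = presence_env.shape[0]
    n_train = max(int(round(train_frac * m)), 2)
    n_train = min(n_train, m - 1) if m > 2 else n_train
    auc_tr, auc_te, thr = [], [], []
    for _ in range(n_rep):
        perm = rng.permutation(m)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_maxent(presence_env[tr], background_env, fm, beta=beta, **fit_kwargs)
        bg_scores = predict_cloglog(model, background_env)
        tr_scores = predict_cloglog(model, presence_env[tr])
        auc_tr.append(auc(tr_scores, bg_scores))
        if te.size:
            auc_te.append(auc(predict_cloglog(model, presence_env[te]), bg_scores))
        thr.append(omission_threshold(tr_scores, omission_rate))
    return EvalResult(
        auc_training=np.asarray(auc_tr),
        auc_test=np.asarray(auc_te),
        omission_threshold_mean=float(np.mean(thr)),
        thresholds=np.asarray(thr),
    )


@dataclass
class ProbabilitySurface:
    """A rescaled, masked occurrence-probability surface for one year."""

    year: int
    values: np.ndarray          # [0, 1] or nan
    threshold_applied: float


def rescale_projection(values: np.ndarray, threshold: float, year: int = 0) -> ProbabilitySurface:
    """Threshold-rescale a cloglog surface to [0, 1].

    Cells below the threshold become nodata; surviving cells map to
    (p - threshold) / (p_max - threshold).  If the maximum equals the
    threshold all survivors become 1.
    """
    vals = np.asarray(values, dtype=float)
    out = np.where(np.isfinite(vals) & (vals >= threshold), vals, np.nan)
    if np.isfinite(out).any():
        p_max = np.nanmax(out)
        if p_max > threshold:
            out = (out - threshold) / (p_max - threshold)
        else:
            out = np.where(np.isfinite(out), 1.0, np.nan)
    return ProbabilitySurface(year=year, values=out, threshold_applied=float(threshold))


def mask_landcover(surface: ProbabilitySurface, mask: np.ndarray) -> ProbabilitySurface:
    """Set cells outside the suitable land-cover mask (mask == 0) to nodata."""
    vals = np.where(np.asarray(mask) != 0, surface.values, np.nan)
    return ProbabilitySurface(surface.year, vals, surface.threshold_applied)


def annual_projection(
    model: MaxentModel,
    score_grids_by_year: dict[int, np.ndarray],
    threshold: float,
    mask: np.ndarray | None = None,
) -> list[ProbabilitySurface]:
    """Project the model onto each year's PCA score grids.

    ``score_grids_by_year[y]`` is a (d, ny, nx) stack in the model's axis
    order.  Each year gets a cloglog prediction, threshold rescaling, and
    optional land-cover masking.
    """
    out = []
    for year in sorted(score_grids_by_year):
        stack = score_grids_by_year[year]
        d, ny, nx = stack.shape
        env = stack.reshape(d, -1).T
        finite = np.isfinite(env).all(axis=1)
        pred = np.full(env.shape[0], np.nan)
        pred[finite] = predict_cloglog(model, env[finite])
        surface = rescale_projection(pred.reshape(ny, nx), threshold, year=year)
        if mask is not None:
            surface = mask_landcover(surface, mask)
        out.append(surface)
    return out
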