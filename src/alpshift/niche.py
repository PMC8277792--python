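"""Realized niche volumes by one-class SVM boundaries in environmental space.

A species' realized niche is delimited by a one-class support-vector machine
(RBF kernel) fitted to its record scores in PCA environmental space; the
enclosed volume is estimated by Monte-Carlo integration over a bounding box
that extends one kernel bandwidth beyond the data in every dimension.
Absolute volumes are implementation-relative (they depend on nu, gamma and
the boundary smoothness); ratios and ranks across species are the meaningful
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import OneClassSVM


@dataclass
class HypervolumeModel:
    points: np.ndarray
    nu: float
    gamma: float
    svm: OneClassSVM
    box_lo: np.ndarray
    box_hi: np.ndarray

    @property
    def d(self) -> int:
        return self.points.shape[1]

    def contains(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(np.asarray(X, dtype=float)) >= 0


def fit_hypervolume(
    points: np.ndarray,
    nu: float = 0.05,
    gamma: float | None = None,
    seed: int = 0,
) -> HypervolumeModel:
    """Fit a one-class SVM niche boundary.

    gamma defaults to 1 / (d * pooled variance); the bounding box extends one
    RBF bandwidth (1/sqrt(2*gamma)) beyond the data per dimension.  At least
    5 points are required — niche volumes from fewer records are meaningless.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("points must be n x d with d >= 2")
    if X.shape[0] < 5:
        raise ValueError("need at least 5 records to fit a niche volume")
    if np.isnan(X).any():
        raise ValueError("points contain missing values")
    if gamma is None:
        var = X.var()
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    svm = OneClassSVM(kernel="rbf", nu=nu, gamma=gamma)
    svm.fit(X)
    bandwidth = 1.0 / np.sqrt(2.0 * gamma)
    return HypervolumeModel(
        points=X,
        nu=nu,
        gamma=gamma,
        svm=svm,
        box_lo=X.min(axis=0) - bandwidth,
        box_hi=X.max(axis=0) + bandwidth,
    )


def estimate_volume(
    model: HypervolumeModel, n_mc: int = 20000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo niche volume and its binomial standard error.

    Volume = box volume x fraction of uniform box samples inside the
    boundary; the standard error shrinks as 1/sqrt(n_mc).
    """
    rng = np.random.default_rng(seed)
    box_vol = float(np.prod(model.box_hi - model.box_lo))
    U = rng.uniform(model.box_lo, model.box_hi, size=(n_mc, model.d))
    inside = model.contains(U)
    p = inside.mean()
    volume = box_vol * p
    se = box_vol * np.sqrt(p * (1.0 - p) / n_mc)
    return float(volume), float(se)


def niche_summary(volumes) -> dict[str, float]:
    """min/max/mean/sd/median over a set of per-species volumes."""
    v = np.asarray(list(volumes), dtype=float)
    if v.size == 0:
        raise ValueError("no volumes")
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
    }
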