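"""k-NN mutual information, target entropy, and the Info-Fraction ratio.

Mutual information between window features and a target label is estimated
with k-nearest-neighbor estimators: the Kraskov-Stogbauer-Grassberger (KSG)
estimator for two continuous variables, and the Ross nearest-neighbor
estimator for a continuous feature block against a discrete target.  The
*Info-Fraction* is the estimated MI divided by the target's entropy — the
fraction of target uncertainty the features explain; the target entropy is
the ceiling on achievable MI.

Because differential entropy of a continuous target is scale-dependent (and
can be negative), the ratio is formed on the target quantized at sensor
resolution (1 mmHg for SBP, 1 bpm for HR, 0.01 s for RWAT): the entropy is
the plug-in Shannon entropy of the quantized target, and the default MI
estimate is the mixed discrete-continuous estimator against the same
quantized target.  Pure-continuous KSG remains available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

__all__ = [
    "DEFAULT_TARGET_RESOLUTIONS",
    "MIConfig",
    "MIEstimate",
    "knn_mi",
    "target_entropy",
    "info_fraction",
]

logger = logging.getLogger(__name__)

#: Sensor quantization per target: SBP mmHg, HR bpm, RWAT s.
DEFAULT_TARGET_RESOLUTIONS = {"SBP": 1.0, "HR": 1.0, "RWAT": 0.01}


@dataclass(frozen=True)
class MIConfig:
    """Estimator settings.

    ``k=3`` is common KSG practice; ``jitter_scale`` adds seeded noise of
    that fraction of each column's SD to break ties (the estimators assume
    continuous distributions with no duplicate coordinates).
    """

    k: int = 3
    estimator: str = "mixed_discrete"  # or "ksg_continuous"
    target_resolution: float = 1.0
    standardize: bool = True
    seed: int = 0
    jitter_scale: float = 1e-10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target_resolution <= 0:
            raise ValueError("target_resolution must be positive")
        if self.estimator not in {"ksg_continuous", "mixed_discrete"}:
            raise ValueError("unknown estimator")


@dataclass
class MIEstimate:
    """MI (nats), quantized-target entropy (nats), and their clamped ratio."""

    mi: float
    target_entropy: float
    info_fraction: float
    n: int
    config: MIConfig
    flags: List[str] = field(default_factory=list)


def _prepare(X, y, cfg: MIConfig):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    mask = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropping %d rows with missing values", dropped)
    X, y = X[mask], y[mask]
    if len(y) < 50:
        raise ValueError(f"need n >= 50 samples after dropping missing (got {len(y)})")
    if cfg.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    rng = np.random.default_rng(cfg.seed)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X + rng.normal(0.0, cfg.jitter_scale, size=X.shape) * sd
    return X, y


def knn_mi(X, y, cfg: MIConfig = MIConfig()) -> float:
    """KSG (algorithm 1) MI estimate between continuous X and y, in nats.

    Chebyshev balls in the joint space with k-th neighbor distance eps;
    marginal neighbor counts strictly inside eps.  Nonnegative after
    clamping at 0; deterministic for a fixed seed.  A constant target
    returns 0 (degenerate-target case).
    """
    X, y = _prepare(X, y, cfg)
    if np.ptp(y) == 0:
        logger.warning("constant target: MI defined as 0")
        return 0.0
    yy = y[:, None].astype(float)
    sd = yy.std() or 1.0
    rng = np.random.default_rng(cfg.seed + 1)
    yy = (yy - yy.mean()) / sd if cfg.standardize else yy
    yy = yy + rng.normal(0.0, cfg.jitter_scale, size=yy.shape) * yy.std()

    n = len(yy)
    k = min(cfg.k, n - 1)
    joint = np.hstack([X, yy])
    tree_joint = cKDTree(joint)
    eps = tree_joint.query(joint, k=k + 1, p=np.inf)[0][:, -1]
    r = np.nextafter(eps, 0)  # strict interior of the ball
    nx = cKDTree(X).query_ball_point(X, r, p=np.inf, return_length=True) - 1
    ny = cKDTree(yy).query_ball_point(yy, r, p=np.inf, return_length=True) - 1
    mi = digamma(k) + digamma(n) - float(np.mean(digamma(nx + 1) + digamma(ny + 1)))
    return max(0.0, float(mi))


def _mi_mixed(X: np.ndarray, y_disc: np.ndarray, k: int) -> float:
    """Ross nearest-neighbor MI between continuous X and discrete y, nats.

    Per point: the k-th neighbor distance among same-class points defines a
    radius; counting all-class points within that radius links the class
    structure to the local density.  Classes with a single member are
    excluded (no within-class neighbor exists).
    """
    n = len(y_disc)
    radius = np.zeros(n)
    label_counts = np.zeros(n)
    k_all = np.zeros(n)
    for label in np.unique(y_disc):
        mask = y_disc == label
        count = int(mask.sum())
        label_counts[mask] = count
        if count > 1:
            kc = min(k, count - 1)
            d = cKDTree(X[mask]).query(X[mask], k=kc + 1, p=np.inf)[0][:, -1]
            radius[mask] = np.nextafter(d, 0)
            k_all[mask] = kc
    keep = label_counts > 1
    if keep.sum() < 2:
        return 0.0
    Xk, rk = X[keep], radius[keep]
    m_all = cKDTree(Xk).query_ball_point(Xk, rk, p=np.inf, return_length=True)
    mi = (
        digamma(int(keep.sum()))
        + float(np.mean(digamma(k_all[keep])))
        - float(np.mean(digamma(label_counts[keep])))
        - float(np.mean(digamma(m_all)))
    )
    return max(0.0, float(mi))


def _quantize(y: np.ndarray, resolution: float) -> np.ndarray:
    return np.floor(y / resolution).astype(np.int64)


def target_entropy(y, cfg: MIConfig = MIConfig()) -> float:
    """Plug-in Shannon entropy (nats) of y quantized at target_resolution.

    Refining the resolution (nested bins) never decreases the estimate; a
    constant target has entropy 0.
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < 50:
        raise ValueError("need n >= 50 samples")
    bins = _quantize(y, cfg.target_resolution)
    _, counts = np.unique(bins, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def info_fraction(X, y, cfg: MIConfig = MIConfig()) -> MIEstimate:
    """Full Info-Fraction estimate: MI / target entropy, clamped to [0, 1].

    With the default ``mixed_discrete`` estimator, MI is computed between
    the continuous features and the target quantized at sensor resolution —
    the same discretization whose entropy forms the denominator, so the
    ratio is a true fraction.  ``ksg_continuous`` uses raw continuous KSG
    in the numerator instead.  A zero-entropy (constant) target leaves the
    fraction undefined (NaN) and flagged.
    """
    flags: List[str] = []
    Xp, yp = _prepare(X, y, cfg)
    n = len(yp)
    h = target_entropy(yp, cfg)
    if cfg.estimator == "mixed_discrete":
        mi = _mi_mixed(Xp, _quantize(yp, cfg.target_resolution), min(cfg.k, n - 1))
    else:
        mi = knn_mi(X, y, cfg)
    if h == 0.0:
        flags.append("degenerate_target")
        frac = float("nan")
    else:
        frac = mi / h
        if frac > 1.0 or frac < 0.0:
            flags.append("clamped")
            logger.info("info_fraction clamped from %.3f", frac)
        frac = float(np.clip(frac, 0.0, 1.0))
    return MIEstimate(
        mi=mi, target_entropy=h, info_fraction=frac, n=n, config=cfg, flags=flags
    )
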