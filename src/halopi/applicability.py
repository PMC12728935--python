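"""Mahalanobis-distance applicability domain.

The domain model stores the training-feature mean and covariance; a query's
Mahalanobis distance sqrt((x - mu)^T Sigma^-1 (x - mu)) is reported both
absolutely and relative to the 95th percentile of the training distances,
so a relative distance above 1 flags a statistically rare geometry.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

__all__ = ["ApplicabilityModel", "fit_md", "mahalanobis", "flag_outliers"]


@dataclasses.dataclass
class ApplicabilityModel:
    mean: np.ndarray
    cov: np.ndarray
    cov_inv: np.ndarray
    scale: float  # 95th-percentile training MD
    percentile: float
    kept: np.ndarray  # boolean mask of non-degenerate feature columns

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "cov_inv": self.cov_inv.tolist(),
            "scale": self.scale,
            "percentile": self.percentile,
            "kept": self.kept.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "ApplicabilityModel":
        return ApplicabilityModel(
            mean=np.array(d["mean"]),
            cov=np.array(d["cov"]),
            cov_inv=np.array(d["cov_inv"]),
            scale=float(d["scale"]),
            percentile=float(d["percentile"]),
            kept=np.array(d["kept"], dtype=bool),
        )


def fit_md(
    X: np.ndarray, percentile: float = 95.0, ridge_factor: float = 1e-8
) -> ApplicabilityModel:
    """Fit the domain model on (scaled) training features.

    Constant feature columns are dropped with a warning; the covariance
    inverse is ridge-regularized with eps = ridge_factor * trace / dim for
    determinism on near-singular data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    spread = X.max(axis=0) - X.min(axis=0)
    kept = spread > 0
    if not kept.any():
        raise ValueError("all feature columns are constant; domain is degenerate")
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} constant feature column(s) from the "
            "applicability domain",
            stacklevel=2,
        )
    Xk = X[:, kept]
    mean = Xk.mean(axis=0)
    cov = np.cov(Xk, rowvar=False)
    cov = np.atleast_2d(cov)
    dim = cov.shape[0]
    eps = ridge_factor * np.trace(cov) / dim
    cov_inv = np.linalg.inv(cov + eps * np.eye(dim))
    md = _md(Xk, mean, cov_inv)
    scale = float(np.percentile(md, percentile))
    if scale <= 0:
        raise ValueError("degenerate training set: 95th-percentile MD is zero")
    return ApplicabilityModel(
        mean=mean, cov=cov, cov_inv=cov_inv, scale=scale,
        percentile=percentile, kept=kept,
    )


def _md(X: np.ndarray, mean: np.ndarray, cov_inv: np.ndarray) -> np.ndarray:
    diff = X - mean
    return np.sqrt(np.einsum("ij,jk,ik->i", diff, cov_inv, diff))


def mahalanobis(x: np.ndarray, m: ApplicabilityModel) -> tuple[np.ndarray, np.ndarray]:
    """Absolute and relative Mahalanobis distance of one or many vectors."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != len(m.kept):
        raise ValueError(f"expected {len(m.kept)} features, got {X.shape[1]}")
    md = _md(X[:, m.kept], m.mean, m.cov_inv)
    rel = md / m.scale
    if single:
        return float(md[0]), float(rel[0])
    return md, rel


def flag_outliers(X: np.ndarray, m: ApplicabilityModel) -> np.ndarray:
    """True where the relative MD exceeds 1 (beyond the training percentile)."""
    _, rel = mahalanobis(np.atleast_2d(np.asarray(X, float)), m)
    return rel > 1.0
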