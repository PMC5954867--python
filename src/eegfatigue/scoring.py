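"""Alert-state baseline and Mahalanobis fatigue deviation.

The alert state is characterized per band by the sample mean and a
shrunk sample covariance of the spectral feature vectors:
``C = (1 - lambda) * S + lambda * diag(S)`` (plus a tiny ridge so the
matrix stays invertible even for degenerate baselines).  The deviation
of an epoch from the alert state is the Mahalanobis distance

    D(x) = [(x - mu)^T C^{-1} (x - mu)]^{1/2}

computed separately for the alpha and theta feature vectors, and the
combined fatigue statistic is the convex combination

    D_C = sigma * D(x_alpha) + (1 - sigma) * D(x_theta),  0 <= sigma <= 1.

All distances are unitless.  Larger D_C means a larger departure from
the alert baseline in either direction of spectral change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import BandFeatures

__all__ = [
    "DEFAULT_SIGMA",
    "DEFAULT_SHRINKAGE",
    "DEFAULT_BASELINE_EPOCHS",
    "FatigueScore",
    "mahalanobis",
    "combined_deviation",
    "FatigueScorer",
    "fit_baseline",
    "score_epoch",
]

#: Default weight of the alpha-band distance in the combined statistic.
DEFAULT_SIGMA = 0.5
#: Default covariance shrinkage toward its diagonal.
DEFAULT_SHRINKAGE = 0.1
#: Default number of leading artifact-free epochs used as the alert baseline.
DEFAULT_BASELINE_EPOCHS = 30

_RIDGE = 1e-9


@dataclass
class FatigueScore:
    """Per-epoch deviation scores."""

    epoch_index: int
    d_alpha: float
    d_theta: float
    sigma: float
    d_c: float


def mahalanobis(x, mu, cov) -> float:
    """Mahalanobis distance of ``x`` from ``(mu, cov)``.

    Uses a Cholesky solve; raises a numerical error naming the
    condition number if the covariance is not positive-definite.
    Returns 0 iff ``x == mu``.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if x.shape != mu.shape or cov.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, mu {mu.shape}, cov {cov.shape}"
        )
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(cov)
        raise np.linalg.LinAlgError(
            f"covariance is not positive-definite (condition number {cond:.3g})"
        ) from exc
    z = np.linalg.solve(L, x - mu)
    return float(np.sqrt(z @ z))


def combined_deviation(d_alpha: float, d_theta: float, sigma: float) -> float:
    """Convex combination ``sigma * d_alpha + (1 - sigma) * d_theta``."""
    if not 0 <= sigma <= 1:
        raise ValueError(f"sigma must lie in [0, 1], got {sigma}")
    if d_alpha < 0 or d_theta < 0:
        raise ValueError("distances must be non-negative")
    return sigma * d_alpha + (1 - sigma) * d_theta


def _shrunk_covariance(X: np.ndarray, shrinkage: float) -> np.ndarray:
    S = np.cov(X, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    shrunk = (1 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    ridge = _RIDGE * max(1.0, float(np.trace(shrunk)) / S.shape[0])
    return shrunk + ridge * np.eye(S.shape[0])


class FatigueScorer(TransformerMixin, BaseEstimator):
    """Alert-baseline model and combined Mahalanobis fatigue scorer.

    Fit on feature rows from *alert* epochs; ``transform`` then maps
    feature rows to the combined deviation ``D_C``.  Feature rows stack
    the theta bins first, then the alpha bins (the layout produced by
    :func:`eegfatigue.features.extract_features`).

    Parameters
    ----------
    sigma : float in [0, 1]
        Weight of the alpha-band distance in ``D_C``.
    shrinkage : float in [0, 1]
        Shrinkage of each band covariance toward its diagonal.
    n_theta : int
        Number of leading columns that are theta bins.

    Attributes
    ----------
    mu_theta_, mu_alpha_ : ndarray
        Baseline band means.
    cov_theta_, cov_alpha_ : ndarray
        Shrunk baseline band covariances (symmetric positive-definite).
    n_epochs_used_ : int
        Number of baseline epochs the model was fitted on.
    """

    def __init__(
        self,
        sigma: float = DEFAULT_SIGMA,
        shrinkage: float = DEFAULT_SHRINKAGE,
        n_theta: int = 3,
    ):
        self.sigma = sigma
        self.shrinkage = shrinkage
        self.n_theta = n_theta

    def fit(self, X, y=None):
        if not 0 <= self.sigma <= 1:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError(f"shrinkage must lie in [0, 1], got {self.shrinkage}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_epochs, n_features)")
        if X.shape[0] < 2:
            raise ValueError(
                f"need at least 2 alert epochs to fit a baseline, got {X.shape[0]}"
            )
        if X.shape[1] <= self.n_theta:
            raise ValueError("feature rows must hold theta bins then alpha bins")
        Xt, Xa = X[:, : self.n_theta], X[:, self.n_theta :]
        self.mu_theta_ = Xt.mean(axis=0)
        self.mu_alpha_ = Xa.mean(axis=0)
        self.cov_theta_ = _shrunk_covariance(Xt, self.shrinkage)
        self.cov_alpha_ = _shrunk_covariance(Xa, self.shrinkage)
        self.n_epochs_used_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        return self

    def _distances(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "mu_theta_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        d_theta = np.array(
            [mahalanobis(row, self.mu_theta_, self.cov_theta_) for row in X[:, : self.n_theta]]
        )
        d_alpha = np.array(
            [mahalanobis(row, self.mu_alpha_, self.cov_alpha_) for row in X[:, self.n_theta :]]
        )
        return d_theta, d_alpha

    def transform(self, X) -> np.ndarray:
        """Combined deviation ``D_C`` per epoch, shape (n_epochs, 1)."""
        d_theta, d_alpha = self._distances(X)
        d_c = self.sigma * d_alpha + (1 - self.sigma) * d_theta
        return d_c[:, None]

    def score_epochs(self, X):
        """Full per-epoch scores as a DataFrame
        (d_theta, d_alpha, sigma, d_c)."""
        import pandas as pd

        d_theta, d_alpha = self._distances(X)
        d_c = self.sigma * d_alpha + (1 - self.sigma) * d_theta
        return pd.DataFrame(
            {
                "epoch": np.arange(len(d_c)),
                "d_theta": d_theta,
                "d_alpha": d_alpha,
                "sigma": self.sigma,
                "d_c": d_c,
            }
        )

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialize the fitted baseline to a JSON document."""
        check_is_fitted(self, "mu_theta_")
        doc = {
            "sigma": self.sigma,
            "shrinkage": self.shrinkage,
            "n_theta": self.n_theta,
            "mu_theta": self.mu_theta_.tolist(),
            "mu_alpha": self.mu_alpha_.tolist(),
            "cov_theta": self.cov_theta_.tolist(),
            "cov_alpha": self.cov_alpha_.tolist(),
            "n_epochs_used": self.n_epochs_used_,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FatigueScorer":
        """Rebuild a fitted scorer from :meth:`to_json` output (a JSON
        string or a file path)."""
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        model = cls(
            sigma=doc["sigma"], shrinkage=doc["shrinkage"], n_theta=doc["n_theta"]
        )
        model.mu_theta_ = np.asarray(doc["mu_theta"])
        model.mu_alpha_ = np.asarray(doc["mu_alpha"])
        model.cov_theta_ = np.asarray(doc["cov_theta"])
        model.cov_alpha_ = np.asarray(doc["cov_alpha"])
        model.n_epochs_used_ = int(doc["n_epochs_used"])
        model.n_features_in_ = model.mu_theta_.size + model.mu_alpha_.size
        return model


def fit_baseline(
    features,
    shrinkage: float = DEFAULT_SHRINKAGE,
    sigma: float = DEFAULT_SIGMA,
) -> FatigueScorer:
    """Fit an alert baseline from feature rows or
    :class:`~eegfatigue.features.BandFeatures` objects."""
    if len(features) and isinstance(features[0], BandFeatures):
        n_theta = features[0].x_theta.size
        X = np.vstack([f.stacked() for f in features])
    else:
        X = np.asarray(features, dtype=float)
        n_theta = X.shape[1] // 2
    return FatigueScorer(sigma=sigma, shrinkage=shrinkage, n_theta=n_theta).fit(X)


def score_epoch(
    features: BandFeatures, baseline: FatigueScorer, sigma: float | None = None
) -> FatigueScore:
    """Score one epoch's features against a fitted baseline."""
    sigma = baseline.sigma if sigma is None else sigma
    if not 0 <= sigma <= 1:
        raise ValueError(f"sigma must lie in [0, 1], got {sigma}")
    d_theta = mahalanobis(features.x_theta, baseline.mu_theta_, baseline.cov_theta_)
    d_alpha = mahalanobis(features.x_alpha, baseline.mu_alpha_, baseline.cov_alpha_)
    d_c = combined_deviation(d_alpha, d_theta, sigma)
    return FatigueScore(
        epoch_index=features.epoch_index,
        d_alpha=d_alpha,
        d_theta=d_theta,
        sigma=sigma,
        d_c=d_c,
    )
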