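"""Artifact flagging and blind-source-separation artifact removal.

Flagging uses the conventional amplitude criterion: any sample whose
absolute amplitude strictly exceeds 50 microvolts is regarded as an
artifact.  Removal decomposes the recording into uncorrelated source
components with SOBI (second-order blind identification: joint
diagonalization of time-lagged covariance matrices), zeroes components
judged artifactual, and reconstructs the signal.  Single-channel
recordings are handled by delay embedding (a Hankel matrix of lagged
copies), so the same multivariate machinery applies.

A component is rejected when its back-projected contribution to the
sensor signal violates the 50 microvolt rule, or when its excess
kurtosis exceeds a bound (default 5) — high kurtosis marks sparse
high-amplitude transients such as blinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .io import EEGRecord, Epoch

__all__ = [
    "ARTIFACT_CUTOFF_UV",
    "ArtifactMask",
    "flag_artifacts",
    "BSSArtifactRemover",
    "remove_artifacts_bss",
    "sobi",
]

#: Amplitude criterion for artifacts, microvolts (strict inequality).
ARTIFACT_CUTOFF_UV = 50.0


@dataclass
class ArtifactMask:
    """Boolean per-sample artifact flags for a recording or epoch."""

    sample_flags: np.ndarray  # (n_channels, n_samples) bool
    cutoff: float

    @property
    def any_flagged(self) -> bool:
        return bool(self.sample_flags.any())

    @property
    def n_flagged(self) -> int:
        return int(self.sample_flags.sum())

    def epoch_flags(self, window: int, step: int | None = None) -> np.ndarray:
        """Per-epoch contamination flags: an epoch is contaminated iff
        any sample flag inside its window is set (any channel)."""
        step = window if step is None else step
        n = self.sample_flags.shape[1]
        if n < window:
            return np.zeros(0, dtype=bool)
        n_epochs = (n - window) // step + 1
        return np.array(
            [
                self.sample_flags[:, i * step : i * step + window].any()
                for i in range(n_epochs)
            ]
        )


def flag_artifacts(data, cutoff: float = ARTIFACT_CUTOFF_UV) -> ArtifactMask:
    """Flag samples whose absolute amplitude strictly exceeds ``cutoff``.

    ``data`` may be an :class:`EEGRecord`, an :class:`Epoch`, or a bare
    array (1-D or channels-by-time).  A sample exactly at the cutoff is
    *not* flagged.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if isinstance(data, EEGRecord):
        arr = data.data
    elif isinstance(data, Epoch):
        arr = data.data
    else:
        arr = np.atleast_2d(np.asarray(data, dtype=float))
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples must be finite")
    return ArtifactMask(sample_flags=np.abs(arr) > cutoff, cutoff=cutoff)


# ---------------------------------------------------------------------------
# SOBI: joint diagonalization of lagged covariances


def _joint_diagonalize(matrices: np.ndarray, tol: float = 1e-10, max_sweeps: int = 100) -> np.ndarray:
    """Orthogonal joint diagonalizer of a stack of symmetric matrices
    by Jacobi rotations.  Returns V with V.T @ M @ V jointly as
    diagonal as possible."""
    m = matrices.shape[1]
    M = matrices.copy()
    V = np.eye(m)
    for _ in range(max_sweeps):
        rotated = False
        for p in range(m - 1):
            for q in range(p + 1, m):
                g1 = M[:, p, p] - M[:, q, q]
                g2 = M[:, p, q] + M[:, q, p]
                ton = g1 @ g1 - g2 @ g2
                toff = 2.0 * (g1 @ g2)
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) > tol:
                    rotated = True
                    Mp, Mq = M[:, :, p].copy(), M[:, :, q].copy()
                    M[:, :, p] = c * Mp + s * Mq
                    M[:, :, q] = -s * Mp + c * Mq
                    Rp, Rq = M[:, p, :].copy(), M[:, q, :].copy()
                    M[:, p, :] = c * Rp + s * Rq
                    M[:, q, :] = -s * Rp + c * Rq
                    Vp, Vq = V[:, p].copy(), V[:, q].copy()
                    V[:, p] = c * Vp + s * Vq
                    V[:, q] = -s * Vp + c * Vq
        if not rotated:
            break
    return V


def sobi(
    X: np.ndarray, n_lags: int = 8, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Second-order blind identification.

    Parameters
    ----------
    X : ndarray of shape (n_signals, n_samples)
        Multivariate signal (rows are channels or embedded lags).
    n_lags : int
        Number of time lags (1..n_lags) whose covariance matrices are
        jointly diagonalized together with lag 0.
    n_components : int, optional
        PCA rank of the whitening step; defaults to full rank.

    Returns
    -------
    sources : (k, n_samples) estimated source time courses
    mixing : (n_signals, k) mixing matrix (back-projection)
    mean : (n_signals,) channel means removed before separation

    The algorithm is deterministic (no random initialization).
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if n <= n_lags + 1:
        raise ValueError("signal shorter than the requested number of lags")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]

    # whitening by PCA
    C0 = (Xc @ Xc.T) / n
    evals, evecs = np.linalg.eigh(C0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = n_components or m
    k = min(k, int(np.sum(evals > max(evals[0], 0) * 1e-12)) or 1)
    d = np.sqrt(evals[:k])
    whitener = evecs[:, :k] / d  # (m, k); Z = whitener.T @ Xc is white
    dewhiten = evecs[:, :k] * d  # (m, k)
    Z = whitener.T @ Xc

    lags = range(1, n_lags + 1)
    R = np.empty((len(lags), k, k))
    for i, tau in enumerate(lags):
        r = (Z[:, :-tau] @ Z[:, tau:].T) / (n - tau)
        R[i] = 0.5 * (r + r.T)
    V = _joint_diagonalize(R)

    sources = V.T @ Z
    mixing = dewhiten @ V
    return sources, mixing, mean


def _delay_embed(x: np.ndarray, m: int) -> np.ndarray:
    """Hankel matrix of m lagged copies: E[i, t] = x[t + i]."""
    n = x.size
    return np.lib.stride_tricks.sliding_window_view(x, n - m + 1)[:m]


def _diag_average(M: np.ndarray, n: int) -> np.ndarray:
    """Invert delay embedding by averaging over anti-diagonals."""
    m, w = M.shape
    out = np.zeros(n)
    counts = np.zeros(n)
    for i in range(m):
        out[i : i + w] += M[i]
        counts[i : i + w] += 1
    return out / counts


@dataclass
class ComponentReport:
    """Diagnostics for one BSS component."""

    index: int
    rejected: bool
    reason: str  # "amplitude", "kurtosis", or ""
    peak_uv: float
    kurtosis: float


@dataclass
class CleaningReport:
    """Summary of one artifact-removal run."""

    n_components: int
    components: list[ComponentReport] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(c.rejected for c in self.components)


class BSSArtifactRemover(BaseEstimator):
    """Artifact removal by SOBI with amplitude/kurtosis component rejection.

    Parameters
    ----------
    cutoff : float
        Amplitude rule in microvolts applied to each component's
        back-projection (strict).
    embed_dim : int
        Number of lagged copies used for single-channel delay
        embedding; ignored for multichannel input.  Must be >= 2.
    n_lags : int
        Time lags for the SOBI joint diagonalization.
    n_components : int or None
        PCA rank retained in whitening; full rank by default.
    kurtosis_max : float
        A component with excess kurtosis above this bound is rejected.
    random_state : int or None
        Seed for the FastICA fallback (SOBI itself is deterministic).
    """

    def __init__(
        self,
        cutoff: float = ARTIFACT_CUTOFF_UV,
        embed_dim: int = 16,
        n_lags: int = 8,
        n_components: int | None = None,
        kurtosis_max: float = 5.0,
        random_state: int | None = 0,
    ):
        self.cutoff = cutoff
        self.embed_dim = embed_dim
        self.n_lags = n_lags
        self.n_components = n_components
        self.kurtosis_max = kurtosis_max
        self.random_state = random_state

    def _separate(self, X: np.ndarray):
        try:
            return sobi(X, n_lags=self.n_lags, n_components=self.n_components)
        except np.linalg.LinAlgError:
            from sklearn.decomposition import FastICA

            ica = FastICA(
                n_components=self.n_components,
                whiten="unit-variance",
                random_state=self.random_state,
                max_iter=1000,
            )
            mean = X.mean(axis=1)
            S = ica.fit_transform((X - mean[:, None]).T).T
            return S, ica.mixing_, mean

    def clean(self, record: EEGRecord) -> tuple[EEGRecord, CleaningReport]:
        """Return a cleaned copy of ``record`` and a component report."""
        single = record.n_channels == 1
        if single and self.embed_dim < 2:
            raise ValueError("single-channel input requires embed_dim >= 2")
        if record.n_samples <= max(self.embed_dim, self.n_lags + 1):
            raise ValueError("record shorter than the embedding dimension")

        if not record.data.any():  # all-zero record: nothing to separate
            return record.copy(), CleaningReport(n_components=0)

        X = _delay_embed(record.data[0], self.embed_dim) if single else record.data
        sources, mixing, mean = self._separate(X)
        k = sources.shape[0]
        report = CleaningReport(n_components=k)

        removed = np.zeros_like(record.data)
        for j in range(k):
            contrib = np.outer(mixing[:, j], sources[j])
            if single:
                back = _diag_average(contrib, record.n_samples)[np.newaxis, :]
            else:
                back = contrib
            peak = float(np.max(np.abs(back)))
            kurt = float(stats.kurtosis(sources[j], fisher=True, bias=True))
            reason = ""
            if peak > self.cutoff:
                reason = "amplitude"
            elif kurt > self.kurtosis_max:
                reason = "kurtosis"
            if reason:
                removed += back
            report.components.append(
                ComponentReport(j, bool(reason), reason, peak, kurt)
            )

        cleaned = record.copy()
        cleaned.data = record.data - removed
        return cleaned, report


def remove_artifacts_bss(
    record: EEGRecord,
    embed_dim: int = 16,
    n_components: int | None = None,
    seed: int | None = 0,
    cutoff: float = ARTIFACT_CUTOFF_UV,
    kurtosis_max: float = 5.0,
) -> tuple[EEGRecord, CleaningReport]:
    """Functional wrapper around :class:`BSSArtifactRemover`."""
    remover = BSSArtifactRemover(
        cutoff=cutoff,
        embed_dim=embed_dim,
        n_components=n_components,
        kurtosis_max=kurtosis_max,
        random_state=seed,
    )
    return remover.clean(record)
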