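"""Common Spatial Patterns for two-class EEG decoding.

CSP finds a linear projection of the channels that maximizes the
variance of one class while minimizing it for the other. Given the two
class-mean normalized spatial covariances C1 and C2:

1. trace-normalize each trial covariance, C = X X' / trace(X X');
2. average per class and form the composite Cc = C1 + C2;
3. eigendecompose Cc = U L U' and whiten with P = L^{-1/2} U';
4. S1 = P C1 P' and S2 = P C2 P' share eigenvectors B, and their
   eigenvalue matrices sum to the identity (simultaneous
   diagonalization);
5. the projection matrix W = B' P has rows ("spatial filters") sorted by
   descending eigenvalue of S1; columns of W^{-1} are the spatial
   patterns.

Features are the natural log of the variance of the first and last
``n_pairs`` projected components — the components most discriminative
for each class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .session import CLASS_LABELS, EpochedSession

#: condition-number threshold beyond which the composite covariance is
#: ridge-regularized before whitening
_COND_MAX = 1e12
_RIDGE_EPS = 1e-10


def normalized_covariance(trial_matrix: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance C = X X' / trace(X X') of one trial."""
    X = np.asarray(trial_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a (channels x samples) matrix, got shape {X.shape}")
    n_channels, n_samples = X.shape
    if n_samples <= n_channels:
        warnings.warn(
            f"trial has {n_samples} samples for {n_channels} channels; "
            "covariance estimate will be rank deficient",
            stacklevel=2,
        )
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("zero-signal trial: covariance trace is zero")
    return C / tr


def class_mean_covariance(session: EpochedSession, class_label: str) -> np.ndarray:
    """Arithmetic mean of per-trial normalized covariances over one class."""
    idx = np.flatnonzero(session.labels == class_label)
    if idx.size == 0:
        raise ValueError(f"no trials with label {class_label!r}")
    acc = np.zeros((session.n_channels, session.n_channels))
    for i in idx:
        acc += normalized_covariance(session.data[i])
    return acc / idx.size


@dataclass
class CSPModel:
    """Fitted CSP projection.

    ``filters`` rows are spatial filters (applied as W @ X); ``patterns``
    columns are the corresponding spatial patterns (W^{-1} columns);
    ``eigvals_class1`` are the whitened class-1 eigenvalues in [0, 1],
    descending — class 2's eigenvalues are their complement to 1.
    """

    filters: np.ndarray
    patterns: np.ndarray
    eigvals_class1: np.ndarray
    n_pairs: int = 3

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]

    def selected_rows(self) -> np.ndarray:
        """Indices of the first and last ``n_pairs`` filters, in fixed order."""
        n = self.filters.shape[0]
        if n < 2 * self.n_pairs:
            raise ValueError(f"{n} components cannot supply {self.n_pairs} pairs")
        return np.r_[np.arange(self.n_pairs), np.arange(n - self.n_pairs, n)]


def fit_csp(C1: np.ndarray, C2: np.ndarray, n_pairs: int = 3) -> CSPModel:
    """Fit CSP from the two class-mean covariances via whitening +
    simultaneous diagonalization.

    Eigenvector signs are fixed by making the largest-magnitude entry of
    each filter positive; rows of W are ordered by descending class-1
    eigenvalue.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    n = C1.shape[0]
    if C1.shape != (n, n) or C2.shape != (n, n):
        raise ValueError("class covariances must be square and of equal shape")
    Cc = 0.5 * (C1 + C2 + C1.T + C2.T)  # symmetrized composite

    lam, U = np.linalg.eigh(Cc)
    if lam[-1] <= 0:
        raise np.linalg.LinAlgError("composite covariance has no positive eigenvalue")
    tol = n * np.finfo(float).eps * lam[-1]
    deficient = int(np.sum(lam <= tol))
    if deficient:
        raise np.linalg.LinAlgError(
            f"composite covariance is rank deficient (rank {n - deficient} of {n})"
        )
    if lam[-1] / lam[0] > _COND_MAX:  # ill-conditioned but full rank: ridge
        Cc = Cc + _RIDGE_EPS * (np.trace(Cc) / n) * np.eye(n)
        lam, U = np.linalg.eigh(Cc)

    P = (U / np.sqrt(lam)).T  # whitening: P Cc P' = I
    S1 = P @ C1 @ P.T
    S1 = 0.5 * (S1 + S1.T)
    mu, B = np.linalg.eigh(S1)  # ascending
    order = np.argsort(mu)[::-1]  # descending class-1 eigenvalue
    mu = mu[order]
    B = B[:, order]

    W = B.T @ P
    # sign convention: dominant coefficient of each filter positive
    signs = np.sign(W[np.arange(n), np.argmax(np.abs(W), axis=1)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    patterns = np.linalg.pinv(W)
    return CSPModel(filters=W, patterns=patterns,
                    eigvals_class1=np.clip(mu, 0.0, 1.0), n_pairs=n_pairs)


def fit_csp_from_session(session: EpochedSession, n_pairs: int = 3,
                         class_labels: tuple[str, str] = CLASS_LABELS) -> CSPModel:
    """Convenience: class-mean covariances from a (filtered, windowed)
    session, then :func:`fit_csp`."""
    C1 = class_mean_covariance(session, class_labels[0])
    C2 = class_mean_covariance(session, class_labels[1])
    return fit_csp(C1, C2, n_pairs=n_pairs)


def apply_csp(model: CSPModel, session: EpochedSession) -> EpochedSession:
    """Project every trial: Z = W @ X. Component signals replace channels."""
    if session.n_channels != model.n_channels:
        raise ValueError(
            f"session has {session.n_channels} channels, model expects {model.n_channels}"
        )
    Z = np.einsum("fc,ncs->nfs", model.filters, session.data)
    out = session.with_data(Z)
    out.channel_names = [f"csp{i:02d}" for i in range(model.filters.shape[0])]
    return out


def logvar_features(projected: EpochedSession, n_pairs: int = 3) -> np.ndarray:
    """Log-variance features: ln var of the first and last ``n_pairs``
    projected components per trial (population variance, denominator N).

    Returns an (n_trials x 2*n_pairs) matrix.
    """
    n_comp = projected.n_channels
    if n_comp < 2 * n_pairs:
        raise ValueError(f"{n_comp} components cannot supply {n_pairs} pairs")
    rows = np.r_[np.arange(n_pairs), np.arange(n_comp - n_pairs, n_comp)]
    var = projected.data[:, rows, :].var(axis=-1)  # ddof=0
    if np.any(var <= 0):
        bad = np.argwhere(var <= 0)[0]
        raise ValueError(
            f"zero-variance projected component (trial {bad[0]}, component row {rows[bad[1]]})"
        )
    return np.log(var)


def features_from_covariances(model: CSPModel, trial_covs: np.ndarray) -> np.ndarray:
    """Log-variance features computed from cached per-trial covariances.

    For centered (mean-removed, /N) trial covariances R, the variance of
    projected component i is (W R W')_ii, so this reproduces
    :func:`logvar_features` without re-projecting the time series.
    """
    Wsel = model.filters[model.selected_rows()]
    var = np.einsum("fc,ncd,fd->nf", Wsel, trial_covs, Wsel)
    if np.any(var <= 0):
        raise ValueError("zero-variance projected component")
    return np.log(var)
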