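"""Time-lagged independent component analysis.

TICA finds the linear combinations of input features that decorrelate
slowest, by solving the generalized eigenvalue problem

    C(tau) U = C(0) U Lambda

where C(0) is the instantaneous covariance of the mean-removed features,
C(tau) the time-lagged covariance at lag tau, U the eigenvector matrix
(columns = independent components) and Lambda the diagonal eigenvalue
matrix.  Both covariances use the symmetrized estimator, which keeps the
eigenvalues real and bounded by 1 in magnitude; columns of U come out
C(0)-orthonormal.  Projection of new data is (x - mean) @ U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg


@dataclass(frozen=True)
class TicaModel:
    lag: float  # ps
    mean: np.ndarray  # feature mean over all trajectories
    eigvals: np.ndarray  # descending, |lambda| <= 1 under symmetrization
    eigvecs: np.ndarray  # (n_features, k), C(0)-orthonormal columns
    k: int


def _as_arrays(features) -> tuple[list[np.ndarray], float]:
    """Accept FeatureTrajectory objects or plain arrays (then dt=1 ps)."""
    arrays, dts = [], []
    for f in features:
        if hasattr(f, "distances"):
            arrays.append(np.asarray(f.distances, float))
            dts.append(float(f.dt))
        else:
            arrays.append(np.atleast_2d(np.asarray(f, float).T).T)
            dts.append(1.0)
    if len(set(dts)) > 1:
        raise ValueError("trajectories disagree on dt")
    return arrays, dts[0]


def tica_fit(features, lag: float = 20.0, k: int | None = None,
             regularization: float = 1e-10) -> TicaModel:
    """Fit TICA on one or more feature trajectories.

    ``lag`` is in ps and must be a positive multiple of the frame spacing;
    every trajectory must be longer than the lag.  ``regularization`` is
    added to the diagonal of C(0); a singular C(0) without regularization
    raises ``numpy.linalg.LinAlgError``.

    Eigenpairs are sorted by descending eigenvalue; each eigenvector's
    largest-magnitude component is made positive so signs are deterministic.
    """
    arrays, dt = _as_arrays(features)
    if lag <= 0 or abs(lag / dt - round(lag / dt)) > 1e-9:
        raise ValueError("lag must be a positive multiple of the frame spacing")
    tau = int(round(lag / dt))
    dim = arrays[0].shape[1]
    if any(a.shape[0] <= tau for a in arrays):
        raise ValueError("every trajectory must be longer than the lag")

    total = sum(a.shape[0] for a in arrays)
    mean = sum(a.sum(axis=0) for a in arrays) / total

    C0 = np.zeros((dim, dim))
    Ct = np.zeros((dim, dim))
    n_pairs = 0
    for a in arrays:
        x = a - mean
        x0, xt = x[:-tau], x[tau:]
        C0 += x0.T @ x0 + xt.T @ xt
        Ct += x0.T @ xt + xt.T @ x0
        n_pairs += 2 * x0.shape[0]
    C0 /= n_pairs
    Ct /= n_pairs
    C0 += regularization * np.eye(dim)

    try:
        w, V = scipy.linalg.eigh(Ct, C0)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(f"ill-conditioned C(0): {exc}") from exc
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    # deterministic sign: largest-|component| of each column positive
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    if k is None:
        k = dim
    if not 1 <= k <= dim:
        raise ValueError("k must lie in [1, n_features]")
    return TicaModel(lag=float(lag), mean=mean, eigvals=w[:k],
                     eigvecs=V[:, :k], k=int(k))


def tica_project(model: TicaModel, features) -> np.ndarray:
    """Project features onto the independent components: (x - mean) @ U."""
    x = np.asarray(features.distances if hasattr(features, "distances") else features, float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError("feature dimension does not match the fitted model")
    y = (x - model.mean) @ model.eigvecs
    return y[0] if squeeze else y
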