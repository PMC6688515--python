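"""Supervised linear band-power decoders: CSP + rLDA and SPoC.

Common spatial patterns (CSP) finds spatial filters W maximizing the
variance ratio between two classes of bandpassed epochs by solving the
generalized eigenvalue problem

    W.T (C1 - C2) = Lambda W.T C,      C = C1 + C2 (pooled),

with the class spatial covariances C_k averaged over each class's epochs.
The two filters belonging to the extreme eigenvalues are kept; per-epoch
log-variance features of the filtered signals feed a shrinkage-regularized
LDA classifier.

Source power comodulation (SPoC) finds a single filter w whose projected
epoch-wise variance maximally covaries with a continuous target z by
solving  C_z w = lambda C w  with C_z the z-weighted spatial covariance
(z standardized across epochs). Predictions are the per-epoch variances of
the filtered test epochs.

Generalized eigenproblems are solved by symmetric whitening of C with an
eigenvalue floor for rank control. A small plug-in registry lets external
decoders participate in benchmark sweeps through the same fit/predict
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "CSPModel",
    "SPoCModel",
    "fit_csp",
    "csp_features",
    "fit_rlda",
    "predict_rlda",
    "fit_spoc",
    "spoc_predict",
    "spatial_pattern",
    "register_decoder",
    "get_decoder",
    "CSPDecoder",
    "SPoCDecoder",
]

EIG_FLOOR = 1e-10


@dataclass
class CSPModel:
    W_full: np.ndarray  # (n_channels, n_channels) all filters
    W_hat: np.ndarray  # (n_channels, 2) extreme-eigenvalue filters
    eigenvalues: np.ndarray  # sorted descending
    C1: np.ndarray
    C2: np.ndarray
    C: np.ndarray
    classifier: LinearDiscriminantAnalysis | None = None
    log_features: bool = True
    classes: tuple[int, int] = (1, 2)


@dataclass
class SPoCModel:
    w: np.ndarray  # (n_channels,), unit l2 norm
    C: np.ndarray
    Cz: np.ndarray
    eigenvalue: float
    meta: dict = field(default_factory=dict)


def _epoch_cov(epochs: np.ndarray, trace_norm: bool = False) -> np.ndarray:
    """Per-epoch spatial covariances X(e) X(e)^T, stacked (e, c, c)."""
    covs = np.einsum("ecs,eds->ecd", epochs, epochs)
    if trace_norm:
        tr = np.trace(covs, axis1=1, axis2=2)
        covs = covs / tr[:, None, None]
    return covs


def _whiten(C: np.ndarray) -> np.ndarray:
    """C^(-1/2) via eigendecomposition with an eigenvalue floor."""
    d, U = np.linalg.eigh(C)
    floor = EIG_FLOOR * d.max()
    d = np.maximum(d, floor)
    return U @ np.diag(d**-0.5) @ U.T


def _gen_eig_sym(B: np.ndarray, C: np.ndarray):
    """Solve B v = lambda C v (B symmetric, C symmetric psd) by whitening.

    Returns eigenvalues descending and the corresponding C-orthonormal
    eigenvectors as columns.
    """
    P = _whiten(C)
    d, V = np.linalg.eigh(P @ B @ P.T)
    order = np.argsort(d)[::-1]
    return d[order], P.T @ V[:, order]


def fit_csp(
    epochs: np.ndarray,
    y_binary: np.ndarray,
    log_features: bool = True,
    trace_norm: bool = False,
    fit_classifier: bool = True,
) -> CSPModel:
    """Fit CSP filters (and by default the rLDA on their power features).

    epochs : (n_epochs, n_channels, n_samples), bandpassed upstream.
    y_binary : two distinct integer labels; the smaller is "class 1".
    """
    epochs = np.asarray(epochs, dtype=float)
    y = np.asarray(y_binary)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"CSP needs exactly two classes, got {classes.tolist()}")
    covs = _epoch_cov(epochs, trace_norm)
    m1 = y == classes[0]
    m2 = y == classes[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 epochs")
    C1 = covs[m1].mean(axis=0)
    C2 = covs[m2].mean(axis=0)
    C = C1 + C2
    d = np.linalg.eigvalsh(C)
    if d.min() < EIG_FLOOR * d.max():
        warnings.warn(
            "pooled covariance is rank deficient; shrinkage applied", stacklevel=2
        )
        gamma = 1e-6
        C = (1 - gamma) * C + gamma * (np.trace(C) / C.shape[0]) * np.eye(C.shape[0])
    evals, W = _gen_eig_sym(C1 - C2, C)
    W_hat = W[:, [0, -1]]  # largest and smallest eigenvalue
    model = CSPModel(
        W_full=W,
        W_hat=W_hat,
        eigenvalues=evals,
        C1=C1,
        C2=C2,
        C=C,
        log_features=log_features,
        classes=(int(classes[0]), int(classes[1])),
    )
    if fit_classifier:
        feats = csp_features(model, epochs)
        model.classifier = fit_rlda(feats, y)
    return model


def csp_features(model: CSPModel, epochs: np.ndarray) -> np.ndarray:
    """Per-epoch (log-)variance of each selected filter's time course."""
    epochs = np.asarray(epochs, dtype=float)
    filtered = np.einsum("ck,ecs->eks", model.W_hat, epochs)
    feats = filtered.var(axis=2)
    if model.log_features:
        feats = np.log(np.maximum(feats, 1e-300))
    return feats


def fit_rlda(
    features: np.ndarray, y: np.ndarray, shrinkage: str | float = "auto"
) -> LinearDiscriminantAnalysis:
    """Shrinkage-regularized LDA (analytic Ledoit-Wolf intensity by default).

    ``shrinkage`` may be a fixed value in [0, 1]; 1 forces a spherical
    covariance so the decision boundary is perpendicular to the difference
    of the class means.
    """
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    clf.fit(np.asarray(features, dtype=float), np.asarray(y))
    return clf


def predict_rlda(model, features: np.ndarray) -> np.ndarray:
    """Continuous decision scores, monotone in the higher-class posterior."""
    clf = model.classifier if isinstance(model, CSPModel) else model
    if clf is None:
        raise ValueError("model has no fitted classifier")
    feats = np.asarray(features, dtype=float)
    if isinstance(model, CSPModel):
        feats = csp_features(model, feats) if feats.ndim == 3 else feats
    return clf.decision_function(feats)


def fit_spoc(
    epochs: np.ndarray,
    z_epoch: np.ndarray,
    standardize_z: bool = True,
    trace_norm: bool = False,
) -> SPoCModel:
    """Fit the SPoC filter maximizing covariance of projected power with z."""
    epochs = np.asarray(epochs, dtype=float)
    z = np.asarray(z_epoch, dtype=float)
    n_epochs, n_channels, _ = epochs.shape
    if z.size != n_epochs:
        raise ValueError("z_epoch length must equal n_epochs")
    if np.var(z) == 0:
        raise ValueError("zero-variance target; SPoC undefined")
    if n_epochs < n_channels:
        warnings.warn(
            f"only {n_epochs} epochs for {n_channels} channels; "
            "covariance estimates will be unstable",
            stacklevel=2,
        )
    covs = _epoch_cov(epochs, trace_norm)
    C = covs.mean(axis=0)
    zw = (z - z.mean()) / z.std() if standardize_z else z
    Cz = np.einsum("e,ecd->cd", zw, covs) / n_epochs
    evals, V = _gen_eig_sym(Cz, C)
    # the largest eigenvalue maximizes w^T Cz w / w^T C w, i.e. the
    # covariance of projected power with (standardized) z; projected power
    # is invariant to the sign of w, so fix the sign by first component
    w = V[:, 0] / np.linalg.norm(V[:, 0])
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
    return SPoCModel(w=w, C=C, Cz=Cz, eigenvalue=float(evals[0]))


def spoc_predict_filters(w: np.ndarray, epochs: np.ndarray) -> np.ndarray:
    filtered = np.einsum("c,ecs->es", w, np.asarray(epochs, dtype=float))
    return filtered.var(axis=1)


def spoc_predict(model: SPoCModel, epochs: np.ndarray) -> np.ndarray:
    """Per-epoch variance of the SPoC-filtered time course."""
    return spoc_predict_filters(model.w, epochs)


def spatial_pattern(C: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Sensor-space pattern a = C w / (w^T C w) of a filter w."""
    num = C @ w
    return num / (w @ num)


# --------------------------------------------------------------------------
# plug-in registry: fit(epochs, labels) -> state; predict(state, epochs) -> scores

_REGISTRY: dict[str, tuple[Callable, Callable]] = {}


def register_decoder(name: str, fit: Callable, predict: Callable) -> None:
    """Register an external decoder under ``name`` for benchmark sweeps."""
    _REGISTRY[name] = (fit, predict)


def get_decoder(name: str) -> tuple[Callable, Callable]:
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown decoder {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def CSPDecoder(epochs, y):  # noqa: N802 - factory-style alias used by benchmark
    return fit_csp(epochs, y)


def SPoCDecoder(epochs, z):  # noqa: N802
    return fit_spoc(epochs, z)


def _csp_predict(model: CSPModel, epochs) -> np.ndarray:
    return predict_rlda(model, np.asarray(epochs, dtype=float))


register_decoder("csp", CSPDecoder, _csp_predict)
register_decoder("spoc", SPoCDecoder, spoc_predict)
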