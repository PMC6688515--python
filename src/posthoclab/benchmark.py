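"""Parameter sweeps over dataset size, label noise, and label variability.

Decoder performance is estimated by chronological k-fold cross-validation:
epochs are split into k contiguous temporal blocks, each block serves once
as the test set, and temporal order is never shuffled (avoiding leakage
between neighbouring epochs). Label noise of intensity xi is injected into
the TRAINING labels only; evaluation is always against the clean post-hoc
labels, so a decoder's score measures what it recovered of the ground
truth, not the irreducible noise. (A flag reproduces the noisy-test
alternative.)

``run_sweep`` runs the full factorial grid (tertile x n_epochs x xi x seed)
and returns a long-format table, one record per cell, fold, and seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score

from .decoders import get_decoder
from .labeling import EpochedDataset
from .noise import NoiseSpec, add_classification_noise, add_regression_noise

__all__ = [
    "SweepConfig",
    "chronological_kfold",
    "evaluate_cell",
    "run_sweep",
    "auc",
    "accuracy",
    "pearson",
]

DEFAULT_EPOCH_COUNTS = [50, 100, 200, 400, 800, 1400, 2000]
DEFAULT_NOISE_GRID = [round(0.05 * i, 2) for i in range(17)]  # 0 .. 0.8


@dataclass
class SweepConfig:
    decoder: str = "csp"  # "csp" | "spoc" | any registered plug-in name
    scheme: str = "binary"  # "binary" | "ternary" | "regression"
    epoch_counts: list[int] = field(default_factory=lambda: list(DEFAULT_EPOCH_COUNTS))
    noise_grid: list[float] = field(default_factory=lambda: list(DEFAULT_NOISE_GRID))
    tertiles: list[str] = field(default_factory=lambda: ["low", "medium", "high"])
    n_folds: int = 5
    seeds: list[int] = field(default_factory=lambda: [0])
    noisy_test_labels: bool = False

    def __post_init__(self) -> None:
        if any(n < 2 * self.n_folds for n in self.epoch_counts):
            raise ValueError(
                f"every epoch count must be >= 2*n_folds={2 * self.n_folds}"
            )
        if any(not (0 <= x < 1) for x in self.noise_grid):
            raise ValueError("noise grid values must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "decoder": self.decoder,
            "scheme": self.scheme,
            "epoch_counts": list(self.epoch_counts),
            "noise_grid": list(self.noise_grid),
            "tertiles": list(self.tertiles),
            "n_folds": self.n_folds,
            "seeds": list(self.seeds),
            "noisy_test_labels": self.noisy_test_labels,
        }


def chronological_kfold(n_epochs: int, k: int = 5):
    """Contiguous temporal blocks; fold i tests on block i, trains on the rest.

    Block sizes differ by at most one, earliest blocks largest.
    """
    if n_epochs < 2 * k:
        raise ValueError(f"need at least {2 * k} epochs for {k} folds")
    blocks = np.array_split(np.arange(n_epochs), k)
    folds = []
    for i, test in enumerate(blocks):
        train = np.concatenate([b for j, b in enumerate(blocks) if j != i])
        folds.append((train, test))
    return folds


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic, ties averaged)."""
    y = np.asarray(y)
    if np.unique(y).size != 2:
        warnings.warn("AUC undefined: need both classes in y", stacklevel=2)
        return float("nan")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    pred, y = np.asarray(pred), np.asarray(y)
    if pred.size == 0:
        warnings.warn("accuracy undefined on empty input", stacklevel=2)
        return float("nan")
    return float(np.mean(pred == y))


def pearson(z_hat: np.ndarray, z: np.ndarray) -> float:
    z_hat, z = np.asarray(z_hat, dtype=float), np.asarray(z, dtype=float)
    if np.std(z_hat) == 0 or np.std(z) == 0:
        warnings.warn("correlation undefined: zero-variance input", stacklevel=2)
        return float("nan")
    return float(sstats.pearsonr(z_hat, z)[0])


def _cell_metric(scheme: str) -> str:
    return {"binary": "auc", "ternary": "accuracy", "regression": "pearson"}[scheme]


def evaluate_cell(
    dataset: EpochedDataset,
    decoder: str,
    n_epochs: int,
    xi: float,
    scheme: str,
    n_folds: int = 5,
    seed: int = 0,
    noisy_test_labels: bool = False,
) -> dict:
    """Score one sweep cell: (dataset, decoder, size, noise intensity).

    The chronologically first ``n_epochs`` epochs are used; training labels
    are corrupted at intensity xi; per-fold metrics (AUC / accuracy /
    Pearson rho) are returned with their mean and sd.
    """
    if n_epochs > dataset.n_epochs:
        raise ValueError(
            f"requested {n_epochs} epochs but dataset has {dataset.n_epochs}"
        )
    fit, predict = get_decoder(decoder)
    sub = dataset.subset(np.arange(n_epochs))
    z = sub.labels.z_epoch
    y = sub.labels.y_epoch
    metric = _cell_metric(scheme)
    if scheme == "regression":
        clean = z
        n_classes = 0
    else:
        if y is None:
            raise ValueError("dataset carries no discrete labels")
        clean = y
        n_classes = int(np.unique(y).size)

    folds = chronological_kfold(n_epochs, n_folds)
    per_fold = []
    for f, (tr, te) in enumerate(folds):
        if scheme == "regression":
            spec = NoiseSpec(xi=xi, kind="regression", seed=seed * 1009 + f)
            lab_tr = add_regression_noise(clean[tr], spec)
            lab_te = (
                add_regression_noise(clean[te], spec) if noisy_test_labels else clean[te]
            )
        else:
            spec = NoiseSpec(
                xi=xi, kind="classification", n_classes=n_classes, seed=seed * 1009 + f
            )
            lab_tr = add_classification_noise(clean[tr], spec)
            lab_te = (
                add_classification_noise(clean[te], spec)
                if noisy_test_labels
                else clean[te]
            )
        if scheme != "regression" and np.unique(lab_tr).size < n_classes:
            warnings.warn(f"fold {f}: single-class training labels; skipped",
                          stacklevel=2)
            per_fold.append(float("nan"))
            continue
        try:
            model = fit(sub.epochs[tr], lab_tr)
        except ValueError as exc:
            warnings.warn(f"fold {f}: fit failed ({exc}); skipped", stacklevel=2)
            per_fold.append(float("nan"))
            continue
        scores = predict(model, sub.epochs[te])
        if metric == "auc":
            per_fold.append(auc(scores, lab_te))
        elif metric == "accuracy":
            per_fold.append(accuracy(scores, lab_te))
        else:
            per_fold.append(pearson(scores, lab_te))
    vals = np.asarray(per_fold, dtype=float)
    ok = vals[np.isfinite(vals)]
    return {
        "metric_name": metric,
        "per_fold": per_fold,
        "mean": float(ok.mean()) if ok.size else float("nan"),
        "sd": float(ok.std(ddof=1)) if ok.size > 1 else float("nan"),
        "n_folds_used": int(ok.size),
    }


def _cell_key(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_sweep(
    config: SweepConfig,
    registry: dict[str, EpochedDataset],
    cache: dict | None = None,
) -> pd.DataFrame:
    """Full factorial sweep over (tertile x epoch count x noise x seed).

    ``registry`` maps tertile tags to labeled datasets. Cells are cached by
    the SHA-256 of their canonicalized config, so a rerun with the same
    cache dict resumes instead of recomputing. Returns a long-format table
    with one row per cell, fold, and seed.
    """
    cache = cache if cache is not None else {}
    records = []
    for tertile in config.tertiles:
        if tertile not in registry:
            warnings.warn(f"no dataset for tertile {tertile!r}; cell skipped",
                          stacklevel=2)
            continue
        dataset = registry[tertile]
        for n_epochs in config.epoch_counts:
            for xi in config.noise_grid:
                for seed in config.seeds:
                    payload = {
                        "decoder": config.decoder,
                        "scheme": config.scheme,
                        "tertile": tertile,
                        "n_epochs": n_epochs,
                        "xi": xi,
                        "seed": seed,
                        "n_folds": config.n_folds,
                        "noisy_test_labels": config.noisy_test_labels,
                    }
                    key = _cell_key(payload)
                    if key not in cache:
                        cache[key] = evaluate_cell(
                            dataset,
                            config.decoder,
                            n_epochs,
                            xi,
                            config.scheme,
                            config.n_folds,
                            seed,
                            config.noisy_test_labels,
                        )
                    cell = cache[key]
                    for f, v in enumerate(cell["per_fold"]):
                        records.append(
                            {
                                "decoder": config.decoder,
                                "tertile": tertile,
                                "n_epochs": n_epochs,
                                "xi": xi,
                                "fold": f,
                                "seed": seed,
                                "metric_name": cell["metric_name"],
                                "metric_value": v,
                            }
                        )
    return pd.DataFrame.from_records(records)
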