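"""Controlled label-noise injection.

Because post-hoc labels are noise-free by construction, corruption of known
intensity xi can be added back to study decoder robustness.

Regression: z_n = z + sqrt((1-(1-xi)^2)/(1-xi)^2) * sqrt(var(z)) * eta with
eta ~ N(0, 1) i.i.d., so the population correlation between clean and noisy
labels is exactly 1 - xi and var(z_n)/var(z) = 1/(1-xi)^2.

Classification: xi = 2 * (1 - P[y_n = y]); each epoch's label is replaced
with probability xi/2 by a class drawn uniformly from the remaining
classes. xi in [0, 1) for regression; xi in [0, 2) is meaningful for
classification (xi = 1 makes labels independent of the truth for two
classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseSpec", "add_regression_noise", "add_classification_noise"]


@dataclass
class NoiseSpec:
    xi: float
    kind: str  # "regression" | "classification"
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("regression", "classification"):
            raise ValueError("kind must be 'regression' or 'classification'")
        if self.kind == "regression" and not (0 <= self.xi < 1):
            raise ValueError("regression noise requires 0 <= xi < 1")
        if self.kind == "classification":
            if not (0 <= self.xi < 2):
                raise ValueError("classification noise requires 0 <= xi < 2")
            if self.n_classes < 2:
                raise ValueError("n_classes must be >= 2")


def add_regression_noise(z_epoch: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Noisy continuous labels with corr(z, z_n) = 1 - xi in population."""
    if spec.kind != "regression":
        raise ValueError("spec.kind must be 'regression'")
    z = np.asarray(z_epoch, dtype=float)
    if z.size > 1 and np.var(z, ddof=1) == 0:
        raise ValueError("zero-variance labels; noise scale undefined")
    if spec.xi == 0:
        return z.copy()
    rng = np.random.default_rng(spec.seed)
    one_minus = 1.0 - spec.xi
    scale = np.sqrt((1.0 - one_minus**2) / one_minus**2) * np.sqrt(np.var(z, ddof=1))
    return z + scale * rng.standard_normal(z.size)


def add_classification_noise(y_epoch: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Flip each label with probability xi/2 to a uniform other class.

    Flip decisions and replacement classes are drawn from a single seeded
    stream in epoch order, so results are reproducible given the seed.
    """
    if spec.kind != "classification":
        raise ValueError("spec.kind must be 'classification'")
    y = np.asarray(y_epoch, dtype=int)
    classes = np.arange(1, spec.n_classes + 1)
    if not np.all(np.isin(y, classes)):
        raise ValueError(f"labels must lie in 1..{spec.n_classes}")
    if spec.xi == 0:
        return y.copy()
    rng = np.random.default_rng(spec.seed)
    y_n = y.copy()
    p_flip = spec.xi / 2.0
    for e in range(y.size):
        if rng.random() < p_flip:
            others = classes[classes != y[e]]
            y_n[e] = others[rng.integers(0, others.size)]
    return y_n
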