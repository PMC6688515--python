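"""Shared oracle helpers for the test suite (independent of the package paths
they check)."""

import numpy as np


def epochs_with_exact_cov(diag_values, n_epochs, n_samples=16):
    """Epochs whose per-epoch covariance X X^T equals diag(diag_values)."""
    n_ch = len(diag_values)
    k = np.arange(1, n_ch + 1)[:, None]
    t = np.arange(n_samples)[None, :]
    Q = np.cos(2 * np.pi * k * t / n_samples)
    Q /= np.linalg.norm(Q, axis=1, keepdims=True)
    ep = np.diag(np.sqrt(np.asarray(diag_values, float))) @ Q
    return np.stack([ep] * n_epochs)


def direction_search_spoc(rng, n_epochs=300, n_grid=20000):
    """Cosine between the eigenproblem SPoC filter and the exhaustive
    maximizer of cov(var(w^T X(e)), z(e)) over a dense unit-sphere grid,
    on a random 3-channel planted-comodulation toy."""
    from posthoclab import fit_spoc

    z = rng.gamma(2.0, size=n_epochs)
    mix = rng.standard_normal((3, 3)) + np.eye(3)
    raw = np.empty((n_epochs, 3, 32))
    raw[:, 0] = rng.standard_normal((n_epochs, 32)) * np.sqrt(z)[:, None]
    raw[:, 1:] = rng.standard_normal((n_epochs, 2, 32))
    epochs = np.einsum("cd,eds->ecs", mix, raw)
    m = fit_spoc(epochs, z)
    k = np.arange(n_grid)
    phi = np.arccos(1 - 2 * (k + 0.5) / n_grid)
    theta = np.pi * (1 + 5**0.5) * k
    W = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    centered = epochs - epochs.mean(axis=2, keepdims=True)
    covs = np.einsum("ecs,eds->ecd", centered, centered) / epochs.shape[2]
    variances = np.einsum("ck,ecd,dk->ek", W, covs, W)
    # the covariance objective carries an implicit unit-projected-power
    # constraint; rescale each candidate so its mean projected variance is 1
    variances = variances / variances.mean(axis=0, keepdims=True)
    zc = (z - z.mean()) / z.std()
    objective = zc @ (variances - 1.0) / n_epochs
    w_star = W[:, np.argmax(objective)]
    return float(abs(m.w @ w_star))
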