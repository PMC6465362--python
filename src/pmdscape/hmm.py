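"""Two-state HMM with Gaussian emissions: scaled forward-backward decoding."""

from __future__ import annotations

import numpy as np


def forward_backward(log_emissions: np.ndarray, p_stay: float,
                     init: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Posterior state probabilities for a 2-state chain.

    Parameters
    ----------
    log_emissions
        (n, 2) array of per-observation log emission densities.
    p_stay
        Symmetric self-transition probability.
    init
        Initial state distribution (default uniform).

    Returns
    -------
    (posteriors, log_likelihood) where posteriors is (n, 2) and each row
    sums to 1.
    """
    n = log_emissions.shape[0]
    if n == 0:
        return np.zeros((0, 2)), 0.0
    trans = np.array([[p_stay, 1.0 - p_stay], [1.0 - p_stay, p_stay]])
    init = np.full(2, 0.5) if init is None else np.asarray(init, dtype=float)

    # emissions scaled per row to avoid under/overflow
    shift = log_emissions.max(axis=1, keepdims=True)
    emis = np.exp(log_emissions - shift)

    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a = init * emis[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ trans) * emis[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        b = trans @ (emis[t + 1] * beta[t + 1])
        beta[t] = b / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.log(scale).sum() + shift.sum())
    return post, loglik
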