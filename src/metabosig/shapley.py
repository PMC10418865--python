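"""Monte-Carlo permutation estimator of Shapley feature attributions.

For a model score f and a test point x, the Shapley value of feature i is the
average over feature orderings of the marginal change in f when feature i's
value is revealed, with unrevealed features filled in from a background
(training) sample.  One random ordering plus one background draw per test
point per iteration gives an unbiased estimate; summing the attributions over
features telescopes exactly to f(x) - f(background draw), so local accuracy
holds in expectation (sum(phi) ~ f(x) - E_background f).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def shapley_importance(
    predict,
    x_test: np.ndarray | pd.DataFrame,
    background: np.ndarray | pd.DataFrame,
    n_permutations: int = 50,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Estimate per-sample, per-feature Shapley values of ``predict``.

    Parameters
    ----------
    predict : callable
        Maps an (n, m) array to n scores (e.g. a decision function).
    x_test : array (n_test, m)
        Points to explain.
    background : array (n_background, m)
        Reference sample supplying values for absent features.
    n_permutations : int
        Random feature orderings per test point (>= 1).

    Returns
    -------
    phi : array (n_test, m)
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x_test = np.asarray(x_test, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    n, m = x_test.shape
    phi = np.zeros((n, m))
    for _ in range(n_permutations):
        order = rng.permutation(m)
        z = background[rng.integers(0, background.shape[0], size=n)].copy()
        prev = np.asarray(predict(z), dtype=float)
        for j in order:
            z[:, j] = x_test[:, j]
            cur = np.asarray(predict(z), dtype=float)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_permutations
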