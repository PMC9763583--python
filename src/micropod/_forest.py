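"""Random-forest helpers shared by the screen and model modules."""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier

try:  # bootstrap bookkeeping internals; present across recent sklearn versions
    from sklearn.ensemble._forest import (
        _generate_unsampled_indices,
        _get_n_samples_bootstrap,
    )

    _HAVE_OOB_INTERNALS = True
except ImportError:  # pragma: no cover - fallback exercised only on API drift
    _HAVE_OOB_INTERNALS = False


def fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int = 1000,
               seed: int = 0) -> RandomForestClassifier:
    """Classification forest with sqrt(p) features per split."""
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def oob_permutation_importance(forest: RandomForestClassifier, X: np.ndarray,
                               y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Mean decrease in accuracy from permuting each feature on OOB samples.

    For every tree, accuracy on its out-of-bag samples is compared with the
    accuracy after permuting one feature's OOB values; the drops are
    averaged over trees.  This is the classical Breiman MDA importance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_samples, n_features = X.shape
    rng = np.random.default_rng(seed)
    if not _HAVE_OOB_INTERNALS:  # pragma: no cover
        return _insample_permutation_importance(forest, X, y, rng)
    try:
        n_bootstrap = _get_n_samples_bootstrap(n_samples, forest.max_samples,
                                               None)
    except TypeError:  # older signature without sample_weight
        n_bootstrap = _get_n_samples_bootstrap(n_samples, forest.max_samples)
    drops = np.zeros(n_features)
    n_used = 0
    # individual trees predict encoded class indices, not original labels
    class_index = {c: i for i, c in enumerate(forest.classes_)}
    y_enc = np.array([class_index[v] for v in y], dtype=float)
    for tree in forest.estimators_:
        try:
            oob = _generate_unsampled_indices(tree.random_state, n_samples,
                                              n_bootstrap, None)
        except TypeError:
            oob = _generate_unsampled_indices(tree.random_state, n_samples,
                                              n_bootstrap)
        if oob.size < 2:
            continue
        X_oob = X[oob]
        y_oob = y_enc[oob]
        base = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(n_features):
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            drops[j] += base - np.mean(tree.predict(X_perm) == y_oob)
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return drops / n_used


def _insample_permutation_importance(forest, X, y, rng) -> np.ndarray:
    base = np.mean(forest.predict(X) == y)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        X_perm = X.copy()
        X_perm[:, j] = X[rng.permutation(X.shape[0]), j]
        drops[j] = base - np.mean(forest.predict(X_perm) == y)
    return drops
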