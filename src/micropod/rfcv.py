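"""Cross-validated random-forest feature-count selection, final panel
training, per-sample probability-of-disease (POD) scoring, ROC/cut-off
evaluation, and external-cohort validation.

The POD of a sample is the fraction of forest trees voting the disease
class.  In cross-validated mode a sample is only ever scored by forests
whose training folds excluded it (averaged over repeats); feature ranking
is re-derived inside every training fold so the error curve carries no
selection leak.  A ``legacy_leaky`` switch reproduces the naive protocol
(rank once on the full cohort) for comparison only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from micropod import _forest
from micropod.otu_io import OtuTable, OtuTableError, RelAbundanceTable


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _matrix(table: OtuTable | RelAbundanceTable) -> np.ndarray:
    mat = table.counts if isinstance(table, OtuTable) else table.values
    return np.asarray(mat, dtype=float)


@dataclass
class RfcvCurve:
    ks: list[int]
    mean_errors: list[float]
    sd_errors: list[float]
    chosen_k: int | None = None
    rule: str | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks, "mean_error": self.mean_errors,
                             "sd_error": self.sd_errors})


@dataclass
class ClassifierModel:
    panel: list[str]
    n_trees: int
    seed: int
    positive_label: str
    training_cohort: str
    training_sample_ids: list[str]
    importances: pd.DataFrame          # mean_decrease_accuracy / mean_decrease_gini
    below_floor: list[str]
    forest: RandomForestClassifier
    training_matrix: np.ndarray        # kept so models persist as plain text
    training_labels: list[str]


@dataclass
class PodScores:
    scores: pd.Series                  # sample_id -> POD in [0, 1]
    mode: str                          # cross-validated | external

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if np.any(vals < -1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("POD values must lie in [0, 1]")
        if self.mode not in ("cross-validated", "external"):
            raise ValueError(f"unknown POD mode {self.mode!r}")


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: pd.DataFrame                # threshold, sensitivity, specificity
    n_case: int
    n_control: int

    def summary(self) -> dict:
        return {"auc": self.auc, "cutoff": self.cutoff,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "n_case": self.n_case, "n_control": self.n_control}


# ---------------------------------------------------------------------------
# feature-count selection


def default_feature_grid(n_candidates: int) -> list[int]:
    """Descending halvings of the candidate count plus every k <= 10."""
    ks = set(range(1, min(10, n_candidates) + 1))
    k = n_candidates
    while k >= 1:
        ks.add(k)
        k //= 2
    return sorted(ks)


def cv_error_curve(table: OtuTable | RelAbundanceTable, labels, ranked_ids,
                   folds: int = 5, repeats: int = 5, n_trees: int = 500,
                   seed: int = 0, grid=None,
                   legacy_leaky: bool = False) -> RfcvCurve:
    """Stratified repeated k-fold misclassification error for forests on
    the top-k features, k over a descending grid.

    Ranking is recomputed on each training fold (impurity importance of a
    forest on all candidates) unless ``legacy_leaky`` is set.
    """
    ranked_ids = list(ranked_ids)
    if len(ranked_ids) < 2:
        raise ValueError("need at least 2 candidate features")
    labels = np.asarray([str(x) for x in np.asarray(labels)])
    classes, class_counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("curve requires exactly 2 classes")
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples; "
            f"use fewer than {folds} folds")
    pos = {o: j for j, o in enumerate(table.otu_ids)}
    X_all = _matrix(table)[:, [pos[o] for o in ranked_ids]]
    y = labels
    ks = sorted(set(grid)) if grid is not None else default_feature_grid(len(ranked_ids))
    ks = [k for k in ks if 1 <= k <= len(ranked_ids)]
    errors = {k: [] for k in ks}
    global_rank = None
    if legacy_leaky:
        f = _forest.fit_forest(X_all, y, n_trees=n_trees, seed=_child_seed(seed, 9))
        global_rank = np.argsort(-f.feature_importances_, kind="stable")
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=_child_seed(seed, r))
        for f_i, (train, test) in enumerate(skf.split(X_all, y)):
            fold_seed = _child_seed(seed, r, f_i)
            if legacy_leaky:
                rank = global_rank
            else:
                ranker = _forest.fit_forest(X_all[train], y[train],
                                            n_trees=n_trees, seed=fold_seed)
                rank = np.argsort(-ranker.feature_importances_, kind="stable")
            for k in ks:
                cols = rank[:k]
                clf = _forest.fit_forest(X_all[np.ix_(train, cols)], y[train],
                                         n_trees=n_trees, seed=fold_seed)
                pred = clf.predict(X_all[np.ix_(test, cols)])
                errors[k].append(float(np.mean(pred != y[test])))
    return RfcvCurve(
        ks=ks,
        mean_errors=[float(np.mean(errors[k])) for k in ks],
        sd_errors=[float(np.std(errors[k], ddof=1)) for k in ks],
    )


def choose_feature_count(curve: RfcvCurve, rule: str = "min") -> int:
    """Smallest k at the minimum mean error (``min``) or within one SE of
    it (``one-se``)."""
    if not curve.ks:
        raise ValueError("empty curve")
    errs = np.asarray(curve.mean_errors)
    sds = np.asarray(curve.sd_errors)
    if rule == "min":
        best = errs.min()
        chosen = min(k for k, e in zip(curve.ks, errs) if e <= best + 1e-12)
    elif rule == "one-se":
        i_min = int(np.argmin(errs))
        bound = errs[i_min] + sds[i_min]
        chosen = min(k for k, e in zip(curve.ks, errs) if e <= bound + 1e-12)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    curve.chosen_k = int(chosen)
    curve.rule = rule
    return int(chosen)


# ---------------------------------------------------------------------------
# final model


def train_final(table: OtuTable | RelAbundanceTable, labels, panel_ids,
                importance_floor: float = 0.001, n_trees: int = 1000,
                seed: int = 0, positive_label: str | None = None,
                training_cohort: str = "discovery",
                drop_below_floor: bool = False) -> ClassifierModel:
    """Fit the final forest on the full training cohort restricted to the
    panel; panel members whose refit MDA importance falls below the floor
    are reported (and dropped only when requested)."""
    panel_ids = list(panel_ids)
    if not panel_ids:
        raise ValueError("panel must be nonempty")
    missing = [o for o in panel_ids if o not in table.otu_ids]
    if missing:
        raise OtuTableError(f"panel OTUs absent from table: {missing}")
    labels = np.asarray([str(x) for x in np.asarray(labels)])
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("final model requires exactly 2 classes")
    if positive_label is None:
        positive_label = classes[-1]
    pos = {o: j for j, o in enumerate(table.otu_ids)}
    X = _matrix(table)[:, [pos[o] for o in panel_ids]]
    forest = _forest.fit_forest(X, labels, n_trees=n_trees, seed=seed)
    mda = _forest.oob_permutation_importance(forest, X, labels, seed=seed)
    gini = forest.feature_importances_
    imp = pd.DataFrame({"mean_decrease_accuracy": mda,
                        "mean_decrease_gini": gini}, index=panel_ids)
    below = [o for o, v in zip(panel_ids, mda) if v <= importance_floor]
    if drop_below_floor and below and len(below) < len(panel_ids):
        keep = [o for o in panel_ids if o not in below]
        return train_final(table, labels, keep, importance_floor, n_trees,
                           seed, positive_label, training_cohort,
                           drop_below_floor=False)
    return ClassifierModel(
        panel=panel_ids, n_trees=n_trees, seed=seed,
        positive_label=str(positive_label), training_cohort=training_cohort,
        training_sample_ids=list(table.sample_ids), importances=imp,
        below_floor=below, forest=forest, training_matrix=X,
        training_labels=list(labels),
    )


def save_model(model: ClassifierModel, path) -> None:
    """Persist as a versioned JSON sidecar.

    The forest itself is not serialized; the training matrix, labels and
    seed are stored so :func:`load_model` refits it deterministically —
    keeping the artifact plain text.
    """
    doc = {
        "format_version": 1,
        "panel": model.panel,
        "n_trees": model.n_trees,
        "seed": model.seed,
        "positive_label": model.positive_label,
        "training_cohort": model.training_cohort,
        "training_sample_ids": model.training_sample_ids,
        "training_labels": model.training_labels,
        "training_matrix": model.training_matrix.tolist(),
        "importances": model.importances.to_dict(orient="index"),
        "below_floor": model.below_floor,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ClassifierModel:
    with open(path) as fh:
        doc = json.load(fh)
    X = np.asarray(doc["training_matrix"], dtype=float)
    y = np.asarray(doc["training_labels"])
    forest = _forest.fit_forest(X, y, n_trees=doc["n_trees"], seed=doc["seed"])
    imp = pd.DataFrame.from_dict(doc["importances"], orient="index")
    imp = imp.reindex(doc["panel"])
    return ClassifierModel(
        panel=list(doc["panel"]), n_trees=int(doc["n_trees"]),
        seed=int(doc["seed"]), positive_label=doc["positive_label"],
        training_cohort=doc["training_cohort"],
        training_sample_ids=list(doc["training_sample_ids"]),
        importances=imp, below_floor=list(doc["below_floor"]),
        forest=forest, training_matrix=X,
        training_labels=list(doc["training_labels"]),
    )


# ---------------------------------------------------------------------------
# POD scoring and ROC


def _panel_matrix(model: ClassifierModel, table, fill_missing: str | None):
    present = set(table.otu_ids)
    missing = [o for o in model.panel if o not in present]
    mat = _matrix(table)
    pos = {o: j for j, o in enumerate(table.otu_ids)}
    if missing:
        if fill_missing != "zero":
            raise OtuTableError(
                f"panel OTUs absent from table: {missing} "
                "(pass fill_missing='zero' to override)")
        cols = np.zeros((mat.shape[0], len(model.panel)))
        for k, o in enumerate(model.panel):
            if o in pos:
                cols[:, k] = mat[:, pos[o]]
        return cols
    return mat[:, [pos[o] for o in model.panel]]


def _vote_fraction(forest: RandomForestClassifier, X: np.ndarray,
                   positive_label: str) -> np.ndarray:
    idx = list(forest.classes_).index(positive_label)
    return forest.predict_proba(X)[:, idx]


def compute_pod(model: ClassifierModel, table, labels=None,
                mode: str = "external", folds: int = 5, repeats: int = 5,
                fill_missing: str | None = None) -> PodScores:
    """POD per sample: mean fraction of trees voting the disease class.

    ``external`` applies the trained forest as-is.  ``cross-validated``
    refits forests with the model's parameters inside repeated stratified
    folds, scoring each sample only from forests that never saw it.
    """
    X = _panel_matrix(model, table, fill_missing)
    if mode == "external":
        pod = _vote_fraction(model.forest, X, model.positive_label)
        return PodScores(pd.Series(pod, index=table.sample_ids, name="pod"),
                         mode="external")
    if mode != "cross-validated":
        raise ValueError(f"unknown mode {mode!r}")
    if labels is None:
        raise ValueError("cross-validated mode requires labels")
    y = np.asarray([str(x) for x in np.asarray(labels)])
    acc = np.zeros(X.shape[0])
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=_child_seed(model.seed, 7, r))
        for f_i, (train, test) in enumerate(skf.split(X, y)):
            clf = _forest.fit_forest(X[train], y[train], n_trees=model.n_trees,
                                     seed=_child_seed(model.seed, 7, r, f_i))
            acc[test] += _vote_fraction(clf, X[test], model.positive_label)
    pod = acc / repeats
    return PodScores(pd.Series(pod, index=table.sample_ids, name="pod"),
                     mode="cross-validated")


def roc_analysis(pod: PodScores, labels, positive_label: str) -> RocResult:
    """Empirical ROC with trapezoid AUC (equal to U/(n1*n2) under midranks)
    and the Youden-optimal cut-off, ties broken toward higher specificity."""
    y = np.asarray([str(x) for x in np.asarray(labels)])
    scores = pod.scores.to_numpy(dtype=float)
    is_case = y == str(positive_label)
    n_case = int(is_case.sum())
    n_control = int((~is_case).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(is_case.astype(int), scores,
                              drop_intermediate=False)
    auc = float(roc_auc_score(is_case.astype(int), scores))
    sens = tpr
    spec = 1.0 - fpr
    j = sens + spec - 1.0
    # maximise J; on ties prefer higher specificity, then the higher cut-off
    order = sorted(range(len(j)),
                   key=lambda i: (j[i], spec[i], thr[i]), reverse=True)
    best = order[0]
    cutoff = float(thr[best])
    if not np.isfinite(cutoff):  # the sens=0 corner; report the max score
        cutoff = float(scores.max())
    curve = pd.DataFrame({"threshold": thr, "sensitivity": sens,
                          "specificity": spec})
    return RocResult(auc=auc, cutoff=cutoff, sensitivity=float(sens[best]),
                     specificity=float(spec[best]), curve=curve,
                     n_case=n_case, n_control=n_control)


def validate_external(model: ClassifierModel, external_table, external_labels,
                      fill_missing: str | None = None) -> RocResult:
    """Score an external cohort with the trained model and evaluate its ROC."""
    overlap = set(external_table.sample_ids) & set(model.training_sample_ids)
    if overlap:
        raise ValueError(
            f"external cohort overlaps training samples: {sorted(overlap)[:5]}")
    pod = compute_pod(model, external_table, mode="external",
                      fill_missing=fill_missing)
    return roc_analysis(pod, external_labels, model.positive_label)
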