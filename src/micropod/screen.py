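"""Three-criterion candidate-OTU screen on the discovery cohort.

An OTU becomes a key candidate when it (1) exceeds a relative abundance of
0.5% in at least one sample (strict), (2) has a two-sided rank-sum p below
0.01, and (3) shows a mean-decrease-in-accuracy forest importance above
1e-4.  A looser p < 0.05 pre-pass selects the features fed to the
screening forest; both thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from micropod import _forest
from micropod.diversity import compare_groups
from micropod.otu_io import OtuTable, RelAbundanceTable, to_relative_abundance


@dataclass
class ScreenConfig:
    abundance_threshold: float = 0.005
    prepass_p: float = 0.05
    key_p: float = 0.01
    importance_threshold: float = 1e-4
    n_trees: int = 1000
    seed: int = 0
    use_proportions: bool = True   # rank-sum on proportions, not raw counts


@dataclass
class ScreenResult:
    table: pd.DataFrame            # per-OTU: max_abundance, p, importance, passed
    candidates: list[str]          # key OTUs, descending importance

    def __post_init__(self) -> None:
        got = set(self.table.index[self.table["passed"]])
        if got != set(self.candidates):
            raise ValueError("candidates inconsistent with passed flags")


def abundance_filter(rel: RelAbundanceTable, threshold: float = 0.005) -> set[str]:
    """OTUs whose maximum per-sample proportion strictly exceeds threshold."""
    max_ab = rel.values.max(axis=0)
    return {o for o, m in zip(rel.otu_ids, max_ab) if m > threshold}


def wilcoxon_screen(table: OtuTable | RelAbundanceTable, labels) -> pd.Series:
    """Two-sided rank-sum p per OTU; constant OTUs get p = 1 by convention."""
    mat = table.counts if isinstance(table, OtuTable) else table.values
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if levels.size != 2:
        raise ValueError("rank-sum screen requires exactly 2 groups")
    for lvl in levels:
        if np.sum(labels == lvl) < 2:
            raise ValueError(f"group {lvl!r} has fewer than 2 samples")
    pvals = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        col = mat[:, j].astype(float)
        if np.unique(col).size == 1:
            pvals[j] = 1.0
            continue
        pvals[j] = compare_groups(col, labels, mode="two-group")["p"]
    return pd.Series(pvals, index=table.otu_ids, name="p")


def importance_screen(table: OtuTable | RelAbundanceTable, labels,
                      candidate_ids, n_trees: int = 1000, seed: int = 0,
                      threshold: float = 1e-4) -> tuple[set[str], pd.Series]:
    """Forest OOB permutation importance (mean decrease in accuracy) over
    the candidate features; returns (retained ids, importance series)."""
    candidate_ids = list(candidate_ids)
    if len(candidate_ids) < 2:
        raise ValueError("importance screen needs at least 2 candidates")
    mat = table.counts if isinstance(table, OtuTable) else table.values
    pos = {o: j for j, o in enumerate(table.otu_ids)}
    X = mat[:, [pos[o] for o in candidate_ids]].astype(float)
    y = np.asarray(labels)
    forest = _forest.fit_forest(X, y, n_trees=n_trees, seed=seed)
    mda = _forest.oob_permutation_importance(forest, X, y, seed=seed)
    imp = pd.Series(mda, index=candidate_ids, name="importance")
    retained = {o for o, v in imp.items() if v > threshold}
    return retained, imp


def select_candidates(rel: RelAbundanceTable, counts: OtuTable, labels,
                      config: ScreenConfig | None = None) -> ScreenResult:
    """Intersection of the three criteria, ordered by descending importance.

    An empty intersection is returned explicitly (callers halt with a
    message) rather than raising here.
    """
    config = config or ScreenConfig()
    stats_table = rel if config.use_proportions else counts
    max_ab = pd.Series(rel.values.max(axis=0), index=rel.otu_ids,
                       name="max_abundance")
    abundant = abundance_filter(rel, config.abundance_threshold)
    pvals = wilcoxon_screen(stats_table, labels)
    prepass = sorted(abundant & set(pvals.index[pvals < config.prepass_p]))
    importance = pd.Series(np.nan, index=rel.otu_ids, name="importance")
    retained: set[str] = set()
    if len(prepass) >= 2:
        retained, imp = importance_screen(
            stats_table, labels, prepass, n_trees=config.n_trees,
            seed=config.seed, threshold=config.importance_threshold)
        importance.loc[imp.index] = imp
    passed = pd.Series(
        [(o in abundant) and (pvals[o] < config.key_p) and (o in retained)
         for o in rel.otu_ids],
        index=rel.otu_ids, name="passed")
    table = pd.concat([max_ab, pvals, importance, passed], axis=1)
    cand = table.index[table["passed"]]
    candidates = list(cand[np.argsort(-table.loc[cand, "importance"].to_numpy())])
    return ScreenResult(table=table, candidates=candidates)
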