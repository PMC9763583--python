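"""Alpha-diversity estimators, nonparametric group comparisons, and
beta-diversity distances (Bray-Curtis, unweighted/weighted UniFrac).

ACE uses the standard abundance-based coverage estimator with the
mothur/EstimateS rare threshold of 10.  No rarefaction is applied by
default; :func:`rarefy` provides explicit, seeded subsampling for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from micropod.otu_io import OtuTable, OtuTableError, RelAbundanceTable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(np.abs(v - v.T) > 1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12):
            raise ValueError("distances must be nonnegative")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(s) for s in df.index], df.to_numpy())


# ---------------------------------------------------------------------------
# alpha diversity


def observed_otus(sample_counts) -> int:
    """Number of OTUs with a strictly positive count."""
    c = np.asarray(sample_counts)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    return int(np.count_nonzero(c > 0))


def ace_index(sample_counts, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    ACE = S_abund + S_rare / C + (F1 / C) * gamma^2, where C = 1 - F1/N_rare
    and gamma^2 is the bias-corrected squared coefficient of variation of
    rare-OTU frequencies (floored at 0).  With no rare OTUs the estimate is
    the observed richness.  When every rare OTU is a singleton C is zero and
    the estimator is undefined; we fall back to the bias-corrected Chao1
    form S_obs + F1*(F1-1)/2 and flag the sample (see :func:`ace_index_full`).
    """
    return ace_index_full(sample_counts, rare_threshold)[0]


def ace_index_full(sample_counts, rare_threshold: int = 10) -> tuple[float, bool]:
    """ACE value plus a flag marking the singleton-only fallback."""
    c = np.asarray(sample_counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("sample has no positive counts")
    rare = c[c <= rare_threshold]
    s_abund = int(np.sum(c > rare_threshold))
    s_rare = int(rare.size)
    s_obs = s_abund + s_rare
    if s_rare == 0:
        return float(s_obs), False
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0:
        # all rare OTUs are singletons: coverage zero, ACE undefined
        chao1_bc = s_obs + f1 * (f1 - 1) / 2.0
        return float(chao1_bc), True
    freq = np.array([np.sum(rare == i) for i in range(1, rare_threshold + 1)])
    i = np.arange(1, rare_threshold + 1)
    sum_term = float(np.sum(i * (i - 1) * freq))
    gamma2 = (s_rare / c_ace) * sum_term / (n_rare * (n_rare - 1)) - 1.0 \
        if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2
    return float(ace), False


def alpha_diversity_table(table: OtuTable, rare_threshold: int = 10) -> pd.DataFrame:
    """Per-sample observed richness and ACE as a long-friendly frame."""
    rows = []
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        ace, flagged = ace_index_full(counts, rare_threshold)
        rows.append({"sample_id": sid, "observed": observed_otus(counts),
                     "ace": ace, "ace_fallback": flagged})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# group comparisons


def compare_groups(values, labels, mode: str = "two-group",
                   exact_max_n: int = 20) -> dict:
    """Mann-Whitney U (two-group) or Kruskal-Wallis H (multi-group).

    Two-group mode uses the exact U distribution when the combined sample
    size is at most ``exact_max_n`` and there are no ties; otherwise the
    normal approximation with tie correction.  Returns a dict with
    ``statistic``, ``p`` and ``method``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    groups = [values[labels == g] for g in levels]
    for g, lvl in zip(groups, levels):
        if g.size == 0:
            raise ValueError(f"group {lvl!r} is empty")
    if mode == "two-group":
        if len(groups) != 2:
            raise ValueError("two-group mode requires exactly 2 groups")
        x, y = groups
        has_ties = np.unique(values).size < values.size
        n = x.size + y.size
        method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return {"statistic": float(res.statistic), "p": float(res.pvalue),
                "method": f"mann-whitney-{method}"}
    if mode == "multi-group":
        if len(groups) < 2:
            raise ValueError("multi-group mode requires >=2 groups")
        res = stats.kruskal(*groups)
        return {"statistic": float(res.statistic), "p": float(res.pvalue),
                "method": "kruskal-wallis"}
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(table: OtuTable | RelAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y) per sample pair."""
    mat = table.counts if isinstance(table, OtuTable) else table.values
    d = squareform(pdist(mat.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def _branch_sample_mass(table: OtuTable, tree: TreeNode):
    """Per-branch descending count totals for every sample.

    Returns (branch_lengths, mass) where mass[b, i] is the number of reads
    of sample i descending through branch b.  The root branch is excluded.
    """
    leaf_col = {}
    for leaf in tree.tips():
        leaf_col[leaf.name] = None
    pos = {o: j for j, o in enumerate(table.otu_ids)}
    used = np.flatnonzero(table.counts.sum(axis=0) > 0)
    missing = [table.otu_ids[j] for j in used if table.otu_ids[j] not in leaf_col]
    if missing:
        raise OtuTableError(f"OTUs absent from tree: {missing}")
    n = table.n_samples
    lengths = []
    masses = []
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            m = np.zeros(n)
            j = pos.get(node.name)
            if j is not None:
                m = table.counts[:, j].astype(float)
        else:
            m = np.zeros(n)
            for child in node.children:
                m = m + node_mass[id(child)]
        node_mass[id(node)] = m
        if node.is_root():
            continue
        length = node.length if node.length is not None else 0.0
        if length < 0:
            raise OtuTableError("negative branch length in tree")
        lengths.append(length)
        masses.append(m)
    return np.asarray(lengths), np.asarray(masses)


def unifrac(table: OtuTable, tree: TreeNode, weighted: bool = True,
            normalized: bool = True) -> DistanceMatrix:
    """UniFrac dissimilarity between all sample pairs.

    Unweighted: fraction of branch length unique to one sample's leaf set
    out of the branch length in either set.  Weighted: sum of b*|pA - pB|
    over branches, with p the fraction of a sample's reads descending from
    the branch; the normalized variant divides by sum of b*(pA + pB).
    """
    lengths, mass = _branch_sample_mass(table, tree)
    totals = table.sample_totals().astype(float)
    n = table.n_samples
    d = np.zeros((n, n))
    if weighted:
        p = mass / totals[None, :]
        for i in range(n):
            for j in range(i + 1, n):
                num = float(np.sum(lengths * np.abs(p[:, i] - p[:, j])))
                if normalized:
                    den = float(np.sum(lengths * (p[:, i] + p[:, j])))
                    d[i, j] = d[j, i] = num / den if den > 0 else 0.0
                else:
                    d[i, j] = d[j, i] = num
    else:
        present = mass > 0
        for i in range(n):
            for j in range(i + 1, n):
                either = present[:, i] | present[:, j]
                unique = present[:, i] ^ present[:, j]
                den = float(np.sum(lengths[either]))
                num = float(np.sum(lengths[unique]))
                d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(list(table.sample_ids), d)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples shallower than ``depth`` are dropped.  Explicit and seeded so
    the (optional) normalization step is reproducible.
    """
    rng = np.random.default_rng(seed)
    keep_rows = []
    new_counts = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        total = int(row.sum())
        if total < depth:
            continue
        reads = np.repeat(np.arange(table.n_otus), row)
        sub = rng.choice(reads, size=depth, replace=False)
        new_counts.append(np.bincount(sub, minlength=table.n_otus))
        keep_rows.append(sid)
    if not keep_rows:
        raise OtuTableError(f"no sample reaches rarefaction depth {depth}")
    return OtuTable(keep_rows, list(table.otu_ids), np.asarray(new_counts))
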