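"""PCoA, NMDS and the ANOSIM permutation test on a distance matrix."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.manifold import MDS

from micropod.diversity import DistanceMatrix


@dataclass
class OrdinationResult:
    method: str
    sample_ids: list[str]
    coordinates: np.ndarray          # samples x axes
    eigenvalues: np.ndarray | None = None   # PCoA: full spectrum, descending
    proportion_explained: np.ndarray | None = None
    stress: float | None = None      # NMDS: Kruskal stress-1
    converged: bool | None = None

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class AnosimResult:
    r: float
    n_permutations: int
    p: float

    def to_dict(self) -> dict:
        return {"R": self.r, "n_permutations": self.n_permutations, "p": self.p}


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); axes with
    non-positive eigenvalues are excluded but the full spectrum (including
    negatives) is reported.  No correction is applied to negative
    eigenvalues.
    """
    if dm.n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    d2 = dm.values ** 2
    n = dm.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > max(1e-10 * abs(eigvals[0]), 1e-12)
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {k_eff} axes",
            stacklevel=2,
        )
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    pos_sum = eigvals[pos].sum()
    prop = np.where(eigvals > 0, eigvals / pos_sum, 0.0) if pos_sum > 0 else eigvals * 0
    return OrdinationResult(
        method="pcoa",
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def nmds(dm: DistanceMatrix, k: int = 2, restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-7, seed: int = 0) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1; best of ``restarts``
    random starts, deterministic given ``seed``.

    A non-converged best start is flagged but still returned.
    """
    if dm.n < k + 2:
        raise ValueError("NMDS requires n >= k + 2")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=restarts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(dm.values)
    converged = model.n_iter_ < max_iter
    return OrdinationResult(
        method="nmds",
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        stress=float(model.stress_),
        converged=bool(converged),
    )


def _anosim_r(cond_ranks: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    rb = cond_ranks[~within_mask].mean()
    rw = cond_ranks[within_mask].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def _within_mask(labels: np.ndarray) -> np.ndarray:
    n = labels.size
    mask = []
    for i in range(n):
        for j in range(i + 1, n):
            mask.append(labels[i] == labels[j])
    return np.asarray(mask)


def anosim(dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0,
           exhaustive: bool = False) -> AnosimResult:
    """Clarke's analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2, computed on midranks of all pairwise distances.  The
    permutation p uses the add-one rule, so it is never 0.  With
    ``exhaustive`` every distinct label permutation is enumerated (the
    identity included), which the Monte-Carlo p converges to.
    """
    labels = np.asarray([str(x) for x in np.asarray(labels)])
    if labels.size != dm.n:
        raise ValueError("labels length must match distance matrix")
    levels, counts = np.unique(labels, return_counts=True)
    if levels.size < 2:
        raise ValueError("ANOSIM requires at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 samples")
    cond = dm.condensed()
    ranks = rankdata(cond)  # midranks on ties
    n = dm.n
    obs = _anosim_r(ranks, _within_mask(labels), n)
    if exhaustive:
        seen = set()
        count_ge = 0
        total = 0
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            r = _anosim_r(ranks, _within_mask(np.asarray(perm)), n)
            total += 1
            if r >= obs - 1e-12:
                count_ge += 1
        return AnosimResult(r=obs, n_permutations=total, p=count_ge / total)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, _within_mask(perm), n) >= obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return AnosimResult(r=obs, n_permutations=n_perm, p=p)
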