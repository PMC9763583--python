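"""SparCC compositional correlation with bootstrap pseudo-p-values.

Implements the classical estimator: per inner resample, component
fractions are drawn from the posterior of each sample's composition under
a uniform prior (Dirichlet(counts + 1)); log-ratio variances
t_ij = Var(log(x_i/x_j)) are converted to basis variances through the
sparsity-assumption linear system, and correlations follow as
rho_ij = (w_i + w_j - t_ij) / (2*sqrt(w_i*w_j)).  The strongest pair above
an exclusion threshold is iteratively removed from the system and the
solve repeated; estimates are averaged over resamples.

Clinical indicators can ride along as continuous log pseudo-components —
a pragmatic extension for OTU-vs-laboratory correlation, with a Spearman
fallback for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SparccResult:
    component_ids: list[str]
    rho: np.ndarray
    omega2: np.ndarray                      # estimated basis variances
    pvalues: np.ndarray | None = None
    n_clipped: int = 0
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    def rho_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.component_ids,
                            columns=self.component_ids)

    def p_frame(self) -> pd.DataFrame:
        if self.pvalues is None:
            raise ValueError("p-values not computed")
        return pd.DataFrame(self.pvalues, index=self.component_ids,
                            columns=self.component_ids)


def _log_abundance(counts: np.ndarray, continuous_mask: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-sample log fractions; continuous columns pass through as-is
    (they are already log values, not counts)."""
    out = np.empty_like(counts, dtype=float)
    comp = ~continuous_mask
    if comp.any():
        alpha = counts[:, comp] + 1.0
        fracs = np.apply_along_axis(rng.dirichlet, 1, alpha)
        out[:, comp] = np.log(fracs)
    if continuous_mask.any():
        out[:, continuous_mask] = counts[:, continuous_mask]
    return out


def _basis_solve(t: np.ndarray, excluded: set[tuple[int, int]]):
    d = t.shape[0]
    m = np.ones((d, d)) + np.eye(d) * (d - 2)
    t_eff = t.copy()
    for i, j in excluded:
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_eff[i, j] = t_eff[j, i] = 0.0
    t_sums = t_eff.sum(axis=1)
    try:
        omega2 = np.linalg.solve(m, t_sums)
    except np.linalg.LinAlgError:
        omega2 = np.linalg.lstsq(m, t_sums, rcond=None)[0]
    return omega2


def _one_sparcc_pass(logx: np.ndarray, exclusion_rho: float,
                     max_exclusions: int):
    """One variation-matrix -> basis-correlation estimation pass."""
    d = logx.shape[1]
    cov = np.cov(logx, rowvar=False)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    excluded: set[tuple[int, int]] = set()
    n_clipped = 0
    for _ in range(max_exclusions + 1):
        omega2 = _basis_solve(t, excluded)
        neg = omega2 <= 0
        n_clipped += int(neg.sum())
        omega2 = np.where(neg, 1e-12, omega2)
        denom = 2.0 * np.sqrt(np.outer(omega2, omega2))
        rho = (omega2[:, None] + omega2[None, :] - t) / denom
        clip_mask = np.abs(rho) > 1.0
        np.fill_diagonal(clip_mask, False)
        n_clipped += int(clip_mask.sum())
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        if len(excluded) >= max_exclusions:
            break
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        # a component may lose at most d-3 partners or the system degenerates
        excl_count = np.zeros(d, dtype=int)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
            excl_count[i] += 1
            excl_count[j] += 1
        saturated = np.flatnonzero(excl_count >= d - 3)
        cand[saturated, :] = 0.0
        cand[:, saturated] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_rho:
            break
        excluded.add((min(i, j), max(i, j)))
    return rho, omega2, n_clipped, excluded


def sparcc_correlate(counts, component_ids=None, n_inner: int = 20,
                     exclusion_rho: float = 0.1, max_exclusions: int = 10,
                     seed: int = 0, continuous_mask=None) -> SparccResult:
    """Estimate basis correlations from a samples x components count matrix.

    ``continuous_mask`` marks columns that are log-scale continuous
    covariates rather than counts (used for clinical pseudo-components).
    """
    counts = np.asarray(counts, dtype=float)
    n, d = counts.shape
    if d < 4:
        raise ValueError(
            "SparCC needs >=4 components for an identifiable basis system")
    if component_ids is None:
        component_ids = [f"c{j}" for j in range(d)]
    if continuous_mask is None:
        continuous_mask = np.zeros(d, dtype=bool)
    continuous_mask = np.asarray(continuous_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    rhos = np.zeros((n_inner, d, d))
    omegas = np.zeros((n_inner, d))
    total_clipped = 0
    excl_union: set[tuple[int, int]] = set()
    for it in range(n_inner):
        logx = _log_abundance(counts, continuous_mask, rng)
        rho, omega2, ncl, excl = _one_sparcc_pass(logx, exclusion_rho,
                                                  max_exclusions)
        rhos[it] = rho
        omegas[it] = omega2
        total_clipped += ncl
        excl_union |= excl
    rho_mean = rhos.mean(axis=0)
    rho_mean = np.clip((rho_mean + rho_mean.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_mean, 1.0)
    ids = [str(c) for c in component_ids]
    return SparccResult(
        component_ids=ids, rho=rho_mean, omega2=omegas.mean(axis=0),
        n_clipped=total_clipped,
        exclusions=sorted((ids[i], ids[j]) for i, j in excl_union),
    )


def sparcc_pvalues(counts, observed: SparccResult, n_boot: int = 100,
                   seed: int = 0, n_inner: int = 5,
                   exclusion_rho: float = 0.1, max_exclusions: int = 10,
                   continuous_mask=None) -> np.ndarray:
    """Two-sided bootstrap pseudo-p: columns are shuffled independently to
    break cross-component association; p = (1 + #{|rho_boot| >= |rho_obs|})
    / (1 + n_boot), never 0."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    counts = np.asarray(counts, dtype=float)
    n, d = counts.shape
    rng = np.random.default_rng(seed)
    exceed = np.zeros((d, d))
    obs_abs = np.abs(observed.rho)
    for b in range(n_boot):
        shuffled = np.column_stack([counts[rng.permutation(n), j]
                                    for j in range(d)])
        boot = sparcc_correlate(
            shuffled, n_inner=n_inner, exclusion_rho=exclusion_rho,
            max_exclusions=max_exclusions,
            seed=int(rng.integers(2**31)), continuous_mask=continuous_mask)
        exceed += np.abs(boot.rho) >= obs_abs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_boot)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 1.0)
    observed.pvalues = p
    return p


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def clinical_association(panel_counts, otu_ids, meta: pd.DataFrame,
                         indicators=("ALB", "Pro24h", "SCr"),
                         method: str = "sparcc", n_inner: int = 20,
                         n_boot: int = 100, seed: int = 0) -> pd.DataFrame:
    """Correlate panel OTUs with clinical indicators.

    ``sparcc`` appends each indicator as a log-transformed pseudo-component
    (min-shifted positive if needed, flagged in the output) and runs the
    compositional estimator on the joint matrix; ``spearman`` is the plain
    rank-correlation fallback.  Samples missing any requested indicator are
    dropped (complete-case); fewer than 10 complete samples is an error.
    Returns the long-format OTU x indicator block with significance stars.
    """
    panel_counts = np.asarray(panel_counts, dtype=float)
    otu_ids = [str(o) for o in otu_ids]
    indicators = list(indicators)
    missing_cols = [c for c in indicators if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"indicators absent from metadata: {missing_cols}")
    clin = meta[indicators].apply(pd.to_numeric, errors="coerce")
    complete = clin.dropna().index
    if len(complete) < 10:
        raise ValueError(
            f"only {len(complete)} samples have complete indicators (<10)")
    row_of = {s: i for i, s in enumerate(meta.index)}
    rows = [row_of[s] for s in complete]
    counts_c = panel_counts[rows]
    clin_c = clin.loc[complete]
    for col in indicators:
        if clin_c[col].nunique() <= 1:
            raise ValueError(f"indicator {col!r} is constant (zero variance)")
    if method == "spearman":
        recs = []
        for i, otu in enumerate(otu_ids):
            for col in indicators:
                rho, p = stats.spearmanr(counts_c[:, i], clin_c[col])
                recs.append({"otu": otu, "indicator": col, "rho": float(rho),
                             "p": float(p), "stars": _stars(p),
                             "n": len(complete), "method": "spearman"})
        return pd.DataFrame(recs)
    if method != "sparcc":
        raise ValueError(f"unknown method {method!r}")
    shifted = []
    log_clin = np.empty(clin_c.shape)
    for k, col in enumerate(indicators):
        vals = clin_c[col].to_numpy(dtype=float)
        if vals.min() <= 0:
            vals = vals - vals.min() + np.abs(vals).max() * 1e-3 + 1e-9
            shifted.append(col)
        lv = np.log(vals)
        # standardize the log pseudo-component: the implied basis
        # correlation is invariant to linear rescaling of a log variable,
        # but the variance solve is badly conditioned for near-constant
        # indicators (e.g. log ALB varies ~0.01 vs ~1 for log fractions)
        log_clin[:, k] = (lv - lv.mean()) / lv.std(ddof=1)
    joint = np.column_stack([counts_c, log_clin])
    ids = otu_ids + indicators
    mask = np.zeros(len(ids), dtype=bool)
    mask[len(otu_ids):] = True
    res = sparcc_correlate(joint, component_ids=ids, n_inner=n_inner,
                           seed=seed, continuous_mask=mask)
    sparcc_pvalues(joint, res, n_boot=n_boot, seed=seed + 1,
                   n_inner=max(2, n_inner // 4), continuous_mask=mask)
    res.flags["log_shifted_indicators"] = shifted
    res.flags["n_complete"] = int(len(complete))
    recs = []
    for i, otu in enumerate(otu_ids):
        for k, col in enumerate(indicators):
            j = len(otu_ids) + k
            recs.append({"otu": otu, "indicator": col,
                         "rho": float(res.rho[i, j]),
                         "p": float(res.pvalues[i, j]),
                         "stars": _stars(res.pvalues[i, j]),
                         "n": len(complete), "method": "sparcc"})
    return pd.DataFrame(recs)
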