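"""Synthetic two-group cohort generator.

Produces Dirichlet-multinomial OTU count tables with a minority of planted
differential OTUs at configurable fold changes, variable sequencing depth,
a random bifurcating phylogeny, cohort/batch effects for external
validation experiments, age/sex metadata (with an optional group shift to
exercise matching), and clinical indicators linearly coupled to chosen
OTUs on the log-abundance scale.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from micropod.otu_io import OtuTable, TaxonomyMap, RANKS


@dataclass
class Coupling:
    """Indicator = intercept + slope * log10(rel. abundance of OTU) + noise."""
    otu_index: int
    indicator: str          # ALB | Pro24h | SCr
    slope: float
    noise_sd: float = 0.1
    intercept: float = 0.0


@dataclass
class SyntheticSpec:
    n_case: int = 30
    n_control: int = 31
    n_otus: int = 200
    n_effect: int = 8
    fold_change: float = 4.0
    depth_mean: float = 10000.0
    depth_dispersion: float = 0.3        # lognormal sigma of depth
    base_abundance_sigma: float = 1.5    # lognormal spread of base means
    theta: float = 0.2                   # Dirichlet concentration (overdispersion)
    batch_sigma: float = 0.0             # per-OTU log-normal batch offset scale
    case_age_shift: float = 0.0
    couplings: list[Coupling] = field(default_factory=list)
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if self.n_effect > self.n_otus:
            raise ValueError("n_effect cannot exceed n_otus")
        for name, v in (("n_case", self.n_case), ("n_control", self.n_control),
                        ("n_otus", self.n_otus), ("fold_change", self.fold_change),
                        ("depth_mean", self.depth_mean), ("theta", self.theta)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for c in self.couplings:
            if not 0 <= c.otu_index < self.n_otus:
                raise ValueError(f"coupling OTU index {c.otu_index} out of range")


@dataclass
class SyntheticTruth:
    effect_otus: list[str]
    fold_changes: dict[str, float]       # >1 enriched in cases, <1 depleted
    couplings: list[dict]
    batch_offsets: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _draw_truth(spec: SyntheticSpec, rng: np.random.Generator):
    base = rng.lognormal(mean=0.0, sigma=spec.base_abundance_sigma,
                         size=spec.n_otus)
    # plant effects among detectable taxa (upper half of base abundance),
    # as real biomarkers must clear the relative-abundance screen
    eligible = np.flatnonzero(base >= np.median(base))
    effect_idx = np.sort(rng.choice(eligible, spec.n_effect, replace=False))
    # half enriched in cases, half depleted
    fold = np.ones(spec.n_otus)
    for r, j in enumerate(effect_idx):
        fold[j] = spec.fold_change if r < spec.n_effect - spec.n_effect // 2 \
            else 1.0 / spec.fold_change
    return base, effect_idx, fold


def random_tree(otu_ids, rng: np.random.Generator,
                branch_scale: float = 0.1) -> TreeNode:
    """Random bifurcating tree with exponential branch lengths."""
    nodes = [TreeNode(name=o, length=float(rng.exponential(branch_scale)) + 1e-6)
             for o in otu_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(branch_scale)) + 1e-6)
        parent.extend([left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _sample_counts(mean_profile: np.ndarray, n_samples: int,
                   spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    props = mean_profile / mean_profile.sum()
    alpha = spec.theta * props * props.size  # scale so theta ~ per-OTU concentration
    out = np.zeros((n_samples, props.size), dtype=np.int64)
    for i in range(n_samples):
        depth = int(max(500, round(rng.lognormal(np.log(spec.depth_mean),
                                                 spec.depth_dispersion))))
        comp = rng.dirichlet(alpha)
        out[i] = rng.multinomial(depth, comp)
        if out[i].sum() == 0:  # unreachable with depth >= 500; safety net
            out[i, 0] = 1
    return out


_INDICATOR_BASELINES = {"ALB": (40.0, 4.0), "Pro24h": (1.0, 0.4),
                        "SCr": (80.0, 12.0)}


def _metadata(table: OtuTable, labels, spec: SyntheticSpec, cohort: str,
              rng: np.random.Generator) -> pd.DataFrame:
    n = table.n_samples
    labels = np.asarray(labels)
    is_case = labels == spec.case_label
    age = rng.normal(45.0, 12.0, size=n) + np.where(is_case,
                                                    spec.case_age_shift, 0.0)
    age = np.clip(age, 18.0, 90.0)
    sex = rng.integers(0, 2, size=n)
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    meta = pd.DataFrame({"group": labels, "age": np.round(age, 1), "sex": sex,
                         "cohort": cohort}, index=table.sample_ids)
    coupled = {c.indicator: c for c in spec.couplings}
    for ind, (mu, sd) in _INDICATOR_BASELINES.items():
        base = rng.normal(mu, sd, size=n)
        if ind in coupled:
            c = coupled[ind]
            logab = np.log10(rel[:, c.otu_index] + 1e-6)
            base = c.intercept + mu + c.slope * logab \
                + rng.normal(0.0, c.noise_sd, size=n)
        vals = np.maximum(base, 0.01)  # clinical values never negative
        meta[ind] = np.round(vals, 3)
    return meta


def _build_cohort(spec: SyntheticSpec, base: np.ndarray, fold: np.ndarray,
                  batch: np.ndarray, cohort: str, prefix: str,
                  rng: np.random.Generator):
    otu_ids = [f"OTU{j + 1}" for j in range(spec.n_otus)]
    case_means = base * fold * batch
    control_means = base * batch
    case_counts = _sample_counts(case_means, spec.n_case, spec, rng)
    control_counts = _sample_counts(control_means, spec.n_control, spec, rng)
    sample_ids = [f"{prefix}case{i + 1:03d}" for i in range(spec.n_case)] + \
                 [f"{prefix}ctrl{i + 1:03d}" for i in range(spec.n_control)]
    labels = [spec.case_label] * spec.n_case + [spec.control_label] * spec.n_control
    table = OtuTable(sample_ids, otu_ids,
                     np.vstack([case_counts, control_counts]))
    meta = _metadata(table, labels, spec, cohort, rng)
    return table, meta


def generate_cohort(spec: SyntheticSpec, seed: int = 0):
    """Generate one cohort: (OtuTable, metadata, tree, SyntheticTruth)."""
    rng = np.random.default_rng(seed)
    base, effect_idx, fold = _draw_truth(spec, rng)
    batch = np.ones(spec.n_otus)
    table, meta = _build_cohort(spec, base, fold, batch, "cohort0", "", rng)
    tree = random_tree(table.otu_ids, rng)
    truth = SyntheticTruth(
        effect_otus=[table.otu_ids[j] for j in effect_idx],
        fold_changes={table.otu_ids[j]: float(fold[j]) for j in effect_idx},
        couplings=[asdict(c) for c in spec.couplings],
    )
    return table, meta, tree, truth


def generate_multicohort(spec: SyntheticSpec, n_cohorts: int = 2,
                         batch_sigma: float | None = None, seed: int = 0,
                         sizes=None, flip_effect_in=()):
    """Cohorts sharing planted truth, each with independent per-OTU batch
    offsets of scale ``batch_sigma``.

    ``sizes`` optionally overrides (n_case, n_control) per cohort (default
    mirrors a small 10+10 external-validation cohort for cohorts beyond the
    first).  ``flip_effect_in`` lists cohort indices whose effect direction
    is inverted — an adversarial transfer scenario.
    """
    if n_cohorts < 2:
        raise ValueError("need at least 2 cohorts")
    if batch_sigma is None:
        batch_sigma = spec.batch_sigma
    rng = np.random.default_rng(seed)
    base, effect_idx, fold = _draw_truth(spec, rng)
    otu_ids = [f"OTU{j + 1}" for j in range(spec.n_otus)]
    tree = random_tree(otu_ids, rng)
    truth = SyntheticTruth(
        effect_otus=[otu_ids[j] for j in effect_idx],
        fold_changes={otu_ids[j]: float(fold[j]) for j in effect_idx},
        couplings=[asdict(c) for c in spec.couplings],
    )
    cohorts = []
    for c in range(n_cohorts):
        cspec = spec
        if sizes is not None:
            n_case, n_control = sizes[c]
        elif c == 0:
            n_case, n_control = spec.n_case, spec.n_control
        else:
            n_case, n_control = 10, 10
        cspec = SyntheticSpec(**{**asdict(spec), "couplings": spec.couplings,
                                 "n_case": n_case, "n_control": n_control})
        # cohort 0 is the reference; only later cohorts receive offsets
        batch = rng.lognormal(0.0, batch_sigma, size=spec.n_otus) \
            if batch_sigma > 0 and c > 0 else np.ones(spec.n_otus)
        cfold = fold.copy()
        if c in flip_effect_in:
            cfold = np.where(cfold != 1.0, 1.0 / cfold, 1.0)
        name = f"cohort{c}"
        table, meta = _build_cohort(cspec, base, cfold, batch, name,
                                    f"c{c}_", rng)
        truth.batch_offsets[name] = [float(x) for x in np.log(batch)]
        cohorts.append((table, meta))
    return cohorts, tree, truth


def placeholder_taxonomy(otu_ids, seed: int = 0) -> TaxonomyMap:
    """Placeholder ranked lineages (rotating phyla, one genus per OTU)."""
    rng = np.random.default_rng(seed)
    phyla = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria"]
    lineages = {}
    for o in otu_ids:
        p = phyla[int(rng.integers(len(phyla)))]
        lineages[o] = ("Bacteria", p, f"{p}_c", f"{p}_o", f"{p}_f",
                       f"g_{o}")
    return TaxonomyMap(lineages, RANKS)
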