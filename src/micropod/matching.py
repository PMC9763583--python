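"""Propensity-score 1:1 case/control matching and the 2:1 cohort split."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression


@dataclass
class MatchedCohort:
    pairs: list[tuple[str, str]]          # (case_id, control_id)
    coefficients: dict[str, float]
    caliper: float
    unmatched_cases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        used = [x for pair in self.pairs for x in pair]
        if len(used) != len(set(used)):
            raise ValueError("a sample id appears in more than one pair")

    @property
    def sample_ids(self) -> list[str]:
        return [x for pair in self.pairs for x in pair]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id"])


@dataclass
class CohortSplit:
    discovery: list[str]
    validation: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.discovery) & set(self.validation):
            raise ValueError("discovery and validation sets overlap")


def propensity_scores(meta: pd.DataFrame, case_label: str,
                      control_label: str) -> tuple[pd.Series, dict[str, float]]:
    """Logit of P(case | age, sex) from an unpenalized logistic model."""
    sub = meta[meta["group"].isin([case_label, control_label])]
    X = sub[["age", "sex"]].astype(float).to_numpy()
    if np.any(~np.isfinite(X)):
        raise ValueError("age and sex must be present for every sample")
    y = (sub["group"] == case_label).astype(int).to_numpy()
    model = LogisticRegression(C=float("inf"), solver="lbfgs", max_iter=1000)
    model.fit(X, y)
    logit = X @ model.coef_[0] + model.intercept_[0]
    coefs = {"intercept": float(model.intercept_[0]),
             "age": float(model.coef_[0][0]),
             "sex": float(model.coef_[0][1])}
    return pd.Series(logit, index=sub.index), coefs


def propensity_match(meta: pd.DataFrame, case_label: str = "case",
                     control_label: str = "control",
                     caliper_sd: float = 0.2, seed: int = 0) -> MatchedCohort:
    """Greedy nearest-neighbor 1:1 matching on the propensity logit.

    Cases are matched hardest-first (descending propensity) without
    replacement; the caliper is ``caliper_sd`` times the SD of the logit.
    Cases with no control inside the caliper are reported unmatched — an
    entirely unmatchable cohort yields an empty match list with a warning,
    never a crash.
    """
    logit, coefs = propensity_scores(meta, case_label, control_label)
    sd = float(np.std(logit.to_numpy(), ddof=1)) if logit.size > 1 else 0.0
    caliper = caliper_sd * sd if sd > 0 else np.inf
    cases = logit[meta.loc[logit.index, "group"] == case_label]
    controls = logit[meta.loc[logit.index, "group"] == control_label]
    if cases.empty or controls.empty:
        raise ValueError("need at least one case and one control")
    # stable order: descending propensity, id as tiebreak
    case_order = sorted(cases.index, key=lambda s: (-cases[s], s))
    available = dict(controls.items())
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for cid in case_order:
        if not available:
            unmatched.append(cid)
            continue
        best = min(available, key=lambda k: (abs(available[k] - cases[cid]), k))
        if abs(available[best] - cases[cid]) <= caliper:
            pairs.append((str(cid), str(best)))
            del available[best]
        else:
            unmatched.append(str(cid))
    if not pairs:
        warnings.warn("no case/control pair within caliper; empty match list",
                      stacklevel=2)
    return MatchedCohort(pairs=pairs, coefficients=coefs, caliper=caliper,
                         unmatched_cases=unmatched)


def split_discovery_validation(matched: MatchedCohort,
                               ratio: tuple[int, int] = (2, 1),
                               seed: int = 0) -> CohortSplit:
    """Randomize matched *pairs* (never splitting one) to discovery vs
    validation at ``ratio``; discovery gets the ceiling on uneven splits."""
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("ratio parts must be positive")
    n = len(matched.pairs)
    if n < 3:
        raise ValueError("need at least 3 matched pairs to split")
    n_disc = math.ceil(n * ratio[0] / (ratio[0] + ratio[1]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    disc_pairs = [matched.pairs[i] for i in sorted(order[:n_disc])]
    val_pairs = [matched.pairs[i] for i in sorted(order[n_disc:])]
    discovery = [x for p in disc_pairs for x in p]
    validation = [x for p in val_pairs for x in p]
    return CohortSplit(discovery=discovery, validation=validation, seed=seed)


def standardized_mean_difference(x_case, x_control) -> float:
    """|SMD| of a covariate between matched groups (pooled-SD denominator)."""
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    pooled = np.sqrt((np.var(x_case, ddof=1) + np.var(x_control, ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(x_case.mean() - x_control.mean()) / pooled)
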