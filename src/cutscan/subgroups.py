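"""Applying certified cut-points: stratification and survival modelling.

One or two certified percentile cut-points split the cohort into two
(low/high) or three (low/inter/high) expression subgroups using the same
floor-rank arithmetic as the scan engine.  Survival is summarized with
Kaplan-Meier product-limit curves per group and hazard ratios of each
non-low group relative to the low group, all from one Cox model with
indicator covariates.  The clinical workflow around a new biomarker is also
covered: a univariate screen (Fisher's exact test for categorical
covariates, Wilcoxon rank-sum for continuous ones) and a multivariate Cox
model pruned by backward elimination on AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .cohort import ClinicalTable, CohortTrait, SurvivalOutcome
from .scan import n_low_at

__all__ = [
    "assign_subgroups",
    "survival_summary",
    "univariate_screen",
    "multivariate_cox_backward_aic",
    "SubgroupAssignment",
    "SurvivalSummary",
    "MultivariateModel",
]

GROUP_NAMES = {2: ("low", "high"), 3: ("low", "inter", "high")}


@dataclass(frozen=True)
class SubgroupAssignment:
    sample_ids: np.ndarray
    labels: np.ndarray            # 'low' / 'inter' / 'high'
    cutpoints: tuple
    group_sizes: dict

    @property
    def group_names(self) -> tuple:
        return GROUP_NAMES[len(self.cutpoints) + 1]

    def mask(self, name: str) -> np.ndarray:
        return self.labels == name


def assign_subgroups(trait: CohortTrait, cutpoints) -> SubgroupAssignment:
    """Stratify into 2 or 3 rank-ordered groups at the given percentiles.

    With cutpoints ``[c1, c2]``: low = ranks below ``floor(c1*n/100)``,
    high = ranks at or above ``floor(c2*n/100)``, inter = the rest.  An
    empty group raises, naming the offending cutpoint.
    """
    cuts = [float(c) for c in cutpoints]
    if not 1 <= len(cuts) <= 2:
        raise ValueError("need one or two cutpoints")
    if any(not 0 < c < 100 for c in cuts) or cuts != sorted(cuts):
        raise ValueError(f"cutpoints must be ascending and inside (0, 100): {cuts}")
    n = trait.n
    bounds = [n_low_at(n, c) for c in cuts]
    names = GROUP_NAMES[len(cuts) + 1]
    ranks = trait.ranks()
    labels = np.empty(n, dtype=object)
    labels[:] = names[-1]
    edges = [0] + bounds + [n]
    for name, lo, hi in zip(names, edges[:-1], edges[1:]):
        if hi - lo == 0:
            cut = cuts[0] if name == "low" else cuts[-1]
            raise ValueError(f"empty {name} group at cutpoint {cut}%")
        labels[(ranks >= lo) & (ranks < hi)] = name
    sizes = {name: int((labels == name).sum()) for name in names}
    return SubgroupAssignment(trait.sample_ids, labels, tuple(cuts), sizes)


@dataclass(frozen=True)
class SurvivalSummary:
    km_curves: dict               # group -> DataFrame(time, survival, n_at_risk, n_events)
    hazard_ratios: pd.DataFrame   # index: non-low groups; HR, ci, p vs low
    flags: tuple = field(default=())

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for g, df in self.km_curves.items():
            part = df.copy()
            part.insert(0, "group", g)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def survival_summary(assignment: SubgroupAssignment, outcome: SurvivalOutcome) -> SurvivalSummary:
    """KM curves per subgroup plus HRs of each non-low group vs low.

    The HRs come from a single Cox model with one indicator per non-low
    group.  A group with zero events gets an unbounded CI and a flag rather
    than an error.
    """
    if not np.array_equal(assignment.sample_ids, outcome.sample_ids):
        raise ValueError("assignment and outcome must be aligned")
    flags = []
    km = {}
    for g in assignment.group_names:
        m = assignment.mask(g)
        kmf = KaplanMeierFitter()
        kmf.fit(outcome.time[m], outcome.event[m], label=g)
        tbl = kmf.event_table
        km[g] = pd.DataFrame({
            "time": tbl.index.to_numpy(),
            "survival": kmf.survival_function_[g].to_numpy(),
            "n_at_risk": tbl["at_risk"].to_numpy(),
            "n_events": tbl["observed"].to_numpy(),
        })
        if outcome.event[m].sum() == 0:
            flags.append(f"group {g!r} has zero events")

    non_low = [g for g in assignment.group_names if g != "low"]
    df = pd.DataFrame({"T": outcome.time, "E": outcome.event})
    for g in non_low:
        df[f"is_{g}"] = assignment.mask(g).astype(int)
    rows = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, "T", "E")
        for g in non_low:
            s = cph.summary.loc[f"is_{g}"]
            rows[g] = {"hr": s["exp(coef)"], "ci_low": s["exp(coef) lower 95%"],
                       "ci_high": s["exp(coef) upper 95%"], "p": s["p"]}
    except Exception as err:  # zero-event group, separation, ...
        flags.append(f"joint Cox model failed: {err}")
        for g in non_low:
            rows[g] = {"hr": np.nan, "ci_low": 0.0, "ci_high": np.inf, "p": np.nan}
    return SurvivalSummary(km, pd.DataFrame(rows).T, tuple(flags))


def univariate_screen(clinical: ClinicalTable, groups: np.ndarray) -> pd.DataFrame:
    """Per-covariate association with a 2-level grouping.

    Categorical covariates: Fisher's exact test on the 2x2 table (chi-square
    with a flag when the covariate has more than two levels).  Continuous
    covariates: two-sided Wilcoxon rank-sum, exact when the combined n is at
    most 50 and there are no ties, normal approximation with tie correction
    otherwise.  Constant covariates are flagged with an undefined p.
    """
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("univariate screen expects exactly two groups")
    rows = []
    for name, kind in clinical.covariate_types.items():
        col = clinical.data[name]
        note = ""
        if col.nunique(dropna=True) <= 1:
            rows.append({"covariate": name, "type": kind, "p": np.nan,
                         "test": "none", "note": "constant covariate"})
            continue
        if kind == "categorical":
            table = pd.crosstab(col, pd.Series(groups, index=clinical.data.index))
            if table.shape[0] == 2:
                p = float(stats.fisher_exact(table.to_numpy())[1])
                test = "fisher"
            else:
                p = float(stats.chi2_contingency(table.to_numpy())[1])
                test, note = "chi2", "k>2 levels: chi-square approximation"
        else:
            a = col[groups == levels[0]].dropna().to_numpy(dtype=float)
            b = col[groups == levels[1]].dropna().to_numpy(dtype=float)
            values = np.concatenate([a, b])
            exact = values.size <= 50 and np.unique(values).size == values.size
            method = "exact" if exact else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method=method, use_continuity=False)[1])
            test = f"wilcoxon-{method}"
        rows.append({"covariate": name, "type": kind, "p": p, "test": test, "note": note})
    return pd.DataFrame(rows).set_index("covariate")


@dataclass(frozen=True)
class MultivariateModel:
    summary: pd.DataFrame | None   # lifelines-style per-covariate summary
    aic: float
    trace: tuple                   # (dropped covariate, AIC after drop) per step
    screened_in: tuple
    flags: tuple = field(default=())

    @property
    def retained(self) -> tuple:
        return tuple(self.summary.index) if self.summary is not None else ()


def _design(clinical: ClinicalTable, covariates) -> pd.DataFrame:
    parts = []
    for name in covariates:
        col = clinical.data[name]
        if clinical.covariate_types[name] == "categorical":
            dummies = pd.get_dummies(col, prefix=name, drop_first=True).astype(float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def multivariate_cox_backward_aic(clinical: ClinicalTable, outcome: SurvivalOutcome,
                                  screen_alpha: float = 0.05,
                                  candidates=None) -> MultivariateModel:
    """Backward-AIC Cox model over covariates passing a univariate screen.

    Each covariate is first screened by its own single-covariate Cox p-value
    (``candidates`` overrides the screen with an explicit list, e.g. one
    produced by :func:`univariate_screen`).  Starting from the full model,
    the covariate whose removal lowers AIC most is dropped, one per step,
    until no removal lowers AIC; ties break on covariate name.  With no
    screened-in covariate an empty model is returned with a flag.
    """
    if not np.array_equal(clinical.sample_ids, outcome.sample_ids):
        raise ValueError("clinical table and outcome must be aligned")
    base = pd.DataFrame({"T": outcome.time, "E": outcome.event},
                        index=clinical.data.index)

    def _fit(covs):
        df = pd.concat([base, _design(clinical, covs)], axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter()
            cph.fit(df, "T", "E")
        return cph

    if candidates is None:
        candidates = []
        for name in clinical.covariate_types:
            try:
                if _fit([name]).summary["p"].min() < screen_alpha:
                    candidates.append(name)
            except Exception:
                pass  # degenerate covariate: screened out
    candidates = sorted(candidates)
    if not candidates:
        return MultivariateModel(None, np.nan, (), (), ("no covariate passed screen",))

    current = list(candidates)
    model = _fit(current)
    aic = model.AIC_partial_
    trace = []
    while len(current) > 1:
        options = []
        for name in sorted(current):
            rest = [c for c in current if c != name]
            try:
                options.append((name, _fit(rest).AIC_partial_))
            except Exception:
                continue
        if not options:
            break
        drop, best_aic = min(options, key=lambda t: (t[1], t[0]))
        if best_aic >= aic:
            break
        current = [c for c in current if c != drop]
        aic = best_aic
        trace.append((drop, float(best_aic)))
        model = _fit(current)
    cols = ["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    summary = model.summary[cols].rename(columns={
        "exp(coef)": "hr", "exp(coef) lower 95%": "ci_low",
        "exp(coef) upper 95%": "ci_high"})
    return MultivariateModel(summary, float(aic), tuple(trace), tuple(candidates))
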