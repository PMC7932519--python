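"""Group composition from symptom change scores, plus multiverse variants.

The cohort is screened on childhood-experience (JTV) sums (strictly below
the cohort median), the SCL-90 change score T1 - T0 is split into tertiles
(Decrease / Stable / Increase), and the Decrease tertile is excluded by
default because its inflated baseline severity would confound network
comparisons.  A multiverse grid re-runs the split over alternative cutoff
specifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STABLE, INCREASE, DECREASE = "Stable", "Increase", "Decrease"
EXCLUDED_JTV, EXCLUDED_MISSING = "ExcludedHighJTV", "ExcludedMissing"
CHANGE_GROUPS = (DECREASE, STABLE, INCREASE)


@dataclass
class CutoffSpec:
    """One grouping rule: cutpoints either as quantiles of the observed
    change-score distribution (``kind='quantile'``, in percent) or as raw
    change-score values (``kind='value'``)."""

    lower: float
    upper: float
    kind: str = "quantile"

    def __post_init__(self):
        if self.kind not in ("quantile", "value"):
            raise ValueError("kind must be 'quantile' or 'value'")
        if self.lower > self.upper:
            raise ValueError("lower cutoff must not exceed upper cutoff")

    def resolve(self, changes: pd.Series):
        vals = np.asarray(changes.dropna(), dtype=float)
        if self.kind == "quantile":
            lo, hi = np.quantile(vals, [self.lower / 100.0, self.upper / 100.0],
                                 method="linear")
        else:
            lo, hi = float(self.lower), float(self.upper)
        return lo, hi


#: default multiverse grid of quantile pairs (percent)
DEFAULT_MULTIVERSE = (
    CutoffSpec(25.0, 75.0),
    CutoffSpec(30.0, 70.0),
    CutoffSpec(100.0 / 3.0, 200.0 / 3.0),
    CutoffSpec(40.0, 60.0),
)


@dataclass
class GroupAssignment:
    """Mapping person -> label plus the cutoffs and provenance that
    produced it.  ``labels`` partitions the cohort; ``analysis_groups``
    lists the labels carried into estimation."""

    labels: pd.Series
    lower: float
    upper: float
    provenance: str = "tertile"
    analysis_groups: tuple = (STABLE, INCREASE)
    baseline_report: pd.DataFrame | None = None
    flags: list = field(default_factory=list)

    def persons(self, label: str):
        return list(self.labels.index[self.labels == label])

    def analysis_labels(self) -> pd.Series:
        return self.labels[self.labels.isin(self.analysis_groups)]

    def sizes(self) -> dict:
        return self.labels.value_counts().to_dict()


# ---------------------------------------------------------------------------
# Elementary scores and splits
# ---------------------------------------------------------------------------

def change_score(meta: pd.DataFrame) -> pd.Series:
    """SCL-90 change T1 - T0 per person (index: person_id); persons with a
    missing score get NaN and are excluded downstream."""
    meta = meta.set_index("person_id") if "person_id" in meta.columns else meta
    t0 = pd.to_numeric(meta["scl_t0"], errors="coerce")
    t1 = pd.to_numeric(meta["scl_t1"], errors="coerce")
    for name, s in (("scl_t0", t0), ("scl_t1", t1)):
        bad = s.dropna()[(s.dropna() < 90) | (s.dropna() > 450)]
        if len(bad):
            raise ValueError(f"{name} outside the 90-450 scale for {list(bad.index[:3])}")
    return (t1 - t0).rename("change")


def median_split_jtv(meta: pd.DataFrame, strict: bool = True):
    """Retain persons scoring below the cohort median JTV sum.

    With ``strict`` (default), at-median scores are excluded along with
    above-median ones.  Returns (included ids, excluded ids, median).
    """
    meta = meta.set_index("person_id") if "person_id" in meta.columns else meta
    jtv = pd.to_numeric(meta["jtv_sum"], errors="coerce").dropna()
    if len(jtv) < 2:
        raise ValueError("need at least two persons for a median split")
    med = float(jtv.median())
    below = jtv < med if strict else jtv <= med
    included = list(jtv.index[below])
    if not included:
        raise ValueError(
            "median split retained nobody (all JTV sums equal the median); "
            "check the score distribution or use strict=False"
        )
    excluded = [p for p in meta.index if p not in set(included)]
    return included, excluded, med


def tertile_split(changes: pd.Series, person_ids=None) -> GroupAssignment:
    """Split change scores into near-equal thirds: lowest third Decrease,
    middle Stable, highest Increase.

    Persons are ranked by a stable sort on (change, person_id), so group
    sizes differ by at most one even in the presence of tied scores; the
    reported cutoffs are the type-7 empirical 1/3 and 2/3 quantiles.
    """
    changes = pd.Series(changes)
    if person_ids is not None:
        changes.index = person_ids
    changes = changes.dropna()
    n = len(changes)
    if n < 3:
        raise ValueError("need at least three persons for a tertile split")
    order = changes.reset_index()
    order.columns = ["person_id", "change"]
    order = order.sort_values(["change", "person_id"], kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = pd.Series(index=changes.index, dtype=object)
    bounds = np.cumsum([0] + sizes)
    for (lo_i, hi_i), g in zip(zip(bounds[:-1], bounds[1:]), CHANGE_GROUPS):
        labels[order["person_id"].iloc[lo_i:hi_i]] = g
    lo, hi = np.quantile(changes.to_numpy(dtype=float),
                         [1.0 / 3.0, 2.0 / 3.0], method="linear")
    return GroupAssignment(labels=labels, lower=float(lo), upper=float(hi),
                           provenance="tertile")


def split_by_cutoffs(changes: pd.Series, spec: CutoffSpec,
                     provenance: str = "custom") -> GroupAssignment:
    lo, hi = spec.resolve(changes)
    vals = changes.dropna()
    labels = pd.Series(INCREASE, index=vals.index, dtype=object)
    labels[vals <= hi] = STABLE
    labels[vals <= lo] = DECREASE
    flags = []
    if spec.kind == "value" and (lo < vals.min() or hi > vals.max()):
        flags.append("cutpoints outside the observed change-score range")
    for g in CHANGE_GROUPS:
        if (labels == g).sum() == 0:
            flags.append(f"empty group: {g}")
    return GroupAssignment(labels=labels, lower=lo, upper=hi,
                           provenance=provenance, flags=flags)


# ---------------------------------------------------------------------------
# Full group-composition pipeline
# ---------------------------------------------------------------------------

def _baseline_report(meta: pd.DataFrame, labels: pd.Series, alpha=0.05) -> pd.DataFrame:
    """Pairwise Welch tests of baseline SCL-90 between change groups."""
    meta = meta.set_index("person_id") if "person_id" in meta.columns else meta
    t0 = pd.to_numeric(meta["scl_t0"], errors="coerce")
    rows = []
    present = [g for g in CHANGE_GROUPS if (labels == g).sum() >= 2]
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            xa = t0[labels.index[labels == a]].dropna()
            xb = t0[labels.index[labels == b]].dropna()
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({
                "group_a": a, "group_b": b,
                "mean_a": xa.mean(), "mean_b": xb.mean(),
                "difference": xb.mean() - xa.mean(),
                "t": t, "p": p, "flagged": p < alpha,
            })
    return pd.DataFrame(rows)


def assign_groups(
    meta: pd.DataFrame,
    drop_decrease: bool = True,
    jtv_screen: bool = True,
    spec: CutoffSpec | None = None,
    on_empty: str = "raise",
) -> GroupAssignment:
    """Compose analysis groups: JTV median screen, change-score split,
    optional exclusion of the Decrease tertile, and a baseline-severity
    comparability report.

    Persons lacking an SCL-90 score are labelled ``ExcludedMissing``;
    persons at or above the median JTV sum are ``ExcludedHighJTV``.
    """
    meta = meta.copy()
    if "person_id" not in meta.columns:
        meta = meta.reset_index()
    meta = meta.set_index("person_id")
    labels = pd.Series(index=meta.index, dtype=object)

    missing = meta.index[meta[["scl_t0", "scl_t1"]].isna().any(axis=1)]
    labels[missing] = EXCLUDED_MISSING

    eligible = meta.drop(index=missing)
    if jtv_screen:
        included, excluded, _med = median_split_jtv(eligible.reset_index())
        labels[[p for p in excluded if p not in missing]] = EXCLUDED_JTV
        eligible = eligible.loc[included]

    changes = change_score(eligible.reset_index())
    if spec is None:
        assignment = tertile_split(changes)
    else:
        assignment = split_by_cutoffs(changes, spec)
    labels[assignment.labels.index] = assignment.labels

    analysis = (STABLE, INCREASE) if drop_decrease else CHANGE_GROUPS
    retained = [g for g in analysis if (labels == g).sum() > 0]
    if len(retained) < 2:
        if on_empty == "raise":
            raise ValueError("fewer than two retained groups; cannot compare networks")
        assignment.flags.append("fewer than two retained groups")

    report = _baseline_report(meta.reset_index(), labels)
    return GroupAssignment(
        labels=labels,
        lower=assignment.lower,
        upper=assignment.upper,
        provenance=assignment.provenance,
        analysis_groups=tuple(analysis),
        baseline_report=report,
        flags=assignment.flags,
    )


def multiverse_grid(
    meta: pd.DataFrame,
    specs=DEFAULT_MULTIVERSE,
    drop_decrease: bool = True,
    jtv_screen: bool = True,
) -> list:
    """One GroupAssignment per cutoff specification, for mapping the
    downstream pipeline over alternative grouping rules."""
    return [
        assign_groups(meta, drop_decrease=drop_decrease,
                      jtv_screen=jtv_screen, spec=s, on_empty="flag")
        for s in specs
    ]
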