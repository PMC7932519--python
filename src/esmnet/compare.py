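"""Group comparison of network metrics with permutation significance.

The observed metric difference between two groups is referenced against a
null distribution obtained by randomly reassigning group labels across
permutation units — whole families by default, so that twins always move
together — preserving the observed group sizes, and re-estimating both
networks per replicate.  Because full multilevel refits inside thousands
of permutations are computationally prohibitive, the default estimator
inside permutations is the two-stage ("fast") tier: per-person lagged
regressions, fitted once, averaged within each permuted group.  The full
multilevel tier is supported at a reduced permutation budget.

P-values use the add-one rule p = (1 + #{|perm| >= |obs|}) / (1 + n_perm),
which is exact under exchangeability and never returns zero.  No
multiple-testing correction is applied across metrics; each metric's
permutation result is reported on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import metrics as _m
from .simulate import NODES, POSITIVE_NODES, NEGATIVE_NODES
from .estimate import (
    AffectNetwork, EstimationError,
    estimate_group_network, person_coefficient_matrices,
    significant_subnetwork,
)

#: metric name -> callable on a 6x6 weight matrix (canonical node order)
DEFAULT_METRICS = {
    "negative_connectivity": lambda W: _m.negative_connectivity(W),
    "out_strength_cheerful": lambda W: _m.out_strength(W, "cheerful"),
    "out_strength_relaxed": lambda W: _m.out_strength(W, "relaxed"),
    "out_strength_energetic": lambda W: _m.out_strength(W, "energetic"),
    "pa_to_na": lambda W: _m.pa_to_na(W),
    "na_to_pa": lambda W: _m.na_to_pa(W),
}


def _resolve_metric(metric):
    if callable(metric):
        return getattr(metric, "__name__", "metric"), metric
    if metric in DEFAULT_METRICS:
        return metric, DEFAULT_METRICS[metric]
    raise KeyError(f"unknown metric {metric!r}; known: {sorted(DEFAULT_METRICS)}")


@dataclass
class MetricDifference:
    metric: str
    value_a: float
    value_b: float
    difference: float          # B - A
    ratio: float               # B / A (NaN when A == 0)
    ratio_defined: bool


def metric_difference(network_a, network_b, metric) -> MetricDifference:
    """Evaluate one metric on two networks; returns B - A and B / A."""
    name, fn = _resolve_metric(metric)
    Wa, nodes_a = _m._as_matrix(network_a)
    Wb, nodes_b = _m._as_matrix(network_b)
    if tuple(nodes_a) != tuple(nodes_b):
        raise ValueError("networks have mismatched node sets")
    va, vb = float(fn(Wa)), float(fn(Wb))
    defined = va != 0.0
    return MetricDifference(
        metric=name, value_a=va, value_b=vb,
        difference=vb - va,
        ratio=vb / va if defined else float("nan"),
        ratio_defined=defined,
    )


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    metric: str
    groups: tuple
    observed: dict
    observed_difference: float
    perm_differences: np.ndarray
    pvalue: float
    n_perm: int
    unit: str
    tier: str
    seed: int | None

    def summary(self) -> dict:
        return {
            "metric": self.metric,
            "group_a": self.groups[0], "group_b": self.groups[1],
            "value_a": self.observed[self.groups[0]],
            "value_b": self.observed[self.groups[1]],
            "difference": self.observed_difference,
            "p": self.pvalue, "n_perm": self.n_perm,
            "unit": self.unit, "tier": self.tier, "seed": self.seed,
        }


def _person_units(design, labels, unit):
    """Person table with unit ids; checks units are group-homogeneous."""
    labels = pd.Series(labels).dropna()
    persons = design[["person_id", "family_id"]].drop_duplicates()
    persons = persons[persons["person_id"].isin(labels.index)]
    persons["group"] = persons["person_id"].map(labels)
    if unit == "person":
        persons["unit"] = persons["person_id"]
    elif unit == "family":
        persons["unit"] = persons["family_id"]
        mixed = persons.groupby("unit")["group"].nunique()
        if (mixed > 1).any():
            bad = list(mixed.index[mixed > 1][:3])
            raise ValueError(
                f"families {bad} contain persons from different groups; "
                "family-level permutation needs group-homogeneous families "
                "(use unit='person')"
            )
    else:
        raise ValueError("unit must be 'person' or 'family'")
    return persons


def permutation_test(
    design: pd.DataFrame,
    labels,
    metric="negative_connectivity",
    n_perm: int = 10000,
    unit: str = "family",
    tier: str = "fast",
    seed: int | None = None,
    group_order=None,
    full_budget: int = 200,
    min_rows: int = 12,
    spec=None,
) -> PermutationResult:
    """Permutation test of a metric difference between two groups.

    ``labels`` maps person_id -> group label (exactly two labels).  Group
    labels are shuffled across permutation units (persons or whole
    families), preserving group sizes; both networks are re-estimated in
    every replicate with the configured tier and the metric difference
    (B - A) recorded.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if tier == "full" and n_perm > full_budget:
        raise ValueError(
            f"tier='full' with n_perm={n_perm} exceeds the configured budget "
            f"({full_budget}); lower n_perm, raise full_budget, or use tier='fast'"
        )
    name, fn = _resolve_metric(metric)
    persons = _person_units(design, labels, unit)
    groups = group_order or sorted(persons["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    ga, gb = groups

    units = persons.groupby("unit")["group"].first()
    if (units == ga).sum() < 2 or (units == gb).sum() < 2:
        raise ValueError("each group needs at least two permutation units")

    rng = np.random.default_rng(seed)
    design = design[design["person_id"].isin(set(persons["person_id"]))]

    if tier == "fast":
        coefs = person_coefficient_matrices(design, min_rows=min_rows)
        usable = persons[persons["person_id"].isin(coefs)]
        mats = np.stack([coefs[p][:, 1:7] for p in usable["person_id"]])
        unit_ids = units.index.to_numpy()
        unit_groups = units.to_numpy()
        person_unit_idx = usable["unit"].map(
            dict(zip(unit_ids, range(len(unit_ids))))).to_numpy()

        def group_means(perm_groups):
            sel_a = np.isin(person_unit_idx, np.flatnonzero(perm_groups == ga))
            sel_b = np.isin(person_unit_idx, np.flatnonzero(perm_groups == gb))
            if sel_a.sum() < 2 or sel_b.sum() < 2:
                raise EstimationError("a permuted group has fewer than two usable persons")
            return mats[sel_a].mean(axis=0), mats[sel_b].mean(axis=0)

        Wa, Wb = group_means(unit_groups)
        observed = {ga: float(fn(Wa)), gb: float(fn(Wb))}
        obs_diff = observed[gb] - observed[ga]
        perm = np.empty(n_perm)
        for i in range(n_perm):
            shuffled = rng.permutation(unit_groups)
            Pa, Pb = group_means(shuffled)
            perm[i] = fn(Pb) - fn(Pa)
    elif tier == "full":
        def full_net(person_set, label):
            return estimate_group_network(
                design, group_label=label, persons=person_set,
                spec=spec, tier="full").weights

        by_group = persons.groupby("group")["person_id"].apply(list)
        Wa = full_net(by_group[ga], ga)
        Wb = full_net(by_group[gb], gb)
        observed = {ga: float(fn(Wa)), gb: float(fn(Wb))}
        obs_diff = observed[gb] - observed[ga]
        unit_groups = units.to_numpy()
        unit_persons = persons.groupby("unit")["person_id"].apply(list)
        perm = np.empty(n_perm)
        for i in range(n_perm):
            shuffled = rng.permutation(unit_groups)
            pa = [p for u in units.index[shuffled == ga] for p in unit_persons[u]]
            pb = [p for u in units.index[shuffled == gb] for p in unit_persons[u]]
            perm[i] = fn(full_net(pb, gb)) - fn(full_net(pa, ga))
    else:
        raise ValueError("tier must be 'fast' or 'full'")

    p = (1.0 + np.sum(np.abs(perm) >= abs(obs_diff))) / (1.0 + n_perm)
    return PermutationResult(
        metric=name, groups=(ga, gb), observed=observed,
        observed_difference=float(obs_diff),
        perm_differences=perm, pvalue=float(p), n_perm=n_perm,
        unit=unit, tier=tier, seed=seed,
    )


# ---------------------------------------------------------------------------
# Full comparison report
# ---------------------------------------------------------------------------

def _descriptives(network: AffectNetwork, alpha: float) -> dict:
    filtered = significant_subnetwork(network, alpha=alpha)
    edges = filtered.edge_list(alpha=alpha)
    sig = edges[edges["significant"]]
    return {
        "significant_edges": sig.to_dict(orient="records"),
        "negative_cycles": _m.find_reinforcing_cycles(
            filtered, node_subset=NEGATIVE_NODES),
        "positive_cycles": _m.find_reinforcing_cycles(
            filtered, node_subset=POSITIVE_NODES),
    }


def compare_all(
    design: pd.DataFrame,
    assignment,
    metrics=None,
    n_perm: int = 10000,
    unit: str = "family",
    tier: str = "fast",
    alpha: float = 0.05,
    seed: int | None = None,
    spec=None,
) -> dict:
    """Descriptive and permutation-based comparison of two group networks.

    Runs :func:`metric_difference` and :func:`permutation_test` for each
    requested metric (default: negative connectivity, out-strength of each
    positive node, and both cross-valence sums), plus significant-edge
    lists and reinforcing-cycle inventories per group.
    """
    labels = assignment.analysis_labels() if hasattr(assignment, "analysis_labels") \
        else pd.Series(assignment)
    present = [g for g in pd.unique(labels) if (labels == g).sum() > 0]
    if len(present) != 2:
        raise ValueError(f"need exactly two analysis groups, got {present}")
    ga, gb = present
    metrics = list(metrics or DEFAULT_METRICS)

    nets = {
        g: estimate_group_network(
            design, group_label=g, persons=labels.index[labels == g],
            spec=spec, tier=tier)
        for g in (ga, gb)
    }
    report = {
        "groups": [ga, gb],
        "settings": {"n_perm": n_perm, "unit": unit, "tier": tier,
                     "alpha": alpha, "seed": seed,
                     "multiple_testing_correction": "none"},
        "metrics": {},
        "descriptives": {g: _descriptives(nets[g], alpha) for g in (ga, gb)},
    }
    for m in metrics:
        diff = metric_difference(nets[ga], nets[gb], m)
        perm = permutation_test(
            design, labels, metric=m, n_perm=n_perm, unit=unit,
            tier=tier, seed=seed, group_order=(ga, gb), spec=spec,
        )
        entry = asdict(diff)
        entry.update({k: v for k, v in perm.summary().items()
                      if k not in ("metric",)})
        report["metrics"][diff.metric] = entry
    return report


def report_to_json(report: dict) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(type(o).__name__)
    return json.dumps(report, indent=2, default=default)


# ---------------------------------------------------------------------------
# Multiverse stability
# ---------------------------------------------------------------------------

@dataclass
class MultiverseReport:
    """Qualitative-feature stability across grouping specifications."""

    stability: pd.DataFrame
    assignments: pd.DataFrame
    features_by_assignment: list = field(default_factory=list)


def _qualitative_features(design, labels, groups, tier, alpha, spec):
    feats = set()
    for g in groups:
        net = estimate_group_network(
            design, group_label=g, persons=labels.index[labels == g],
            spec=spec, tier=tier)
        filtered = significant_subnetwork(net, alpha=alpha)
        edges = filtered.edge_list(alpha=alpha)
        for _, e in edges[edges["significant"]].iterrows():
            sign = "+" if e["b"] > 0 else "-"
            feats.add(f"edge {e['from']}->{e['to']} ({sign}) in {g}")
        for subset, tag in ((NEGATIVE_NODES, "negative"), (POSITIVE_NODES, "positive")):
            for cyc in _m.find_reinforcing_cycles(filtered, node_subset=subset):
                feats.add(f"{tag} cycle {'->'.join(cyc['nodes'])} in {g}")
    return feats


def multiverse_report(
    design: pd.DataFrame,
    assignments,
    tier: str = "fast",
    alpha: float = 0.05,
    spec=None,
) -> MultiverseReport:
    """Stability of qualitative network features across grouping rules.

    For every assignment, the significance-filtered networks of its
    analysis groups are computed and their qualitative features
    (significant edges with sign; reinforcing cycles) recorded; stability
    is the fraction of valid assignments exhibiting each feature.
    Assignments with an empty analysis group are flagged and excluded from
    the fractions.
    """
    if len(assignments) < 2:
        raise ValueError("need at least two assignments for a multiverse report")
    rows, all_feats = [], []
    for i, a in enumerate(assignments):
        labels = a.analysis_labels()
        sizes = {g: int((labels == g).sum()) for g in a.analysis_groups}
        designed = set(design["person_id"])
        usable = {g: len([p for p in labels.index[labels == g] if p in designed])
                  for g in a.analysis_groups}
        valid = all(v >= 2 for v in usable.values())
        rows.append({
            "assignment": i,
            "lower": a.lower, "upper": a.upper,
            "provenance": a.provenance,
            **{f"n_{g}": sizes[g] for g in a.analysis_groups},
            "valid": valid,
            "flags": "; ".join(a.flags),
        })
        if valid:
            feats = _qualitative_features(
                design, labels, a.analysis_groups, tier, alpha, spec)
        else:
            feats = None
        all_feats.append(feats)

    valid_feats = [f for f in all_feats if f is not None]
    universe = sorted(set().union(*valid_feats)) if valid_feats else []
    stab = pd.DataFrame({
        "feature": universe,
        "count": [sum(f in feats for feats in valid_feats) for f in universe],
    })
    stab["n_assignments"] = len(valid_feats)
    stab["fraction"] = stab["count"] / max(len(valid_feats), 1)
    return MultiverseReport(
        stability=stab,
        assignments=pd.DataFrame(rows),
        features_by_assignment=all_feats,
    )
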