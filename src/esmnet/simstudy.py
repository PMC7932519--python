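"""Built-in simulation studies validating the pipeline end to end.

Each function generates its own synthetic cohorts with known ground truth,
runs the relevant pipeline stages, and returns the measured operating
characteristics: exact agreement of the network metrics with brute-force
enumeration, parameter recovery of the multilevel estimator, type-I-error
calibration of the permutation test, qualitative structure recovery of the
significance-filtered networks, and the behaviour of the group-composition
rules under the emulated symptom-change distributions.

All studies are deterministic given their seed.  Problem sizes default to
the emulated study design (80 persons in 40 twin families per group, 6
days x 10 beeps, 25% beep-level missingness); the lighter checks use
smaller cohorts.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics as _m
from .simulate import (
    NODES, NEGATIVE_NODES, POSITIVE_NODES,
    stable_config, increase_config, simulate_cohort,
)
from .preprocess import filter_by_missingness, make_lag_design
from .groups import assign_groups, tertile_split, change_score
from .estimate import (
    estimate_group_network, significant_subnetwork, ModelSpec,
)
from .compare import permutation_test
import statsmodels.api as sm


def _child_seed(seed, *path):
    """Derive a reproducible 31-bit child seed."""
    ss = np.random.SeedSequence([int(seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _cohort_design(config, seed, scheduled=None):
    panel, meta, truth = simulate_cohort([config], seed=seed)
    scheduled = scheduled or config.n_days * config.beeps_per_day
    kept, _ = filter_by_missingness(panel, scheduled_beeps=scheduled)
    design, _ = make_lag_design(kept)
    return design, meta, truth


# ---------------------------------------------------------------------------
# 1. Metric oracles: exact agreement with brute-force enumeration
# ---------------------------------------------------------------------------

def _brute_force_metrics(W):
    """Independent O(n^2) / exhaustive-search metric implementations."""
    neg = [NODES.index(n) for n in NEGATIVE_NODES]
    pos = [NODES.index(n) for n in POSITIVE_NODES]
    nc = sum(abs(W[j, k]) for j in neg for k in neg if j != k)
    outs = {}
    for node in NODES:
        k = NODES.index(node)
        outs[node] = sum(abs(W[j, k]) for j in range(6) if j != k)
    p2n = sum(abs(W[j, k]) for j in neg for k in pos)
    n2p = sum(abs(W[j, k]) for j in pos for k in neg)
    cycles = set()
    for L in (2, 3):
        for combo in itertools.permutations(neg, L):
            ws = [W[combo[(i + 1) % L], combo[i]] for i in range(L)]
            if all(w > 0 for w in ws):
                names = [NODES[i] for i in combo]
                rot = names.index(min(names))
                cycles.add(tuple(names[rot:] + names[:rot]))
    return nc, outs, p2n, n2p, cycles


def metric_oracle_check(n_networks: int = 1000, seed: int = 0) -> dict:
    """Compare the metric implementations against brute force on random
    6-node networks (dense weights, random sparsity and signs)."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_networks):
        W = rng.normal(0.0, 0.2, size=(6, 6))
        W[rng.random((6, 6)) < rng.uniform(0.2, 0.8)] = 0.0
        nc, outs, p2n, n2p, cycles = _brute_force_metrics(W)
        ok = (
            np.isclose(_m.negative_connectivity(W), nc, rtol=0, atol=1e-12)
            and all(np.isclose(_m.out_strength(W, n), outs[n], atol=1e-12)
                    for n in NODES)
            and np.isclose(_m.pa_to_na(W), p2n, atol=1e-12)
            and np.isclose(_m.na_to_pa(W), n2p, atol=1e-12)
            and {c["nodes"] for c in _m.find_reinforcing_cycles(W)} == cycles
        )
        mismatches += not ok
    return {"n_networks": n_networks, "mismatches": mismatches}


# ---------------------------------------------------------------------------
# 2. Parameter recovery of the multilevel estimator
# ---------------------------------------------------------------------------

def recovery_study(
    n_cohorts: int = 20,
    n_families: int = 40,
    missing_rate: float = 0.25,
    seed: int = 0,
    tier: str = "full",
) -> dict:
    """Estimate the bias and RMSE of every transition-matrix entry over
    repeated cohorts with known dynamics.

    Cohorts use the default Stable dynamics with the generator's
    continuous observation mode, which isolates the estimator's own
    sampling behaviour from Likert coarsening.
    """
    config = stable_config(n_families=n_families, missing_rate=missing_rate,
                           observe="continuous")
    B = config.transition_matrix
    ests = []
    for i in range(n_cohorts):
        design, _, _ = _cohort_design(config, _child_seed(seed, 2, i))
        net = estimate_group_network(design, group_label="Stable", tier=tier)
        ests.append(net.weights)
    ests = np.asarray(ests)
    bias = ests.mean(axis=0) - B
    rmse = np.sqrt(((ests - B) ** 2).mean(axis=0))
    return {
        "n_cohorts": n_cohorts,
        "truth": B,
        "bias": bias,
        "rmse": rmse,
        "max_abs_bias": float(np.abs(bias).max()),
        "max_abs_bias_offdiag": float(
            np.abs(bias - np.diag(np.diag(bias))).max()),
        "max_abs_bias_diag": float(np.abs(np.diag(bias)).max()),
        "max_rmse": float(rmse.max()),
    }


def degenerate_limit_check(seed: int = 0, n_families: int = 60) -> dict:
    """With all random-effect SDs and phi at zero in the generator, the
    multilevel fit's fixed effects must match pooled OLS."""
    config = stable_config(
        n_families=n_families, observe="continuous", missing_rate=0.0,
        person_sd=(0.0,) * 6, family_sd=(0.0,) * 6, slope_sd=0.0,
        resid_phi=0.0,
    )
    from .estimate import fit_lagged_model
    design, _, truth = _cohort_design(config, _child_seed(seed, 21))
    max_dev = 0.0
    for outcome in NODES:
        fit = fit_lagged_model(design, ModelSpec(outcome))
        X = np.column_stack([
            np.ones(len(design)),
            design[[f"lag_{n}" for n in NODES]].to_numpy(),
            design["time"].to_numpy() / 60.0,
        ])
        y = design[f"y_{outcome}"].to_numpy()
        ols = sm.OLS(y, X).fit()
        dev = np.abs(fit.coef[[f"lag_{n}" for n in NODES]].to_numpy()
                     - ols.params[1:7]).max()
        max_dev = max(max_dev, float(dev))
    return {"max_deviation_from_ols": max_dev, "n_rows": len(design)}


# ---------------------------------------------------------------------------
# 3. Permutation-test calibration under the null
# ---------------------------------------------------------------------------

def calibration_study(
    n_experiments: int = 200,
    n_perm: int = 199,
    n_families_per_group: int = 10,
    alpha: float = 0.05,
    metric: str = "negative_connectivity",
    seed: int = 0,
) -> dict:
    """Type-I-error rate of the permutation test when both groups are
    drawn from an identical generator.

    Returns the rejection rate at ``alpha`` together with the exact
    binomial 95% acceptance band around ``alpha``.
    """
    rejections = 0
    for i in range(n_experiments):
        cfgs = [
            stable_config(n_families=n_families_per_group, group_label="A",
                          meta_group="Stable"),
            stable_config(n_families=n_families_per_group, group_label="B",
                          meta_group="Stable"),
        ]
        s = _child_seed(seed, 3, i)
        panel, meta, _ = simulate_cohort(cfgs, seed=s)
        kept, _ = filter_by_missingness(panel, scheduled_beeps=60)
        design, _ = make_lag_design(kept)
        labels = meta.set_index("person_id")["true_group"]
        labels = labels[labels.index.isin(design["person_id"])]
        res = permutation_test(design, labels, metric=metric,
                               n_perm=n_perm, unit="family", tier="fast",
                               seed=s)
        rejections += res.pvalue <= alpha
    lo, hi = stats.binom.interval(0.95, n_experiments, alpha)
    return {
        "n_experiments": n_experiments,
        "n_perm": n_perm,
        "alpha": alpha,
        "rejections": int(rejections),
        "rejection_rate": rejections / n_experiments,
        "binomial_band": (lo / n_experiments, hi / n_experiments),
    }


def power_study(
    n_replicates: int = 20,
    n_families_per_group: int = 40,
    n_perm: int = 499,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate when the groups differ by a large injected
    negative-connectivity gap (Increase vs Stable default dynamics)."""
    rejections = 0
    for i in range(n_replicates):
        cfgs = [stable_config(n_families=n_families_per_group),
                increase_config(n_families=n_families_per_group)]
        s = _child_seed(seed, 4, i)
        panel, meta, _ = simulate_cohort(cfgs, seed=s)
        kept, _ = filter_by_missingness(panel, scheduled_beeps=60)
        design, _ = make_lag_design(kept)
        labels = meta.set_index("person_id")["true_group"]
        labels = labels[labels.index.isin(design["person_id"])]
        res = permutation_test(design, labels, metric="negative_connectivity",
                               n_perm=n_perm, unit="family", tier="fast",
                               seed=s)
        rejections += res.pvalue <= alpha
    return {
        "n_replicates": n_replicates,
        "rejection_rate": rejections / n_replicates,
    }


# ---------------------------------------------------------------------------
# 4. Qualitative structure recovery
# ---------------------------------------------------------------------------

def structure_recovery_study(
    n_replicates: int = 20,
    n_families_per_group: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
    tier: str = "full",
) -> dict:
    """Recovery of the qualitative network contrast: the reciprocal
    down <-> lonely reinforcing 2-cycle exists only in the Increase
    generator, and the Stable generator has no paths between negative
    nodes.

    Per replicate both groups are simulated with the full Likert pipeline,
    networks estimated and significance-filtered at ``alpha``, and two
    events recorded: the 2-cycle is present in the Increase network, and
    the Stable network has no significant negative-negative edges.
    """
    cycle_hits = clean_hits = joint_hits = 0
    neg_idx = [NODES.index(n) for n in NEGATIVE_NODES]
    for i in range(n_replicates):
        s = _child_seed(seed, 5, i)
        panel, meta, _ = simulate_cohort(
            [stable_config(n_families=n_families_per_group),
             increase_config(n_families=n_families_per_group)], seed=s)
        kept, _ = filter_by_missingness(panel, scheduled_beeps=60)
        design, _ = make_lag_design(kept)
        labels = meta.set_index("person_id")["true_group"]
        nets = {}
        for g in ("Stable", "Increase"):
            persons = labels.index[labels == g]
            net = estimate_group_network(design, group_label=g,
                                         persons=persons, tier=tier)
            nets[g] = significant_subnetwork(net, alpha=alpha)
        cycles = _m.find_reinforcing_cycles(nets["Increase"],
                                            node_subset=NEGATIVE_NODES)
        has_cycle = any(set(c["nodes"]) == {"down", "lonely"} for c in cycles)
        Ws = nets["Stable"].weights
        offdiag = [(j, k) for j in neg_idx for k in neg_idx if j != k]
        clean = all(Ws[j, k] == 0.0 for j, k in offdiag)
        cycle_hits += has_cycle
        clean_hits += clean
        joint_hits += has_cycle and clean
    return {
        "n_replicates": n_replicates,
        "increase_cycle_rate": cycle_hits / n_replicates,
        "stable_clean_rate": clean_hits / n_replicates,
        "joint_rate": joint_hits / n_replicates,
    }


# ---------------------------------------------------------------------------
# 5. Group composition under the emulated change-score distributions
# ---------------------------------------------------------------------------

def composition_study(seed: int = 0) -> dict:
    """Tertile split of a 239-person cohort with the emulated group-level
    change distributions, plus the baseline-comparability behaviour.

    The cohort mixes the three generating groups at the emulated sizes
    (80 Decrease, 81 Stable, 78 Increase); the Decrease generator has an
    inflated baseline, which the comparability report must flag, while
    Stable and Increase baselines must not differ significantly.
    """
    from .simulate import simulate_person_meta
    rng = np.random.default_rng(_child_seed(seed, 6))
    rows = []
    for g, n in (("Decrease", 80), ("Stable", 81), ("Increase", 78)):
        for i in range(n):
            rows.append(simulate_person_meta(
                g, rng=rng, person_id=f"{g[:3].lower()}{i:03d}",
                family_id=f"f{g[:3].lower()}{i:03d}"))
    meta = pd.DataFrame(rows)

    changes = change_score(meta)
    tert = tertile_split(changes)
    sizes = sorted(
        (tert.sizes().get(g, 0) for g in ("Decrease", "Stable", "Increase")),
        reverse=True)

    assignment = assign_groups(meta, drop_decrease=True, jtv_screen=False)
    rep = assignment.baseline_report
    si = rep[(rep.group_a == "Stable") & (rep.group_b == "Increase")].iloc[0]
    dec = rep[(rep.group_a == "Decrease") | (rep.group_b == "Decrease")]
    return {
        "n": len(meta),
        "tertile_sizes": sizes,
        "max_size_deviation": int(max(abs(a - b) for a, b in
                                      zip(sizes, [80, 80, 79]))),
        "stable_increase_p": float(si["p"]),
        "stable_increase_flagged": bool(si["flagged"]),
        "decrease_flagged": bool(dec["flagged"].all()),
        "labels": tert.labels,
        "true_groups": meta.set_index("person_id")["true_group"],
    }
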