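"""Preprocessing: inclusion filters, person-mean centering, lag design,
and item-level inclusion diagnostics.

A beep is *complete* when all six affect items are present; only complete
observations enter the analysis.  Lagged outcome/predictor pairs are formed
only for consecutive beeps within the same day, so no pair spans a night.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import NODES

ITEM_COLS = list(NODES)
CENTERED_COLS = [f"c_{n}" for n in NODES]
LAG_COLS = [f"lag_{n}" for n in NODES]
Y_COLS = [f"y_{n}" for n in NODES]


def complete_mask(panel: pd.DataFrame) -> pd.Series:
    """True where all six affect items are present."""
    return panel[ITEM_COLS].notna().all(axis=1)


# ---------------------------------------------------------------------------
# Participant-level missingness filter
# ---------------------------------------------------------------------------

def filter_by_missingness(
    panel: pd.DataFrame,
    scheduled_beeps: int,
    max_missing_fraction: float = 0.30,
):
    """Exclude persons with *more than* ``max_missing_fraction`` missing beeps.

    The denominator is the scheduled beep count (60 in the emulated design),
    and an observation counts as missing unless all six items are present.
    The boundary is strictly-more-than: with 60 scheduled beeps, 18 missing
    (30%) is kept, 19 is excluded.

    Returns the panel restricted to included persons plus a per-person
    exclusion report.
    """
    if scheduled_beeps <= 0:
        raise ValueError("scheduled_beeps must be positive")
    complete = complete_mask(panel)
    counts = complete.groupby(panel["person_id"]).sum()
    report = pd.DataFrame({
        "person_id": counts.index,
        "n_complete": counts.values.astype(int),
    })
    report["n_missing"] = scheduled_beeps - report["n_complete"]
    report["missing_fraction"] = report["n_missing"] / scheduled_beeps
    report["included"] = report["missing_fraction"] <= max_missing_fraction
    report["zero_observations"] = report["n_complete"] == 0
    kept = set(report.loc[report["included"], "person_id"])
    return panel[panel["person_id"].isin(kept)].copy(), report


# ---------------------------------------------------------------------------
# Person-mean centering
# ---------------------------------------------------------------------------

def person_mean_center(panel: pd.DataFrame):
    """Add person-mean-centered item columns (``c_<item>``).

    Means are taken over each person's *complete* observations (the analysis
    set), isolating within-person fluctuations.  Returns the augmented panel
    and the per-person means used.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    out = panel.copy()
    complete = complete_mask(out)
    means = (
        out.loc[complete]
        .groupby("person_id")[ITEM_COLS]
        .mean()
    )
    aligned = means.reindex(out["person_id"]).to_numpy()
    centered = out[ITEM_COLS].to_numpy(dtype=float) - aligned
    for i, c in enumerate(CENTERED_COLS):
        out[c] = centered[:, i]
    return out, means


# ---------------------------------------------------------------------------
# Lag design
# ---------------------------------------------------------------------------

def build_lag_pairs(centered_panel: pd.DataFrame) -> pd.DataFrame:
    """Pair each complete beep with the previous complete beep.

    A row is formed only when beeps t-1 and t are consecutive in
    ``beep_number``, fall on the same day, and are both complete — pairs
    never span a night.  Outcomes (``y_<item>``) are the raw ratings at t;
    predictors (``lag_<item>``) are the person-mean-centered ratings at
    t-1; the time covariate is the beep number at t.
    """
    missing = [c for c in CENTERED_COLS if c not in centered_panel.columns]
    if missing:
        raise ValueError("panel lacks centered columns; run person_mean_center first")
    df = centered_panel.sort_values(["person_id", "beep_number"], kind="stable")
    complete = complete_mask(df).to_numpy()

    same_person = df["person_id"].to_numpy()[1:] == df["person_id"].to_numpy()[:-1]
    consecutive = np.diff(df["beep_number"].to_numpy()) == 1
    same_day = np.diff(df["day"].to_numpy()) == 0
    both_complete = complete[1:] & complete[:-1]
    ok = same_person & consecutive & same_day & both_complete

    idx_t = np.flatnonzero(ok) + 1
    idx_lag = idx_t - 1
    rows = pd.DataFrame({
        "person_id": df["person_id"].to_numpy()[idx_t],
        "family_id": df["family_id"].to_numpy()[idx_t],
        "day": df["day"].to_numpy()[idx_t],
        "beep_number": df["beep_number"].to_numpy()[idx_t],
        "time_min": df["time_min"].to_numpy()[idx_t],
        "dt_min": df["time_min"].to_numpy()[idx_t] - df["time_min"].to_numpy()[idx_lag],
        "time": df["beep_number"].to_numpy()[idx_t],
    })
    raw = df[ITEM_COLS].to_numpy(dtype=float)
    cen = df[CENTERED_COLS].to_numpy(dtype=float)
    for i, node in enumerate(NODES):
        rows[f"y_{node}"] = raw[idx_t, i]
        rows[f"lag_{node}"] = cen[idx_lag, i]
    return rows.reset_index(drop=True)


def make_lag_design(panel: pd.DataFrame):
    """Convenience: center then build the lag design; returns (design, means)."""
    centered, means = person_mean_center(panel)
    return build_lag_pairs(centered), means


# ---------------------------------------------------------------------------
# Item-level inclusion diagnostics
# ---------------------------------------------------------------------------

@dataclass
class ItemDiagnostics:
    """Item-selection diagnostics mirroring the inclusion criteria:
    within-person SD near 1, pairwise within-person correlations below .5,
    no group mean differences, and group within-person-SD ratios within a
    tolerance (default 12%)."""

    within_person_sd: pd.Series
    correlations: pd.DataFrame
    mean_tests: pd.DataFrame
    sd_ratio: pd.Series
    flags: pd.DataFrame
    sd_band: tuple
    max_sd_ratio: float


def _pooled_within_sd(values: pd.DataFrame, persons: pd.Series) -> pd.Series:
    """Pooled within-person SD: sqrt of the (n_i - 1)-weighted mean of
    per-person variances."""
    grouped = values.groupby(persons)
    var = grouped.var(ddof=1)
    n = grouped.count()
    w = (n - 1).clip(lower=0)
    pooled = (var * w).sum() / w.sum()
    return np.sqrt(pooled)


def item_diagnostics(
    panel: pd.DataFrame,
    group_assignment,
    sd_band=(0.7, 1.4),
    max_sd_ratio: float = 1.12,
    alpha: float = 0.05,
) -> ItemDiagnostics:
    """Run the item-level inclusion diagnostics on complete observations.

    ``group_assignment`` maps person_id -> group label; at least two groups
    with at least two persons each are required.
    """
    group_assignment = pd.Series(dict(group_assignment))
    df = panel[complete_mask(panel)].copy()
    df["_group"] = df["person_id"].map(group_assignment)
    df = df.dropna(subset=["_group"])
    groups = sorted(df["_group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups for diagnostics")
    for g in groups:
        if df.loc[df["_group"] == g, "person_id"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than two persons")

    centered, _ = person_mean_center(df)
    within_sd = _pooled_within_sd(df[ITEM_COLS], df["person_id"])

    corr = pd.DataFrame(
        np.corrcoef(centered[CENTERED_COLS].to_numpy(dtype=float), rowvar=False),
        index=ITEM_COLS, columns=ITEM_COLS,
    )

    person_means = df.groupby("person_id")[ITEM_COLS].mean()
    person_groups = group_assignment.reindex(person_means.index)
    mean_rows = []
    for item in ITEM_COLS:
        samples = [person_means.loc[person_groups == g, item] for g in groups]
        if len(groups) == 2:
            stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
            diff = samples[1].mean() - samples[0].mean()
        else:
            stat, p = stats.f_oneway(*samples)
            diff = np.nan
        mean_rows.append({"item": item, "difference": diff, "stat": stat, "p": p})
    mean_tests = pd.DataFrame(mean_rows).set_index("item")

    per_group_sd = pd.DataFrame(
        {g: _pooled_within_sd(df.loc[df["_group"] == g, ITEM_COLS],
                              df.loc[df["_group"] == g, "person_id"])
         for g in groups}
    )
    sd_ratio = per_group_sd.max(axis=1) / per_group_sd.min(axis=1)

    offdiag = corr.where(~np.eye(len(ITEM_COLS), dtype=bool))
    flags = pd.DataFrame({
        "sd_in_band": (within_sd >= sd_band[0]) & (within_sd <= sd_band[1]),
        "uncorrelated": offdiag.abs().max(axis=1) < 0.5,
        "mean_comparable": mean_tests["p"] > alpha,
        "sd_ratio_ok": sd_ratio <= max_sd_ratio,
    })
    return ItemDiagnostics(
        within_person_sd=within_sd,
        correlations=corr,
        mean_tests=mean_tests,
        sd_ratio=sd_ratio,
        flags=flags,
        sd_band=tuple(sd_band),
        max_sd_ratio=max_sd_ratio,
    )


# ---------------------------------------------------------------------------
# Internal-consistency coefficient
# ---------------------------------------------------------------------------

def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / variance of sum).

    ``items`` is an (n respondents x k items) table with no missing values.
    """
    X = np.asarray(pd.DataFrame(items), dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two items")
    if X.shape[0] < 2:
        raise ValueError("need at least two respondents")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
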