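"""Synthetic experience-sampling (ESM) cohorts with known lagged dynamics.

Generates long-format beep-level panels that emulate a twin-cohort ESM
study design: persons nested in families, six days of ten semi-random
beeps between 07:30 and 22:30 (~90-minute mean gap), six momentary affect
items on a 1-7 Likert scale (three positive: cheerful, relaxed, energetic;
three negative: irritated, down, lonely), beep-level missingness, and
per-person symptom metadata (SCL-90 sums at baseline and one-year
follow-up, childhood-experience screening sums).

The latent affect process is a group-specific VAR(1) around person-specific
means with AR(1)-correlated innovations,

    x_t = mu_p + B_p (x_{t-1} - mu_p) + delta * t + e_t,
    e_t = phi e_{t-1} + u_t,

restarted from its stationary distribution at the first beep of each day
(overnight reset).  The ground-truth transition matrices B are returned so
that estimation stages have a parameter-recovery surface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

# ---------------------------------------------------------------------------
# Node and scale constants
# ---------------------------------------------------------------------------

NODES = ("cheerful", "relaxed", "energetic", "irritated", "down", "lonely")
POSITIVE_NODES = NODES[:3]
NEGATIVE_NODES = NODES[3:]
N_NODES = len(NODES)

LIKERT_MIN, LIKERT_MAX = 1, 7
SCL_MIN, SCL_MAX = 90, 450          # 90 items x Likert 1-5
JTV_MIN, JTV_MAX = 4, 20            # 4 items x Likert 1-5

PANEL_COLUMNS = [
    "person_id", "family_id", "day", "beep_in_day", "beep_number", "time_min",
    *NODES,
]

# ---------------------------------------------------------------------------
# Ground-truth dynamics per symptom-course group
# ---------------------------------------------------------------------------
# Orientation: B[j, k] is the effect of node k at t-1 on node j at t
# (row = outcome, column = lagged predictor).

def _stable_transition() -> np.ndarray:
    """Positive cluster only; negative nodes mutually unconnected."""
    B = np.zeros((6, 6))
    np.fill_diagonal(B, [0.22, 0.20, 0.18, 0.18, 0.20, 0.16])
    B[1, 0] = 0.12   # cheerful -> relaxed
    B[0, 1] = 0.12   # relaxed  -> cheerful
    B[2, 0] = 0.10   # cheerful -> energetic
    B[0, 2] = 0.08   # energetic -> cheerful
    B[2, 1] = 0.06   # relaxed  -> energetic
    B[1, 2] = 0.06   # energetic -> relaxed
    B[4, 0] = -0.10  # cheerful dampens down
    B[0, 4] = -0.06  # down dampens cheerful
    return B


def _increase_transition() -> np.ndarray:
    """Positive cluster plus an interconnected negative cluster with a
    reciprocal (mutually reinforcing) down <-> lonely pair."""
    B = np.zeros((6, 6))
    np.fill_diagonal(B, [0.20, 0.18, 0.18, 0.20, 0.22, 0.18])
    B[1, 0] = 0.10   # cheerful -> relaxed
    B[0, 1] = 0.10   # relaxed  -> cheerful
    B[2, 0] = 0.08   # cheerful -> energetic
    B[0, 2] = 0.08   # energetic -> cheerful
    B[3, 2] = -0.10  # energetic dampens irritated
    B[5, 4] = 0.15   # down -> lonely      (reinforcing 2-cycle)
    B[4, 5] = 0.15   # lonely -> down
    B[4, 3] = 0.06   # irritated -> down
    B[3, 5] = 0.05   # lonely -> irritated
    B[0, 4] = -0.08  # down dampens cheerful
    B[2, 5] = -0.06  # lonely dampens energetic
    return B


# Mean affect levels per group (Likert scale), matching the Stable /
# Increase cohort descriptives; the Decrease group reuses the Stable
# dynamics since no separate dynamics are characterised for it.
STABLE_MU = (4.76, 5.03, 4.63, 2.24, 1.79, 1.69)
INCREASE_MU = (4.53, 4.86, 4.34, 2.41, 1.91, 1.86)

# Per-person symptom metadata distributions per group:
# scl_t0 ~ N(t0_mean, t0_sd); change ~ N(change_mean, change_sd).
META_PARAMS = {
    "Stable": {"t0": (126.8, 26.1), "change": (-5.04, 4.95)},
    "Increase": {"t0": (130.24, 34.0), "change": (25.7, 22.5)},
    "Decrease": {"t0": (168.3, 35.0), "change": (-41.48, 33.09)},
}

#: population median of the 4-item childhood-experience sum; all simulated
#: persons score strictly below it (the cohort emulates the post-screening,
#: at-risk half of the population).
JTV_POPULATION_MEDIAN = 18


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Design and dynamics of one simulated group cohort.

    Defaults follow the emulated study: twin pairs, 6 days x 10 beeps in a
    07:30-22:30 window (minutes-of-day 450-1350) with ~90-minute mean gaps,
    within-person SDs near 1.0 per item, and up to ~30% beep-level
    missingness.
    """

    n_families: int = 40
    persons_per_family: int = 2
    n_days: int = 6
    beeps_per_day: int = 10
    day_start_min: float = 450.0
    day_end_min: float = 1350.0
    mean_gap_min: float = 90.0
    transition_matrix: np.ndarray = field(default_factory=_stable_transition)
    node_means: tuple = STABLE_MU
    innovation_sd: tuple = (0.95,) * 6
    person_sd: tuple = (0.6,) * 6
    family_sd: tuple = (0.3,) * 6
    slope_sd: float = 0.08
    resid_phi: float = 0.0
    trend_slope: float = 0.0
    missing_rate: float = 0.25
    group_label: str = "Stable"
    #: group whose symptom metadata distributions to use (defaults to
    #: group_label when that label is a known group)
    meta_group: str | None = None
    #: "likert" rounds/clips latent values to the 1-7 scale; "continuous"
    #: records the latent values directly
    observe: str = "likert"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (N_NODES, N_NODES):
            raise ConfigurationError("transition_matrix must be 6x6")
        if spectral_radius(self.transition_matrix) >= 1.0:
            raise ConfigurationError(
                "transition_matrix must have spectral radius < 1 "
                f"(got {spectral_radius(self.transition_matrix):.3f})"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.resid_phi < 1.0:
            raise ConfigurationError("resid_phi must be in [0, 1)")
        if self.day_start_min >= self.day_end_min:
            raise ConfigurationError("day_start_min must precede day_end_min")
        window = self.day_end_min - self.day_start_min
        if window < self.beeps_per_day:
            raise ConfigurationError(
                f"window of {window:.0f} min cannot hold {self.beeps_per_day} beeps"
            )
        if self.observe not in ("likert", "continuous"):
            raise ConfigurationError("observe must be 'likert' or 'continuous'")
        if self.meta_group is None:
            self.meta_group = (
                self.group_label if self.group_label in META_PARAMS else "Stable"
            )

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def stable_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


def increase_config(**overrides) -> SimulationConfig:
    base = dict(
        transition_matrix=_increase_transition(),
        node_means=INCREASE_MU,
        group_label="Increase",
    )
    base.update(overrides)
    return SimulationConfig(**base)


def decrease_config(**overrides) -> SimulationConfig:
    # Dynamics unknown for this (excluded) group: reuse the Stable dynamics;
    # only its symptom metadata (inflated baseline, large decrease) differ.
    base = dict(group_label="Decrease")
    base.update(overrides)
    return SimulationConfig(**base)


def spectral_radius(B: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(B, dtype=float)))))


# ---------------------------------------------------------------------------
# Beep schedule
# ---------------------------------------------------------------------------

def _schedule_times(n_days, beeps_per_day, day_start_min, day_end_min, rng):
    """Stratified-interval jitter: the day window is split into
    beeps_per_day equal blocks and one uniform time drawn per block, giving
    strictly increasing within-day times with mean gap = window / beeps."""
    window = day_end_min - day_start_min
    if day_start_min >= day_end_min or window < beeps_per_day:
        raise ConfigurationError("infeasible beep window")
    block = window / beeps_per_day
    rows = []
    for day in range(1, n_days + 1):
        offsets = rng.uniform(0.0, block, size=beeps_per_day)
        times = day_start_min + (np.arange(beeps_per_day) + offsets / block) * block
        for b, t in enumerate(times, start=1):
            rows.append((day, b, float(t)))
    return rows


def generate_beep_schedule(
    n_days: int,
    beeps_per_day: int,
    day_start_min: float = 450.0,
    day_end_min: float = 1350.0,
    mean_gap_min: float = 90.0,
    seed: int = 0,
):
    """Semi-random beep schedule: list of (day, beep_in_day, minutes-of-day).

    Deterministic given ``seed``.  ``mean_gap_min`` documents the intended
    mean within-day gap; the realised mean gap is window / beeps_per_day.
    """
    rng = np.random.default_rng(seed)
    return _schedule_times(n_days, beeps_per_day, day_start_min, day_end_min, rng)


# ---------------------------------------------------------------------------
# Latent VAR(1) process with AR(1) innovations and overnight reset
# ---------------------------------------------------------------------------

def _stacked_stationary_cov(B, phi, innov_sd):
    """Stationary covariance of the stacked state (z_t, e_t) where
    z_t = B z_{t-1} + e_t and e_t = phi e_{t-1} + u_t."""
    k = B.shape[0]
    A = np.zeros((2 * k, 2 * k))
    A[:k, :k] = B
    A[:k, k:] = phi * np.eye(k)
    A[k:, k:] = phi * np.eye(k)
    Su = np.diag(np.square(innov_sd) * (1.0 - phi**2))
    Q = np.block([[Su, Su], [Su, Su]])
    S = sla.solve_discrete_lyapunov(A, Q)
    return 0.5 * (S + S.T)


def stationary_cov(B, phi, innov_sd) -> np.ndarray:
    """Closed-form stationary covariance of the latent affect vector."""
    k = np.shape(B)[0]
    return _stacked_stationary_cov(np.asarray(B, float), phi, np.asarray(innov_sd, float))[:k, :k]


def stationary_lag1_cov(B, phi, innov_sd) -> np.ndarray:
    """Closed-form lag-1 cross-covariance E[z_t z_{t-1}'] of the latent
    process (within a day, away from the overnight reset)."""
    B = np.asarray(B, float)
    k = B.shape[0]
    S = _stacked_stationary_cov(B, phi, np.asarray(innov_sd, float))
    # E[z_t z_{t-1}'] = B Var(z) + phi Cov(e, z)
    return B @ S[:k, :k] + phi * S[k:, :k]


def simulate_latent_series(
    config: SimulationConfig,
    schedule,
    person_effects: dict,
    seed=None,
    rng=None,
) -> np.ndarray:
    """Simulate the 6 x T latent affect matrix for one person.

    ``person_effects`` holds ``mu`` (the person's mean vector) and ``B``
    (the person's transition matrix, ground truth plus random slopes).
    Each day starts with a fresh draw from the stationary distribution of
    the stacked (state, innovation) process — the overnight reset.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    B = np.asarray(person_effects["B"], dtype=float)
    if spectral_radius(B) >= 1.0:
        raise ConfigurationError("person transition matrix is non-stationary")
    mu = np.asarray(person_effects["mu"], dtype=float)
    phi = config.resid_phi
    innov_sd = np.asarray(config.innovation_sd, dtype=float)

    S = _stacked_stationary_cov(B, phi, innov_sd)
    # S is singular when innovation_sd = 0; use an eigendecomposition root.
    w, V = np.linalg.eigh(S)
    root = V * np.sqrt(np.clip(w, 0.0, None))

    T = len(schedule)
    out = np.empty((N_NODES, T))
    u_sd = innov_sd * np.sqrt(1.0 - phi**2)
    prev_day = None
    z = e = None
    for t, (day, _beep, _time) in enumerate(schedule):
        if day != prev_day:
            s = root @ rng.standard_normal(2 * N_NODES)
            z, e = s[:N_NODES], s[N_NODES:]
            prev_day = day
        else:
            u = u_sd * rng.standard_normal(N_NODES)
            e = phi * e + u
            z = B @ z + e
        out[:, t] = mu + z + config.trend_slope * t
    return out


# ---------------------------------------------------------------------------
# Observation model and missingness
# ---------------------------------------------------------------------------

def observe_likert(latent: np.ndarray) -> np.ndarray:
    """Map latent values to the 1-7 Likert scale: round half up, then clip.

    NaNs (missing values) are preserved.
    """
    latent = np.asarray(latent, dtype=float)
    out = np.floor(latent + 0.5)
    out = np.clip(out, LIKERT_MIN, LIKERT_MAX)
    out[np.isnan(latent)] = np.nan
    return out


def apply_missingness(panel: pd.DataFrame, missing_rate: float, seed=None, rng=None) -> pd.DataFrame:
    """Drop whole beeps (all six items at once) independently with
    probability ``missing_rate``; mirrors a complete-observation analysis
    where partially answered beeps are unusable anyway."""
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    out = panel.copy()
    if missing_rate == 0.0:
        return out
    if rng is None:
        rng = np.random.default_rng(seed)
    drop = rng.random(len(out)) < missing_rate
    out.loc[drop, list(NODES)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Person metadata
# ---------------------------------------------------------------------------

def _truncated_normal_int(rng, mean, sd, lo, hi, max_tries=1000):
    # Truncation by resampling (not clipping) to avoid boundary point masses.
    for _ in range(max_tries):
        v = int(round(rng.normal(mean, sd)))
        if lo <= v <= hi:
            return v
    raise RuntimeError("truncated draw failed; bounds too tight")


def simulate_person_meta(group_label: str, seed=None, rng=None,
                         person_id=None, family_id=None, label=None) -> dict:
    """Draw one person's symptom metadata for the given group.

    SCL-90 baseline and the group-specific change score are rounded normal
    draws resampled until both scores fall inside the 90-450 scale; the
    childhood-experience (JTV) sum is drawn strictly below the population
    median, because every simulated person belongs to the screened,
    at-risk half of the cohort.
    """
    if group_label not in META_PARAMS:
        raise KeyError(
            f"no metadata distributions for group {group_label!r}; "
            f"known groups: {sorted(META_PARAMS)}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    p = META_PARAMS[group_label]
    for _ in range(1000):
        t0 = int(round(rng.normal(*p["t0"])))
        change = int(round(rng.normal(*p["change"])))
        t1 = t0 + change
        if SCL_MIN <= t0 <= SCL_MAX and SCL_MIN <= t1 <= SCL_MAX:
            break
    else:  # pragma: no cover
        raise RuntimeError("SCL draw failed")
    jtv = _truncated_normal_int(rng, 15.3, 2.0, JTV_MIN, JTV_POPULATION_MEDIAN - 1)
    age = _truncated_normal_int(rng, 17.4, 3.8, 14, 34)
    sex = "F" if rng.random() < 0.66 else "M"
    return {
        "person_id": person_id,
        "family_id": family_id,
        "scl_t0": t0,
        "scl_t1": t1,
        "jtv_sum": jtv,
        "age": age,
        "sex": sex,
        "true_group": label if label is not None else group_label,
    }


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _person_panel(config, person_id, family_id, schedule, person_effects, rng):
    latent = simulate_latent_series(config, schedule, person_effects, rng=rng)
    if config.observe == "likert":
        ratings = observe_likert(latent)
    else:
        ratings = latent
    days = [s[0] for s in schedule]
    beeps = [s[1] for s in schedule]
    tod = [s[2] for s in schedule]
    rows = pd.DataFrame({
        "person_id": person_id,
        "family_id": family_id,
        "day": days,
        "beep_in_day": beeps,
        "beep_number": np.arange(1, len(schedule) + 1),
        "time_min": [(d - 1) * 1440.0 + t for d, t in zip(days, tod)],
    })
    for i, node in enumerate(NODES):
        rows[node] = ratings[i]
    return rows


def simulate_cohort(configs, seed: int = 0):
    """Simulate a multi-group cohort.

    Parameters
    ----------
    configs : sequence of SimulationConfig
        One per group.  Persons in a family share the family-level random
        effect and the family's group.
    seed : int
        Master seed; all per-person randomness is spawned from it.

    Returns
    -------
    panel : DataFrame
        Long-format beep-level observations (NaN = missing).
    meta : DataFrame
        One row per person with SCL-90, JTV, age, sex and the generating
        group label.
    truth : dict
        Group label -> ground-truth 6x6 transition matrix.
    """
    if isinstance(configs, SimulationConfig):
        configs = [configs]
    master = np.random.SeedSequence(seed)
    panels, metas, truth = [], [], {}
    seen = set()
    for config, cfg_ss in zip(configs, master.spawn(len(configs))):
        if config.seed is not None:
            cfg_ss = np.random.SeedSequence(config.seed)
        truth[config.group_label] = config.transition_matrix.copy()
        prefix = config.group_label[:3].lower()
        mu0 = np.asarray(config.node_means, dtype=float)
        fam_sd = np.asarray(config.family_sd, dtype=float)
        per_sd = np.asarray(config.person_sd, dtype=float)
        for fam_idx, fam_ss in enumerate(cfg_ss.spawn(config.n_families), start=1):
            fam_rng = np.random.default_rng(fam_ss)
            family_id = f"{prefix}{fam_idx:03d}"
            fam_eff = fam_sd * fam_rng.standard_normal(N_NODES)
            for p_idx in range(1, config.persons_per_family + 1):
                person_id = f"{family_id}_{p_idx}"
                if person_id in seen:
                    raise ValueError(f"duplicate person id {person_id!r}")
                seen.add(person_id)
                rng = fam_rng  # persons draw sequentially from the family stream
                mu_p = mu0 + fam_eff + per_sd * rng.standard_normal(N_NODES)
                for _ in range(100):
                    B_p = config.transition_matrix + config.slope_sd * rng.standard_normal((N_NODES, N_NODES))
                    if spectral_radius(B_p) < 0.98:
                        break
                schedule = _schedule_times(
                    config.n_days, config.beeps_per_day,
                    config.day_start_min, config.day_end_min, rng,
                )
                rows = _person_panel(
                    config, person_id, family_id, schedule,
                    {"mu": mu_p, "B": B_p}, rng,
                )
                rows = apply_missingness(rows, config.missing_rate, rng=rng)
                panels.append(rows)
                metas.append(simulate_person_meta(
                    config.meta_group, rng=rng,
                    person_id=person_id, family_id=family_id,
                    label=config.group_label,
                ))
    panel = pd.concat(panels, ignore_index=True)
    meta = pd.DataFrame(metas)
    return panel, meta, truth


# ---------------------------------------------------------------------------
# Writers (long-format CSV; empty cell = missing)
# ---------------------------------------------------------------------------

def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_edges(B: np.ndarray, path) -> None:
    """Ground-truth network as an edge-list CSV (from, to, weight)."""
    B = np.asarray(B, dtype=float)
    rows = [
        {"from": NODES[k], "to": NODES[j], "weight": B[j, k]}
        for j in range(N_NODES) for k in range(N_NODES) if B[j, k] != 0.0
    ]
    pd.DataFrame(rows, columns=["from", "to", "weight"]).to_csv(path, index=False)
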