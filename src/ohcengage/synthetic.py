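"""Synthetic cohort generator.

Real online-health-community usage logs and the paired survey responses of
their users are not publicly available, so every downstream stage of the
pipeline is exercised on synthetic cohorts generated here.  The generator
reproduces the latent structure the analysis assumes:

* each user belongs to one of K engagement components drawn from mixing
  weights;
* a 3-state Markov chain (high / low / disengaged, absorbing
  disengagement, start at high) produces a latent daily state path over the
  observation horizon;
* each day the user is "engaged" with the state's emission probability
  (0 while disengaged); day 1 is always engaged, mirroring the eligibility
  rule that surveyed users were active shortly after signing up;
* on engaged days the seven activity measures get Poisson counts; clicks
  are unit-shifted Poisson so an engaged day always has a nonzero count;
* paired survey responses (13-item activation instrument, 5-dimension
  health-status instrument, health-care-utilization categories,
  demographics) are drawn with a configurable component-specific
  baseline-to-follow-up activation shift and a ceiling-score injection rate.

All randomness flows through one seeded generator; draws are consumed in a
fixed order (components, state paths, engagement flags, activity counts,
surveys) so cohorts are bit-reproducible given the seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .mixture import MEASURES, N_STATES, expected_engaged_days

__all__ = [
    "ConfigError",
    "ComponentSpec",
    "SurveyEffect",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "default_scenario",
    "expected_engaged_days",
]

VISIT_SERVICES = ("gp", "nurse", "outpatient", "ae")
VISIT_CATEGORIES = ("never", "1-3", "4-6", ">6")


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _check_prob_vector(v, name: str, atol: float = 1e-12) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ConfigError(f"{name}: entries must be non-negative")
    if abs(v.sum() - 1.0) > atol:
        raise ConfigError(f"{name}: must sum to 1 (got {v.sum()!r})")
    return v


@dataclasses.dataclass
class ComponentSpec:
    """One mixture component: a 3x3 transition matrix plus a label."""

    transition_matrix: np.ndarray
    label: str = ""

    def validate(self) -> None:
        A = np.asarray(self.transition_matrix, dtype=float)
        if A.shape != (N_STATES, N_STATES):
            raise ConfigError(f"transition_matrix ({self.label}): must be 3x3")
        if np.any(A < 0):
            raise ConfigError(f"transition_matrix ({self.label}): negative entry")
        if np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigError(f"transition_matrix ({self.label}): rows must sum to 1")
        if not np.array_equal(A[2], [0.0, 0.0, 1.0]):
            raise ConfigError(
                f"transition_matrix ({self.label}): disengaged row must be (0, 0, 1)"
            )


@dataclasses.dataclass
class SurveyEffect:
    """Parameters of the paired activation-score responses.

    Baseline scaled scores are Normal(baseline_mean, baseline_sd) truncated
    to [0, 100]; follow-up = baseline + the user's component shift +
    Normal(0, change_sd), truncated.  Ceiling users (scaled score exactly
    100 at one time point) are injected at ``ceiling_prob`` to exercise the
    downstream exclusion rule.
    """

    baseline_mean: float = 60.2
    baseline_sd: float = 14.0
    followup_shift: tuple = (2.0, 0.5, 2.5, 5.1)
    change_sd: float = 8.4
    ceiling_prob: float = 0.046


@dataclasses.dataclass
class GeneratorConfig:
    n_users: int
    components: list
    mixing_weights: Sequence[float]
    horizon_days: int = 91
    emission_probs: Sequence[float] = (0.95, 0.14, 0.0)
    count_intensity: dict = dataclasses.field(
        default_factory=lambda: {
            "pages_viewed": 5.0,
            "clicks": 8.0,
            "groups_followed": 0.2,
            "users_followed": 0.1,
            "posts_liked": 1.2,
            "comments": 0.8,
            "posts": 0.15,
        }
    )
    survey_effect: SurveyEffect = dataclasses.field(default_factory=SurveyEffect)
    #: per service: array (n_components, 2 time points, 4 categories)
    utilization_probs: dict | None = None
    hospital_any_prob: np.ndarray | None = None  # (n_components, 2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 1:
            raise ConfigError("n_users: must be >= 1")
        if self.horizon_days < 1:
            raise ConfigError("horizon_days: must be >= 1")
        if len(self.components) < 1:
            raise ConfigError("components: need at least one component")
        for comp in self.components:
            comp.validate()
        w = _check_prob_vector(self.mixing_weights, "mixing_weights")
        if len(w) != len(self.components):
            raise ConfigError("mixing_weights: length must match components")
        b = np.asarray(self.emission_probs, dtype=float)
        if b.shape != (N_STATES,) or np.any(b < 0) or np.any(b > 1):
            raise ConfigError("emission_probs: need 3 probabilities in [0, 1]")
        if b[2] != 0.0:
            raise ConfigError("emission_probs: disengaged emission must be exactly 0")
        if len(self.survey_effect.followup_shift) != len(self.components):
            raise ConfigError("survey_effect.followup_shift: one shift per component")
        missing = [m for m in MEASURES if m not in self.count_intensity]
        if missing:
            raise ConfigError(f"count_intensity: missing measures {missing}")
        if self.count_intensity["clicks"] < 1.0:
            raise ConfigError("count_intensity: clicks intensity must be >= 1")
        if self.utilization_probs is not None:
            for svc in VISIT_SERVICES:
                arr = np.asarray(self.utilization_probs[svc], dtype=float)
                if arr.shape != (len(self.components), 2, 4):
                    raise ConfigError(
                        f"utilization_probs[{svc}]: need shape (K, 2, 4)"
                    )
                for k in range(arr.shape[0]):
                    for t in range(2):
                        _check_prob_vector(arr[k, t], f"utilization_probs[{svc}][{k},{t}]")


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort: usage logs, paired surveys and ground truth."""

    engagement: pd.DataFrame      # long: user_id, day_index, 7 measure columns
    surveys: pd.DataFrame         # wide: one row per user
    true_component: np.ndarray    # (n_users,)
    true_state_paths: np.ndarray  # (n_users, horizon_days)
    config: GeneratorConfig

    @property
    def user_ids(self) -> list:
        return list(self.surveys["user_id"])

    def engagement_matrix(self) -> np.ndarray:
        """Dense (n_users, horizon) engaged-day flags, row order = user_ids."""
        T = self.config.horizon_days
        n = self.config.n_users
        X = np.zeros((n, T), dtype=bool)
        idx = {u: i for i, u in enumerate(self.user_ids)}
        active = self.engagement[list(MEASURES)].values.sum(axis=1) > 0
        rows = self.engagement.loc[active]
        X[
            [idx[u] for u in rows["user_id"]],
            rows["day_index"].to_numpy() - 1,
        ] = True
        return X


# ---------------------------------------------------------------------------


def _default_utilization(K: int) -> tuple[dict, np.ndarray]:
    """Visit-category distributions per component and time point.

    Any-visit rates rise with engagement for most services while emergency
    attendance falls at follow-up for the most engaged; positive counts are
    split 80/15/5 across the 1-3 / 4-6 / >6 categories.
    """
    any_rate = {
        "gp": ([0.88, 0.85, 0.92, 0.86], [0.82, 0.85, 0.87, 0.81]),
        "nurse": ([0.44, 0.21, 0.37, 0.41], [0.31, 0.32, 0.29, 0.44]),
        "outpatient": ([0.65, 0.52, 0.63, 0.68], [0.53, 0.45, 0.60, 0.59]),
        "ae": ([0.12, 0.17, 0.28, 0.20], [0.24, 0.14, 0.19, 0.07]),
    }
    split = np.array([0.80, 0.15, 0.05])
    out = {}
    for svc, (base, fup) in any_rate.items():
        arr = np.zeros((K, 2, 4))
        for t, rates in enumerate((base, fup)):
            for k in range(K):
                p = rates[min(k, len(rates) - 1)]
                arr[k, t, 0] = 1.0 - p
                arr[k, t, 1:] = p * split
        out[svc] = arr
    hosp = np.zeros((K, 2))
    hosp_base = [0.22, 0.21, 0.25, 0.20]
    hosp_fup = [0.06, 0.12, 0.19, 0.15]
    for k in range(K):
        hosp[k, 0] = hosp_base[min(k, 3)]
        hosp[k, 1] = hosp_fup[min(k, 3)]
    return out, hosp


def default_scenario(n_users: int = 1000, seed: int = 1729) -> GeneratorConfig:
    """The packaged reference scenario: four engagement components.

    The components form a low / medium / high / very-high gradient with
    expected active-day counts of roughly 7, 13, 36 and 60 over a 91-day
    horizon and strictly decreasing disengagement hazards, with mixing
    weights (0.15, 0.20, 0.35, 0.30).  The four profiles are separated
    along both lifetime and engagement density so that trajectories are
    statistically attributable to their component:

    * low — mixed-intensity activity that disengages after about two
      weeks (daily hazard 0.06 from either state);
    * medium — drops to the low-intensity state almost immediately and
      engages sparsely (roughly one day in seven), rarely disengaging;
    * high — alternates between states in multi-day runs, engaged about
      two days in five;
    * very high — mostly high-intensity, engaged about two days in three,
      essentially never disengaging inside the window.

    Pure function: two calls return identical configurations.
    """
    comps = [
        ComponentSpec(
            np.array([[0.74, 0.20, 0.06], [0.06, 0.88, 0.06], [0.0, 0.0, 1.0]]),
            label="low",
        ),
        ComponentSpec(
            np.array([[0.02, 0.978, 0.002], [0.005, 0.993, 0.002], [0.0, 0.0, 1.0]]),
            label="medium",
        ),
        ComponentSpec(
            np.array([[0.644, 0.355, 0.001], [0.167, 0.832, 0.001], [0.0, 0.0, 1.0]]),
            label="high",
        ),
        ComponentSpec(
            np.array(
                [[0.8335, 0.1660, 0.0005], [0.299, 0.7005, 0.0005], [0.0, 0.0, 1.0]]
            ),
            label="very high",
        ),
    ]
    util, hosp = _default_utilization(4)
    return GeneratorConfig(
        n_users=n_users,
        components=comps,
        mixing_weights=(0.15, 0.20, 0.35, 0.30),
        horizon_days=91,
        emission_probs=(0.95, 0.14, 0.0),
        utilization_probs=util,
        hospital_any_prob=hosp,
        seed=seed,
    )


def _simulate_paths(rng, config, comp_idx):
    """Latent state paths; vectorized over users, day-by-day."""
    n, T = config.n_users, config.horizon_days
    A = np.stack([np.asarray(c.transition_matrix, dtype=float) for c in config.components])
    paths = np.zeros((n, T), dtype=np.int8)  # everybody starts at high (0)
    cum = np.cumsum(A, axis=2)
    for t in range(1, T):
        rows = cum[comp_idx, paths[:, t - 1]]  # (n, 3) cumulative rows
        u = rng.random(n)
        paths[:, t] = (u[:, None] >= rows).sum(axis=1)
    return paths


def _distribute_raw(rng, raw: int) -> np.ndarray:
    """13 item responses in 1..4 summing to the given raw score."""
    items = np.ones(13, dtype=int)
    need = raw - 13
    while need > 0:
        open_slots = np.flatnonzero(items < 4)
        items[open_slots[rng.integers(len(open_slots))]] += 1
        need -= 1
    return items


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a validated configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_users, config.horizon_days
    K = len(config.components)
    b = np.asarray(config.emission_probs, dtype=float)

    # 1. component memberships
    comp_idx = rng.choice(K, size=n, p=np.asarray(config.mixing_weights, dtype=float))
    # 2. latent state paths
    paths = _simulate_paths(rng, config, comp_idx)
    # 3. engaged-day flags; day 1 always engaged
    engaged = rng.random((n, T)) < b[paths]
    engaged[:, 0] = True
    # 4. activity counts on engaged days
    users, days = np.nonzero(engaged)
    m = len(users)
    counts = {}
    for meas in MEASURES:
        lam = config.count_intensity[meas]
        if meas == "clicks":  # unit-shifted: an engaged day always counts
            counts[meas] = 1 + rng.poisson(lam - 1.0, size=m)
        else:
            counts[meas] = rng.poisson(lam, size=m)
    user_ids = [f"u{i:05d}" for i in range(n)]
    engagement = pd.DataFrame(
        {
            "user_id": [user_ids[i] for i in users],
            "day_index": days + 1,
            **counts,
        }
    )

    # 5. surveys
    eff = config.survey_effect
    base_scaled = np.clip(rng.normal(eff.baseline_mean, eff.baseline_sd, size=n), 0, 100)
    shifts = np.asarray(eff.followup_shift, dtype=float)[comp_idx]
    fup_scaled = np.clip(base_scaled + shifts + rng.normal(0, eff.change_sd, size=n), 0, 100)
    ceiling = rng.random(n) < eff.ceiling_prob
    ceiling_at_followup = rng.random(n) < 0.5
    base_raw = np.clip(np.rint(base_scaled / 100.0 * 39.0 + 13.0), 13, 52).astype(int)
    fup_raw = np.clip(np.rint(fup_scaled / 100.0 * 39.0 + 13.0), 13, 52).astype(int)
    base_raw[ceiling & ~ceiling_at_followup] = 52
    fup_raw[ceiling & ceiling_at_followup] = 52
    pam_b = np.stack([_distribute_raw(rng, r) for r in base_raw])
    pam_f = np.stack([_distribute_raw(rng, r) for r in fup_raw])

    eq_probs = np.array([0.45, 0.25, 0.15, 0.10, 0.05])
    eq_b = rng.choice(5, size=(n, 5), p=eq_probs) + 1
    eq_f = rng.choice(5, size=(n, 5), p=eq_probs) + 1

    util = config.utilization_probs
    hosp = config.hospital_any_prob
    if util is None:
        util, default_hosp = _default_utilization(K)
        if hosp is None:
            hosp = default_hosp
    elif hosp is None:
        hosp = np.full((K, 2), 0.2)
    visits = {}
    for svc in VISIT_SERVICES:
        arr = np.asarray(util[svc], dtype=float)
        for t, suffix in enumerate(("b", "f")):
            cats = np.empty(n, dtype=object)
            for k in range(K):
                mask = comp_idx == k
                cats[mask] = rng.choice(
                    VISIT_CATEGORIES, size=int(mask.sum()), p=arr[k, t]
                )
            visits[f"{svc}_{suffix}"] = cats
    hosp_days = {}
    for t, suffix in enumerate(("b", "f")):
        any_h = rng.random(n) < np.asarray(hosp, dtype=float)[comp_idx, t]
        d = np.where(any_h, 1 + rng.poisson(2.0, size=n), 0)
        hosp_days[f"hospital_days_{suffix}"] = d

    age_groups = rng.choice(
        ["<40", "40-49", "50-59", "60-69", ">70"],
        size=n,
        p=[0.08, 0.14, 0.29, 0.36, 0.13],
    )
    gender = rng.choice(["female", "male"], size=n, p=[0.77, 0.23])

    surveys = pd.DataFrame({"user_id": user_ids, "age_group": age_groups, "gender": gender})
    for j in range(13):
        surveys[f"pam{j + 1}_b"] = pam_b[:, j]
    for j in range(13):
        surveys[f"pam{j + 1}_f"] = pam_f[:, j]
    for j, dim in enumerate(("mobility", "selfcare", "activities", "pain", "anxiety")):
        surveys[f"eq_{dim}_b"] = eq_b[:, j]
        surveys[f"eq_{dim}_f"] = eq_f[:, j]
    for col, vals in visits.items():
        surveys[col] = vals
    for col, vals in hosp_days.items():
        surveys[col] = vals

    return SyntheticCohort(
        engagement=engagement,
        surveys=surveys,
        true_component=comp_idx,
        true_state_paths=paths,
        config=config,
    )
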