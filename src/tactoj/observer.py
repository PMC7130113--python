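"""Synthetic observers and patient cohorts for the tactile TOJ task.

The generative model is a cumulative-normal (probit) observer expressed in
the *affected frame*: let ``u`` be the lead time (ms) of the unaffected
hand, so ``u > 0`` means the unaffected hand was stimulated first.  The
probability of reporting the affected hand first is

    P(affected first | u) = lapse/2 + (1 - lapse) * Phi((pss_true - u) / sigma_p)

where ``Phi`` is the standard normal CDF and ``sigma_p = sigma *
crossed_sigma_factor`` when the arms are crossed (crossing the hands
degrades temporal sensitivity; the crossed-hands deficit).  ``pss_true`` is
the observer's point of subjective simultaneity: positive values mean
stimuli on the affected limb are prioritized.

This sign convention makes the fitted PSS directly comparable across
subjects with left- or right-sided pain without any post-hoc sign flip.

The cohort simulator draws per-subject covariates (pain duration, pain
intensity, hand-temperature difference) and maps them to each subject's
``pss_true`` through linear effect coefficients, optionally interacting
with posture, then simulates every trial of the standard schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import TrialSchedule, build_trial_schedule

SIDES = ("left", "right")
GROUPS = ("CRPS", "shoulder", "wrist")
RESPONSES = ("left_first", "right_first")


@dataclass(frozen=True)
class Observer:
    """Generative psychometric parameters of one subject.

    Parameters
    ----------
    pss_true
        True point of subjective simultaneity in ms; positive = stimuli on
        the affected limb are prioritized.
    sigma
        Psychometric spread in ms (uncrossed posture); must be > 0.
    crossed_sigma_factor
        Multiplier (>= 1) applied to ``sigma`` when the arms are crossed.
    lapse
        Stimulus-independent lapse probability in [0, 0.5); on a lapse the
        response is a coin flip.
    affected_side
        Which hand is the painful/affected one.
    """

    pss_true: float
    sigma: float
    crossed_sigma_factor: float = 1.0
    lapse: float = 0.0
    affected_side: str = "left"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")
        if self.crossed_sigma_factor < 1:
            raise ValueError("crossed_sigma_factor must be >= 1")
        if self.affected_side not in SIDES:
            raise ValueError(f"affected_side must be one of {SIDES}")


@dataclass
class SubjectMeta:
    """Subject-level metadata used as model covariates."""

    subject_id: str
    group: str
    affected_side: str
    pain_duration_months: float
    pain_intensity: float
    temp_diff_c: float | None = None  # affected minus unaffected; None = missing
    temp_imputed: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.affected_side not in SIDES:
            raise ValueError(f"affected_side must be one of {SIDES}")
        if not 0 <= self.pain_intensity <= 10:
            raise ValueError("pain_intensity must be in [0, 10]")
        if self.pain_duration_months < 0:
            raise ValueError("pain_duration_months must be >= 0")


# ---------------------------------------------------------------------------
# Frame conversion: left/right lab frame <-> affected frame
# ---------------------------------------------------------------------------

def unaffected_lead(soa_ms, affected_side: str):
    """Convert signed lab-frame SOA to the unaffected hand's lead time u.

    Lab frame: soa < 0 = left hand first.  u > 0 = unaffected hand first.
    """
    if affected_side == "left":
        return np.asarray(soa_ms, dtype=float) + 0.0
    if affected_side == "right":
        return -np.asarray(soa_ms, dtype=float)
    raise ValueError(f"affected_side must be one of {SIDES}")


def is_affected_first(response, affected_side: str):
    """Whether a lab-frame response names the affected hand as first."""
    first = affected_side + "_first"
    return np.asarray(response) == first


def response_label(affected_first, affected_side: str):
    """Map affected-frame responses back to lab-frame labels."""
    aff = affected_side + "_first"
    una = ("right" if affected_side == "left" else "left") + "_first"
    return np.where(np.asarray(affected_first, dtype=bool), aff, una)


# ---------------------------------------------------------------------------
# Single-observer simulation
# ---------------------------------------------------------------------------

def response_probability(observer: Observer, u, posture: str):
    """P(report affected hand first) at unaffected lead time ``u`` (ms).

    Vectorized over ``u``.  Non-increasing in ``u`` whenever lapse < 0.5.
    """
    sigma_p = observer.sigma * (
        observer.crossed_sigma_factor if posture == "crossed" else 1.0
    )
    u = np.asarray(u, dtype=float)
    core = norm.cdf((observer.pss_true - u) / sigma_p)
    p = observer.lapse / 2 + (1 - observer.lapse) * core
    return p if p.ndim else float(p)


def simulate_subject(
    observer: Observer,
    schedule: TrialSchedule,
    meta: SubjectMeta | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one subject's responses over a full trial schedule.

    Returns a tidy trial frame with columns
    ``subject_id, block, trial_index, posture, soa_ms, response``,
    with ``response`` in the lab frame (``left_first`` / ``right_first``).
    Deterministic given the seed.
    """
    if meta is not None and meta.affected_side != observer.affected_side:
        raise ValueError("meta.affected_side must match observer.affected_side")
    subject_id = meta.subject_id if meta is not None else "S00"
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    trials = schedule.to_frame(subject_id=subject_id)
    u = unaffected_lead(trials["soa_ms"].to_numpy(), observer.affected_side)
    p = np.empty(len(trials))
    for posture in ("uncrossed", "crossed"):
        mask = (trials["posture"] == posture).to_numpy()
        if mask.any():
            p[mask] = response_probability(observer, u[mask], posture)
    affected_first = rng.random(len(trials)) < p
    trials["response"] = response_label(affected_first, observer.affected_side)
    return trials


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectCoefficients:
    """Linear map from covariates to a subject's true PSS (ms).

    ``pss_true(posture) = intercept + temp * temp_diff
    + duration * pain_duration + [crossed] * (temp_x_crossed * temp_diff
    + duration_x_crossed * pain_duration)``
    """

    intercept: float = 0.0
    temp: float = 0.0  # ms per degC
    duration: float = 0.0  # ms per month
    temp_x_crossed: float = 0.0
    duration_x_crossed: float = 0.0


@dataclass(frozen=True)
class GroupConfig:
    """Generative settings for one patient group."""

    n: int
    pain_duration_mean: float  # months; log-normal with this mean
    pain_duration_sdlog: float = 0.8
    pain_intensity_mean: float = 5.0
    pain_intensity_sd: float = 2.0
    temp_diff_mean: float = 0.3  # degC, affected minus unaffected
    temp_diff_sd: float = 1.0
    n_missing_temp: int = 0
    effects: EffectCoefficients = field(default_factory=EffectCoefficients)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name in ("pain_duration_sdlog", "pain_intensity_sd", "temp_diff_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.n_missing_temp <= self.n:
            raise ValueError("n_missing_temp must be in [0, n]")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort generative configuration.

    Defaults (see :func:`default_cohort_config`) reproduce the study's
    conditions: group sizes 14/15/16, base spread 100 ms, roughly doubled
    crossed spread, and covariate effects of the reported magnitudes.
    """

    groups: dict[str, GroupConfig]
    sigma: float = 100.0  # ms, uncrossed psychometric spread
    sigma_sdlog: float = 0.25  # subject-level log-normal spread of sigma
    crossed_sigma_factor: float = 2.2
    lapse: float = 0.02
    pss_noise_sd: float = 30.0  # ms, subject-level residual PSS spread
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for name in ("sigma_sdlog", "pss_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(g.n for g in self.groups.values())


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """The study-scale default cohort: 45 subjects in three pain groups.

    Group sizes (14 CRPS, 15 shoulder, 16 wrist) and pain-duration means
    match the analysed samples; the temperature and duration effect
    coefficients carry the reported magnitudes (+12.25 ms/degC on wrist PSS,
    -37.69 ms/degC temperature-by-posture interaction for shoulder,
    -0.74 ms/month pain duration for wrist).  Five subjects (2 CRPS,
    3 wrist) have missing temperature measurements.
    """
    return CohortConfig(
        groups={
            "CRPS": GroupConfig(n=14, pain_duration_mean=10.0, n_missing_temp=2),
            "shoulder": GroupConfig(
                n=15,
                pain_duration_mean=24.0,
                effects=EffectCoefficients(temp_x_crossed=-37.69),
            ),
            "wrist": GroupConfig(
                n=16,
                pain_duration_mean=24.0,
                n_missing_temp=3,
                effects=EffectCoefficients(temp=12.25, duration=-0.74),
            ),
        },
        seed=seed,
    )


def simulate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: metadata, all trials, and generative truth.

    Per-subject randomness uses a stream seeded ``master_seed +
    subject_index`` so subjects are independent yet individually
    reproducible; the start posture alternates with subject index
    (even index -> uncrossed first) to counterbalance posture order.

    Returns
    -------
    meta : DataFrame
        One row per subject (SubjectMeta fields; missing temp_diff as NaN).
    trials : DataFrame
        One row per trial (subject_id, block, trial_index, posture, soa_ms,
        response).
    truth : DataFrame
        One row per subject x posture with the generative pss_true, sigma
        used, and the latent (pre-masking) temperature difference.
    """
    master_seed = config.seed if seed is None else seed
    if master_seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(master_seed)

    meta_rows: list[SubjectMeta] = []
    truth_rows = []
    trial_frames = []
    idx = 0
    for group_name, g in config.groups.items():
        # draw which subjects of this group lose their temperature record
        missing_idx = set(
            rng.choice(g.n, size=g.n_missing_temp, replace=False).tolist()
        )
        for j in range(g.n):
            subject_id = f"{group_name[0].upper()}{j + 1:02d}"
            affected_side = "left" if rng.random() < 0.5 else "right"
            mulog = np.log(g.pain_duration_mean) - g.pain_duration_sdlog**2 / 2
            duration = float(rng.lognormal(mulog, g.pain_duration_sdlog))
            intensity = float(
                np.clip(rng.normal(g.pain_intensity_mean, g.pain_intensity_sd), 0, 10)
            )
            temp = float(rng.normal(g.temp_diff_mean, g.temp_diff_sd))
            noise = float(rng.normal(0.0, config.pss_noise_sd))
            sigma_j = float(config.sigma * rng.lognormal(0.0, config.sigma_sdlog))

            e = g.effects
            pss = {}
            for posture in ("uncrossed", "crossed"):
                crossed = posture == "crossed"
                pss[posture] = (
                    e.intercept
                    + e.temp * temp
                    + e.duration * duration
                    + (e.temp_x_crossed * temp if crossed else 0.0)
                    + (e.duration_x_crossed * duration if crossed else 0.0)
                    + noise
                )

            meta_rows.append(
                SubjectMeta(
                    subject_id=subject_id,
                    group=group_name,
                    affected_side=affected_side,
                    pain_duration_months=duration,
                    pain_intensity=intensity,
                    temp_diff_c=None if j in missing_idx else temp,
                )
            )
            truth_rows.extend(
                {
                    "subject_id": subject_id,
                    "posture": posture,
                    "pss_true": pss[posture],
                    "sigma": sigma_j,
                    "crossed_sigma_factor": config.crossed_sigma_factor,
                    "latent_temp_diff_c": temp,
                }
                for posture in ("uncrossed", "crossed")
            )

            # a crossed-posture PSS shift is a shift of the crossed curve only;
            # simulate each posture's trials with its own pss_true
            start = "uncrossed" if idx % 2 == 0 else "crossed"
            schedule = build_trial_schedule(
                start_posture=start, seed=master_seed + idx
            )
            sub_rng = np.random.default_rng(master_seed + idx)
            trials = schedule.to_frame(subject_id=subject_id)
            u = unaffected_lead(trials["soa_ms"].to_numpy(), affected_side)
            p = np.empty(len(trials))
            for posture in ("uncrossed", "crossed"):
                obs = Observer(
                    pss_true=pss[posture],
                    sigma=sigma_j,
                    crossed_sigma_factor=config.crossed_sigma_factor,
                    lapse=config.lapse,
                    affected_side=affected_side,
                )
                mask = (trials["posture"] == posture).to_numpy()
                p[mask] = response_probability(obs, u[mask], posture)
            affected_first = sub_rng.random(len(trials)) < p
            trials["response"] = response_label(affected_first, affected_side)
            trial_frames.append(trials)
            idx += 1

    meta = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "affected_side": m.affected_side,
                "pain_duration_months": m.pain_duration_months,
                "pain_intensity": m.pain_intensity,
                "temp_diff_c": np.nan if m.temp_diff_c is None else m.temp_diff_c,
                "temp_imputed": m.temp_imputed,
            }
            for m in meta_rows
        ]
    )
    return meta, pd.concat(trial_frames, ignore_index=True), pd.DataFrame(truth_rows)


def impute_temperature(meta: pd.DataFrame) -> pd.DataFrame:
    """Impute missing temperature differences by the group median.

    Missing ``temp_diff_c`` values (NaN) are replaced by the median of the
    non-missing values within the same group, and flagged in
    ``temp_imputed``.  A group whose values are all missing cannot be
    imputed and raises ``ValueError``.
    """
    out = meta.copy()
    missing = out["temp_diff_c"].isna()
    if not missing.any():
        return out
    for group, idx in out.groupby("group").groups.items():
        sub = out.loc[idx, "temp_diff_c"]
        if sub.isna().all():
            raise ValueError(f"group {group!r} has no observed temp_diff_c to impute from")
        med = sub.median()
        fill = idx[sub.isna()]
        out.loc[fill, "temp_diff_c"] = med
        out.loc[fill, "temp_imputed"] = True
    return out


def observer_from_meta(meta: SubjectMeta, pss_true: float, sigma: float, **kw) -> Observer:
    """Convenience: build an Observer consistent with a SubjectMeta."""
    return Observer(
        pss_true=pss_true, sigma=sigma, affected_side=meta.affected_side, **kw
    )
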