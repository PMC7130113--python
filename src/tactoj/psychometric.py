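"""Per-subject probit estimation of PSS and JND from TOJ trials.

For each subject and posture the proportion of affected-hand-first reports
is tabulated per SOA (expressed in the affected frame: u = lead time of the
unaffected hand), converted to z-scores through the inverse standard normal
CDF (probits), and a straight line z = intercept + slope * u is fitted by
ordinary least squares.  The point of subjective simultaneity is the SOA at
which the line crosses z = 0,

    PSS = -intercept / slope,

positive values meaning stimuli on the affected limb are prioritized.  The
just noticeable difference — the interval needed for 75% correct order
discrimination — is

    JND = 0.675 / slope,

whose magnitude equals, up to rounding of 0.675 ~ Phi^-1(0.75), half the
distance between the SOAs at which the line crosses the 0.25 and 0.75
points.  Under the affected-frame axis the slope is negative for any
competent observer, so signed JNDs are negative; the magnitude is reported
alongside.

Observed proportions of 0 or 1 have infinite probits; by default they are
clipped to 1/(2n) and 1 - 1/(2n) before transformation (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress, norm

from .observer import is_affected_first, unaffected_lead

#: Conventional constant for the 75% point (Phi^-1(0.75) rounded).
JND_CONSTANT = 0.675


@dataclass(frozen=True)
class LineFit:
    """Ordinary least-squares line through (u, z) points."""

    slope: float  # probit units per ms
    intercept: float  # probit units
    n_points: int
    r_squared: float


@dataclass(frozen=True)
class PostureEstimates:
    """Fitted quantities for one posture of one subject."""

    fit: LineFit
    pss_ms: float
    jnd_signed_ms: float
    jnd_mag_ms: float
    pct_correct_200: float


@dataclass(frozen=True)
class SubjectSummary:
    """Per-posture fitted estimates for one subject."""

    subject_id: str
    affected_side: str
    postures: dict[str, PostureEstimates]

    def to_rows(self) -> list[dict]:
        rows = []
        for posture, est in self.postures.items():
            rows.append(
                {
                    "subject_id": self.subject_id,
                    "posture": posture,
                    "slope": est.fit.slope,
                    "intercept": est.fit.intercept,
                    "r_squared": est.fit.r_squared,
                    "pss_ms": est.pss_ms,
                    "jnd_signed_ms": est.jnd_signed_ms,
                    "jnd_mag_ms": est.jnd_mag_ms,
                    "pct_correct_200": est.pct_correct_200,
                }
            )
        return rows


def aggregate_proportions(trials: pd.DataFrame, affected_side: str) -> pd.DataFrame:
    """Tabulate affected-first proportions per SOA and posture.

    Converts lab-frame SOAs and responses into the affected frame, then
    counts trials and affected-first reports per distinct u per posture.

    Returns a frame with columns ``posture, u_ms, n, k, p`` where ``p = k/n``.
    """
    if len(trials) == 0:
        raise ValueError("no trials to aggregate")
    if trials["subject_id"].nunique() > 1:
        raise ValueError("aggregate_proportions expects a single subject's trials")
    df = trials.copy()
    df["u_ms"] = unaffected_lead(df["soa_ms"].to_numpy(), affected_side)
    df["affected_first"] = is_affected_first(df["response"].to_numpy(), affected_side)
    out = (
        df.groupby(["posture", "u_ms"], as_index=False)
        .agg(n=("affected_first", "size"), k=("affected_first", "sum"))
        .astype({"k": int})
    )
    out["p"] = out["k"] / out["n"]
    return out


def table_from_probabilities(u_ms, probs, posture: str = "uncrossed") -> pd.DataFrame:
    """Build a proportion table directly from exact probabilities.

    Used for closed-form checks: with exact cumulative-normal probabilities
    the probit pipeline is an identity for the generating parameters.
    Rows carry n = 1 placeholder counts; pair with ``clip=None``.
    """
    u = np.asarray(u_ms, dtype=float)
    p = np.asarray(probs, dtype=float)
    return pd.DataFrame(
        {"posture": posture, "u_ms": u, "n": 1, "k": np.nan, "p": p}
    )


def probit_transform(table: pd.DataFrame, clip: str | None = "half") -> pd.DataFrame:
    """Convert proportions to probit z-scores.

    ``clip="half"`` (default) clips p into [1/(2n), 1 - 1/(2n)] so that
    extreme proportions of 0 or 1 remain finite; ``clip=None`` transforms
    the raw proportions (infinite z for p in {0, 1}).

    Returns the table with a ``z`` column added.
    """
    out = table.copy()
    p = out["p"].to_numpy(dtype=float)
    if clip == "half":
        n = out["n"].to_numpy(dtype=float)
        p = np.clip(p, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    elif clip is not None:
        raise ValueError(f"unknown clip rule {clip!r}")
    out["z"] = norm.ppf(p)
    return out


def fit_probit_line(points: pd.DataFrame) -> LineFit:
    """Unweighted least-squares line z = intercept + slope * u.

    ``points`` needs columns ``u_ms`` and ``z`` with at least two distinct
    u values.
    """
    u = points["u_ms"].to_numpy(dtype=float)
    z = points["z"].to_numpy(dtype=float)
    if np.unique(u).size < 2:
        raise ValueError("need >= 2 distinct u values to fit a line")
    res = linregress(u, z)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=len(u),
        r_squared=float(res.rvalue**2),
    )


def compute_pss(fit: LineFit) -> float:
    """PSS in ms: the opposite of the intercept divided by the slope."""
    if fit.slope == 0:
        raise ZeroDivisionError("slope is 0: PSS undefined")
    return -fit.intercept / fit.slope


def compute_jnd(fit: LineFit) -> tuple[float, float]:
    """(signed, magnitude) JND in ms: 0.675 divided by the slope."""
    if fit.slope == 0:
        raise ZeroDivisionError("slope is 0: JND undefined")
    signed = JND_CONSTANT / fit.slope
    return signed, abs(signed)


def percent_correct_at(trials: pd.DataFrame, abs_soa: float = 200.0) -> float:
    """Proportion of correct order reports among trials with |SOA| = abs_soa.

    Correctness is anatomical: the response must name the hand that was
    truly stimulated first, regardless of posture.
    """
    sub = trials[trials["soa_ms"].abs() == abs_soa]
    if len(sub) == 0:
        raise ValueError(f"no trials with |soa| = {abs_soa}")
    truly_left_first = sub["soa_ms"].to_numpy() < 0
    said_left_first = sub["response"].to_numpy() == "left_first"
    return float(np.mean(truly_left_first == said_left_first))


def fit_subject(
    trials: pd.DataFrame, affected_side: str, clip: str | None = "half"
) -> SubjectSummary:
    """Full per-subject pipeline: proportions -> probits -> line -> PSS/JND.

    Fits each posture separately and attaches the percent correct at the
    largest SOA (computed within that posture's trials), as used by the
    inclusion criteria.
    """
    subject_id = str(trials["subject_id"].iloc[0])
    table = aggregate_proportions(trials, affected_side)
    table = probit_transform(table, clip=clip)
    postures = {}
    for posture, pts in table.groupby("posture"):
        fit = fit_probit_line(pts)
        pss = compute_pss(fit)
        jnd_signed, jnd_mag = compute_jnd(fit)
        pct = percent_correct_at(trials[trials["posture"] == posture])
        postures[str(posture)] = PostureEstimates(
            fit=fit,
            pss_ms=pss,
            jnd_signed_ms=jnd_signed,
            jnd_mag_ms=jnd_mag,
            pct_correct_200=pct,
        )
    return SubjectSummary(
        subject_id=subject_id, affected_side=affected_side, postures=postures
    )


def fit_cohort(
    trials: pd.DataFrame, meta: pd.DataFrame, clip: str | None = "half"
) -> list[SubjectSummary]:
    """Fit every subject in a tidy cohort trial frame."""
    sides = meta.set_index("subject_id")["affected_side"]
    out = []
    for subject_id, sub in trials.groupby("subject_id", sort=False):
        out.append(fit_subject(sub, sides[subject_id], clip=clip))
    return out


def summaries_to_frame(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """Stack subject summaries into one tidy frame (one row per subject x posture)."""
    rows = [row for s in summaries for row in s.to_rows()]
    return pd.DataFrame(rows)
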