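"""Double random staircase for matching vibrotactile intensity between hands.

The procedure has two parts of 16 trials each.  Part 1 presents stimuli to
the left hand, rated against a maximum-intensity reference (0.21 W) on a
1-5 sensation scale; the intensity whose average rating is 3 becomes the
left-hand stimulus intensity.  Part 2 repeats the procedure on the right
hand, rating each stimulus against the selected left-hand intensity on a
1-5 comparison scale (3 = "equally strong").

Within a part, two staircases — one starting high, one low — are
interleaved in seeded random order (8 trials each).  After each rating the
active staircase's level moves one fixed step toward the target rating of
3 (down after a rating above 3, up after one below, unchanged at 3);
levels are clamped to (0, max_power].  The selected intensity is read off
the per-level mean ratings: an exact mean of 3 wins (lowest such level on
ties), otherwise the intensity at mean rating 3 is linearly interpolated
between the two bracketing levels; if 3 lies outside the observed range
the closest level is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

MAX_POWER_W = 0.21  # reference stimulus power


@dataclass(frozen=True)
class StaircaseConfig:
    max_power: float = MAX_POWER_W
    n_trials_per_part: int = 16
    step_fraction: float = 0.10  # step size as a fraction of max_power
    start_levels: tuple[float, float] = (0.20, 0.02)  # (high, low)

    def __post_init__(self) -> None:
        if not 0 < self.step_fraction < 1:
            raise ValueError("step_fraction must be in (0, 1)")
        for lv in self.start_levels:
            if not 0 < lv <= self.max_power:
                raise ValueError("start levels must be within (0, max_power]")
        if self.n_trials_per_part < 2 or self.n_trials_per_part % 2:
            raise ValueError("n_trials_per_part must be an even integer >= 2")

    @property
    def step(self) -> float:
        return self.step_fraction * self.max_power


class RatingModel(Protocol):
    """Maps a delivered intensity (W) to a rating in 1..5, possibly stochastic."""

    def rate(self, intensity: float, rng: np.random.Generator) -> int: ...


@dataclass(frozen=True)
class LinearRatingModel:
    """Rating = 3 + gain * (intensity - anchor), rounded and clipped to 1..5.

    ``anchor`` is the intensity at which the expected rating is 3;
    ``gain`` is in rating units per Watt (default steep enough that one
    staircase step moves the rounded rating off 3).  Gaussian rating noise
    with SD ``noise_sd`` may be added before rounding.
    """

    anchor: float
    gain: float = 30.0
    noise_sd: float = 0.0

    def rate(self, intensity: float, rng: np.random.Generator) -> int:
        raw = 3.0 + self.gain * (intensity - self.anchor)
        if self.noise_sd > 0:
            raw += rng.normal(0.0, self.noise_sd)
        return int(np.clip(round(raw), 1, 5))


@dataclass(frozen=True)
class ConstantRatingModel:
    """Always returns the same rating (useful fixed-point check)."""

    rating: int = 3

    def rate(self, intensity: float, rng: np.random.Generator) -> int:
        return self.rating


def run_double_staircase(
    model: RatingModel,
    config: StaircaseConfig = StaircaseConfig(),
    seed: int = 0,
    part: int = 1,
) -> tuple[float, pd.DataFrame]:
    """Run one part of the procedure and return (selected intensity, log).

    The log has one row per trial: part, trial, staircase_id, intensity_watt,
    rating.  Identical seeds give identical logs.
    """
    rng = np.random.default_rng(seed)
    n_each = config.n_trials_per_part // 2
    order = rng.permutation([0] * n_each + [1] * n_each)
    levels = list(config.start_levels)
    rows = []
    for t, sc in enumerate(order, start=1):
        intensity = float(np.clip(levels[sc], 1e-9, config.max_power))
        rating = int(model.rate(intensity, rng))
        if not 1 <= rating <= 5:
            raise ValueError(f"rating model returned {rating}, outside 1..5")
        rows.append(
            {
                "part": part,
                "trial": t,
                "staircase_id": sc,
                "intensity_watt": intensity,
                "rating": rating,
            }
        )
        if rating > 3:
            levels[sc] = intensity - config.step
        elif rating < 3:
            levels[sc] = intensity + config.step
        levels[sc] = float(np.clip(levels[sc], 1e-9, config.max_power))
    log = pd.DataFrame(rows)
    return select_intensity(log), log


def select_intensity(log: pd.DataFrame) -> float:
    """Selected intensity: the level whose average rating is 3.

    Entries are grouped by intensity level and the mean rating per level is
    computed.  An exact mean of 3 returns that level (lowest on ties);
    otherwise the intensity at rating 3 is linearly interpolated between the
    two adjacent levels whose mean ratings bracket 3; if no pair brackets 3,
    the level with mean rating closest to 3 is returned.
    """
    if log is None or len(log) == 0:
        raise ValueError("empty staircase log")
    # guard against float dust when grouping by level
    lv = log.assign(level=log["intensity_watt"].round(9))
    means = (
        lv.groupby("level")["rating"].mean().sort_index()
    )
    exact = means.index[np.isclose(means.to_numpy(), 3.0)]
    if len(exact):
        return float(exact.min())
    x = means.index.to_numpy(dtype=float)
    y = means.to_numpy(dtype=float)
    for i in range(len(x) - 1):
        if (y[i] - 3.0) * (y[i + 1] - 3.0) < 0:
            frac = (3.0 - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    best = np.flatnonzero(np.abs(y - 3.0) == np.min(np.abs(y - 3.0)))
    return float(x[best[0]])


def match_hands(
    model_left: RatingModel,
    model_right: RatingModel,
    config: StaircaseConfig = StaircaseConfig(),
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Run both parts and return (intensity_left, intensity_right, full log).

    Part 1 selects the left-hand intensity against the maximum-power
    reference; part 2 selects the right-hand intensity against the left
    selection, with the same staircase mechanics.  The two parts use
    distinct seeded random interleavings.
    """
    left, log1 = run_double_staircase(model_left, config, seed=seed, part=1)
    right, log2 = run_double_staircase(model_right, config, seed=seed + 1, part=2)
    return left, right, pd.concat([log1, log2], ignore_index=True)
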