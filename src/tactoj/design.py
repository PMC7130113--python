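"""Trial-schedule construction for the tactile temporal-order-judgment task.

The task presents pairs of vibrotactile stimuli, one to each hand, separated
by a signed stimulus onset asynchrony (SOA).  Negative SOAs mean the left
hand was stimulated first, positive the right hand.  The main experiment
runs 4 blocks of 60 trials: each block contains each of the 10 SOA types
(±10, ±30, ±55, ±90, ±200 ms) exactly 6 times in seeded random order, and
arm posture (uncrossed / crossed over the body midline) alternates between
consecutive blocks.

Three practice blocks of increasing difficulty precede the main blocks:
8 single-stimulus localisation trials, then 12 and 18 order-judgment trials
restricted to the three largest |SOA| values (55, 90, 200 ms), the last
block with arms crossed.

Schedule generation is a pure function of its arguments: the same seed
yields a byte-identical schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

#: The ten SOA types of the main blocks, in ms (negative = left hand first).
SOA_LEVELS_MS: tuple[int, ...] = (-200, -90, -55, -30, -10, 10, 30, 55, 90, 200)

#: |SOA| values used in the paired practice trials (the three easiest levels).
PRACTICE_ABS_SOA_MS: tuple[int, ...] = (55, 90, 200)

#: The two arm postures.
POSTURES: tuple[str, str] = ("uncrossed", "crossed")

Posture = Literal["uncrossed", "crossed"]

#: Practice gate: minimum proportion correct at |SOA| = 200 ms required to
#: proceed from the last practice block to the experiment.
PRACTICE_GATE_PCT_CORRECT = 0.75

N_BLOCKS = 4
REPS_PER_SOA_PER_BLOCK = 6


def _check_posture(posture: str) -> str:
    if posture not in POSTURES:
        raise ValueError(f"posture must be one of {POSTURES}, got {posture!r}")
    return posture


@dataclass(frozen=True)
class Block:
    """One block: a posture and an ordered list of signed SOAs (ms)."""

    posture: str
    soa_ms: tuple[int, ...]

    @property
    def n_trials(self) -> int:
        return len(self.soa_ms)


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered list of blocks plus the seed that generated them."""

    blocks: tuple[Block, ...]
    seed: int
    start_posture: str = "uncrossed"

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        """Tidy long form: one row per trial (block, trial_index, posture, soa_ms)."""
        rows = [
            (bi + 1, ti + 1, b.posture, soa)
            for bi, b in enumerate(self.blocks)
            for ti, soa in enumerate(b.soa_ms)
        ]
        out = pd.DataFrame(rows, columns=["block", "trial_index", "posture", "soa_ms"])
        if subject_id is not None:
            out.insert(0, "subject_id", subject_id)
        return out


def build_trial_schedule(
    start_posture: Posture = "uncrossed",
    seed: int = 0,
    n_reps: int = REPS_PER_SOA_PER_BLOCK,
) -> TrialSchedule:
    """Build the 4-block main schedule.

    Parameters
    ----------
    start_posture
        Posture of the first block; posture alternates between blocks, so two
        blocks are run in each posture.
    seed
        Non-negative integer seeding the within-block shuffles.
    n_reps
        Repetitions of each SOA type per block (6 in the standard design,
        giving 60-trial blocks).  Exposed so estimator behaviour can be
        studied as a function of trials per SOA.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    _check_posture(start_posture)
    rng = np.random.default_rng(seed)
    base = np.repeat(SOA_LEVELS_MS, n_reps)
    blocks = []
    for bi in range(N_BLOCKS):
        posture = POSTURES[(POSTURES.index(start_posture) + bi) % 2]
        order = rng.permutation(base)
        blocks.append(Block(posture=posture, soa_ms=tuple(int(s) for s in order)))
    return TrialSchedule(blocks=tuple(blocks), seed=seed, start_posture=start_posture)


@dataclass(frozen=True)
class PracticeBlock:
    """One practice block.

    ``kind`` is ``"single"`` (localisation: one stimulus, ``hands`` gives the
    stimulated hand per trial) or ``"paired"`` (order judgment, ``soa_ms``
    gives signed SOAs per trial).
    """

    kind: Literal["single", "paired"]
    posture: str
    hands: tuple[str, ...] = field(default=())
    soa_ms: tuple[int, ...] = field(default=())

    @property
    def n_trials(self) -> int:
        return len(self.hands) if self.kind == "single" else len(self.soa_ms)


def build_practice_blocks(seed: int = 0) -> list[PracticeBlock]:
    """Build the three practice blocks (8, 12 and 18 trials).

    Block 1: single-stimulus localisation, 4 left + 4 right in random order.
    Block 2: 12 paired trials, |SOA| in {55, 90, 200} ms balanced (2 per
    signed level), arms uncrossed.
    Block 3: 18 such trials (3 per signed level), arms crossed.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)

    hands = np.array(["left"] * 4 + ["right"] * 4)
    block1 = PracticeBlock(
        kind="single", posture="uncrossed", hands=tuple(rng.permutation(hands))
    )

    signed = [s * a for a in PRACTICE_ABS_SOA_MS for s in (-1, 1)]
    paired = []
    for n_per_level, posture in ((2, "uncrossed"), (3, "crossed")):
        soas = rng.permutation(np.repeat(signed, n_per_level))
        paired.append(
            PracticeBlock(
                kind="paired",
                posture=posture,
                soa_ms=tuple(int(s) for s in soas),
            )
        )
    return [block1, *paired]
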