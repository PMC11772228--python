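"""Overlap-paradigm trial schedule.

The face-preference test presents a central stimulus (a face or a
luminance/colour-matched non-face pattern, 9.6 deg x 10.2 deg) followed,
after a 1000 ms stimulus-onset asynchrony, by a lateral checkerboard
distractor ~12 deg left or right of centre for 2000 ms.  An infant sees
4 blocks of 12 trials (48 trials).  Within every block the face / non-face
order is randomised under a 6/6 constraint, and the distractor side is
balanced (3 left / 3 right) within each block separately for the face and
the non-face trials.  Parent faces appear in blocks 2 and 3; two
unfamiliar adult faces in blocks 1 and 4.  Face trials cycle through
neutral, happy and fearful expressions (2 of each per block per class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_BLOCKS = 4
TRIALS_PER_BLOCK = 12
N_TRIALS = N_BLOCKS * TRIALS_PER_BLOCK

SOA_MS = 1000.0
DISTRACTOR_DURATION_MS = 2000.0
ANALYSIS_WINDOW_MS = (150.0, 1000.0)

# stimulus geometry, degrees of visual angle
CENTRAL_WIDTH_DEG = 9.6
CENTRAL_HEIGHT_DEG = 10.2
DISTRACTOR_ECCENTRICITY_DEG = 12.0

#: identity of the central face (and of the face each non-face pattern was
#: derived from) by block; the block order is fixed for every infant.
BLOCK_IDENTITY = ("unfamiliar", "parent", "parent", "unfamiliar")

CLASSES = ("face", "nonface")
EXPRESSIONS = ("neutral", "happy", "fearful")
SIDES = ("left", "right")


@dataclass
class TrialSchedule:
    """A single infant's 48-trial schedule plus paradigm timing."""

    trials: pd.DataFrame
    soa_ms: float = SOA_MS
    distractor_duration_ms: float = DISTRACTOR_DURATION_MS
    analysis_window_ms: tuple[float, float] = field(default=ANALYSIS_WINDOW_MS)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.trials)


def _schedule_arrays(rng: np.random.Generator, n: int):
    """Vectorised schedules for ``n`` infants.

    Returns (stimulus_class, identity, expression, distractor_side) as
    object arrays of shape (n, 48) honouring all balance constraints.
    """
    # face/nonface order: shuffle a fixed 6/6 template per (infant, block)
    base = np.array([0] * 6 + [1] * 6)  # 0=face, 1=nonface
    order = np.argsort(rng.random((n, N_BLOCKS, TRIALS_PER_BLOCK)), axis=-1)
    cls = base[order]  # (n, 4, 12)

    # stable sort puts the 6 face positions first, then the 6 nonface ones,
    # each group in order of appearance; scatter per-class attributes there
    pos = np.argsort(cls, axis=-1, kind="stable")

    def per_class_perm(template: np.ndarray) -> np.ndarray:
        """Independent shuffle of ``template`` per (infant, block, class)."""
        keys = rng.random((n, N_BLOCKS, 2, len(template)))
        return template[np.argsort(keys, axis=-1)]

    side_tpl = np.array([0, 0, 0, 1, 1, 1])  # 3 left / 3 right
    expr_tpl = np.array([0, 0, 1, 1, 2, 2])  # 2 of each expression
    sides_grouped = per_class_perm(side_tpl).reshape(n, N_BLOCKS, TRIALS_PER_BLOCK)
    exprs_grouped = per_class_perm(expr_tpl).reshape(n, N_BLOCKS, TRIALS_PER_BLOCK)

    sides = np.empty_like(sides_grouped)
    exprs = np.empty_like(exprs_grouped)
    np.put_along_axis(sides, pos, sides_grouped, axis=-1)
    np.put_along_axis(exprs, pos, exprs_grouped, axis=-1)

    cls = cls.reshape(n, N_TRIALS)
    sides = sides.reshape(n, N_TRIALS)
    exprs = exprs.reshape(n, N_TRIALS)
    identity = np.tile(np.repeat(np.array(BLOCK_IDENTITY), TRIALS_PER_BLOCK), (n, 1))
    return (
        np.array(CLASSES)[cls],
        identity,
        np.array(EXPRESSIONS)[exprs],
        np.array(SIDES)[sides],
    )


def _schedule_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cls, identity, expr, side = _schedule_arrays(rng, n)
    block = np.tile(np.repeat(np.arange(1, N_BLOCKS + 1), TRIALS_PER_BLOCK), n)
    trial_index = np.tile(np.arange(1, N_TRIALS + 1), n)
    return pd.DataFrame(
        {
            "block": block,
            "trial_index": trial_index,
            "stimulus_class": cls.ravel(),
            "identity": identity.ravel(),
            "expression": expr.ravel(),
            "distractor_side": side.ravel(),
        }
    )


def generate_trial_schedule(seed: int) -> TrialSchedule:
    """Generate one infant's randomised, balance-constrained schedule."""
    rng = np.random.default_rng(seed)
    return TrialSchedule(trials=_schedule_frame(rng, 1))
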