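"""Synthetic experiment schedules and ground-truth choice generators.

Replicates the block/trial structure of the magnitude-classification
experiments (ring size or beep pitch sorted into 2, 4 or 8 quantile-defined
classes, plus paired classification-scaling / classification-reproduction
designs) and generates choice sequences either from the Bayesian observers
or from probit agents with known, injected history effects -- so that every
analysis stage can be validated against a generator whose parameters are
exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidArgumentError, InvalidSpecError

__all__ = [
    "StimulusDistribution",
    "BlockSpec",
    "ExperimentSchedule",
    "AgentSpec",
    "make_schedule",
    "sample_stimuli",
    "class_of_stimulus",
    "probit_agent",
    "TEMPLATES",
]


@dataclass(frozen=True)
class StimulusDistribution:
    """The fixed normal population of stimulus magnitudes.

    ``mean`` is the class boundary (e.g. the 3-degree ring radius or the
    170 Hz pitch boundary); ``sd`` is the calibrated threshold SD.  Class
    boundaries at every granularity are quantiles of this distribution, so
    it fully determines the task's correct answers.
    """

    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.sd <= 0:
            raise InvalidArgumentError("stimulus SD must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n <= 0:
            raise InvalidArgumentError("n must be positive")
        return self.mean + self.sd * rng.standard_normal(n)

    def cdf(self, s):
        return norm.cdf((np.asarray(s, dtype=float) - self.mean) / self.sd)


@dataclass(frozen=True)
class BlockSpec:
    """One block: task pairing, granularity schedule and bookkeeping."""

    block_id: int
    tasks: tuple[str, ...]
    granularities: tuple[int, ...]      # one entry per trial
    n_trials: int
    modality: str = "ring"
    mode: str = "single"                # single | joint | pair
    hand: tuple[str, ...] | None = None
    iti: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ExperimentSchedule:
    blocks: tuple[BlockSpec, ...]
    stimulus_distribution: StimulusDistribution
    template: str = "custom"

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def trials_per_granularity(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for b in self.blocks:
            for g in b.granularities:
                out[g] = out.get(g, 0) + 1
        return out


def sample_stimuli(n: int, mean: float, sd: float, seed: int) -> np.ndarray:
    """I.i.d. normal stimulus magnitudes; identical seed, identical draw."""
    return StimulusDistribution(mean, sd).sample(n, np.random.default_rng(seed))


def class_of_stimulus(s, dist: StimulusDistribution, G: int):
    """True class of a stimulus: ceil(G * F(s)) with the half-open-(left]
    bin convention (F(s) = 0 maps to class 1)."""
    if G < 2:
        raise InvalidArgumentError("granularity must be at least 2")
    q = dist.cdf(s)
    cls = np.ceil(q * G).astype(int)
    cls = np.clip(cls, 1, G)
    if np.isscalar(s) or np.ndim(s) == 0:
        return int(cls)
    return cls


def _balanced_blockwise(levels: Sequence[int], n_blocks: int,
                        rng: np.random.Generator,
                        balanced: bool = True) -> list[int]:
    """Assign one granularity level per block.

    The printed per-level trial totals of the blocked experiments are exactly
    equal, so the default is a balanced random permutation (equal block
    counts per level); i.i.d. assignment is available for completeness.
    """
    if balanced:
        if n_blocks % len(levels):
            raise InvalidArgumentError(
                f"{n_blocks} blocks cannot be balanced over {levels}")
        seq = list(levels) * (n_blocks // len(levels))
        rng.shuffle(seq)
        return seq
    return [int(rng.choice(levels)) for _ in range(n_blocks)]


# default per-template stimulus populations; the absolute scale is
# immaterial downstream (regressors are standardized), the SD is chosen so
# that a sensory-noise-limited binary classifier is right about 9 times in
# 10 on stimuli from the extreme octiles
_RING = StimulusDistribution(3.0, 0.5)
_PITCH = StimulusDistribution(170.0, 10.0)
_UNIT = StimulusDistribution(0.0, 1.0)

TEMPLATES = ("exp1", "exp2", "exp3", "exp4", "exp5", "exp6", "exp7", "expS")


def make_schedule(template: str, seed: int = 0, balanced: bool = True,
                  stimulus_distribution: StimulusDistribution | None = None,
                  ) -> ExperimentSchedule:
    """Build the testing-phase block structure of a named experiment.

    Templates
    ---------
    exp1 / exp2
        21 blocks x 45 trials of ring (pitch) classification; block-wise
        granularity balanced over {2, 4, 8} -> exactly 315 trials per level.
    exp3
        Ring and pitch classification randomly interleaved across trials;
        granularity alternates between 2 and 4 block to block.
    exp4
        20 blocks x 50 trials; half the blocks fixed at G=2, half switching
        G between 2 and 8 from trial to trial.
    exp5 / exp6
        Paired trials (classification then scaling, or classification then
        reproduction); granularity 2 or 8 per block; 3 testing blocks x 35
        trial pairs per condition -> 105 testing trials per condition.
    exp7
        20 blocks x 50 trials; granularity alternates 2/4; modality fixed
        within a block and alternating between blocks; response hand drawn
        at random each trial.
    expS
        9 blocks x 33 trials; granularity random in {2, 8} per trial and
        inter-trial interval random in {short, long}.
    """
    rng = np.random.default_rng(seed)
    blocks: list[BlockSpec] = []
    if template in ("exp1", "exp2"):
        dist = stimulus_distribution or (_RING if template == "exp1" else _PITCH)
        modality = "ring" if template == "exp1" else "pitch"
        gs = _balanced_blockwise([2, 4, 8], 21, rng, balanced)
        for i, g in enumerate(gs):
            blocks.append(BlockSpec(i, ("classification",), (g,) * 45, 45,
                                    modality))
    elif template == "exp3":
        dist = stimulus_distribution or _RING
        for i in range(20):
            g = 2 if i % 2 == 0 else 4
            blocks.append(BlockSpec(i, ("classification",), (g,) * 50, 50,
                                    "interleaved"))
    elif template == "exp4":
        dist = stimulus_distribution or _RING
        kinds = _balanced_blockwise([0, 1], 20, rng, balanced)
        for i, varying in enumerate(kinds):
            if varying:
                start = int(rng.integers(2))
                gseq = tuple(2 if (t + start) % 2 == 0 else 8
                             for t in range(50))
            else:
                gseq = (2,) * 50
            blocks.append(BlockSpec(i, ("classification",), gseq, 50, "ring"))
    elif template in ("exp5", "exp6"):
        dist = stimulus_distribution or _RING
        conditions = [(g, second) for g in (2, 8)
                      for second in ("scaling", "reproduction")]
        order = [c for c in conditions for _ in range(3)]
        rng.shuffle(order)
        for i, (g, second) in enumerate(order):
            blocks.append(BlockSpec(i, ("classification", second),
                                    (g,) * 35, 35, "ring", mode="pair"))
    elif template == "exp7":
        dist = stimulus_distribution or _RING
        for i in range(20):
            g = 2 if i % 2 == 0 else 4
            modality = "ring" if (i // 2) % 2 == 0 else "pitch"
            hands = tuple(rng.choice(["left", "right"], size=50))
            blocks.append(BlockSpec(i, ("classification",), (g,) * 50, 50,
                                    modality, hand=hands))
    elif template == "expS":
        dist = stimulus_distribution or _UNIT
        for i in range(9):
            gseq = tuple(int(g) for g in rng.choice([2, 8], size=33))
            itis = tuple(rng.choice(["short", "long"], size=33))
            blocks.append(BlockSpec(i, ("classification",), gseq, 33, "disk",
                                    iti=itis))
    else:
        raise InvalidArgumentError(f"unknown template {template!r}")
    return ExperimentSchedule(tuple(blocks), dist, template)


# ---------------------------------------------------------------------------
# probit ground-truth agent


#: regressors the agent understands; betas apply to standardized stimulus
#: values, +/-1-coded binarized previous choice, and raw granularity codes
SUPPORTED_BETAS = (
    "intercept",
    "stimulus",
    "prev_choice",
    "prev_choice_x_G",
    "prev_stimulus",
    "prev_stimulus_x_G",
)


@dataclass(frozen=True)
class AgentSpec:
    """True effect sizes of a probit choice agent.

    The linear predictor is
    ``beta0 + b_s*z_t + b_c*x_{t-1} + b_cG*x_{t-1}*G' + b_ps*z_{t-1}
    + b_psG*z_{t-1}*G'`` where ``z`` is the z-scored stimulus, ``x`` the
    +/-1-coded binarized previous choice, and ``G'`` the granularity code of
    the previous trial.  The binary upper/lower-half outcome is drawn
    through the probit link; the within-half class is then assigned
    uniformly to reach the trial's granularity.
    """

    beta: dict = field(default_factory=dict)
    granularity_coding: dict | None = None   # level -> code
    seed: int = 0

    def __post_init__(self):
        for name in self.beta:
            if name not in SUPPORTED_BETAS:
                raise InvalidSpecError(f"unsupported beta {name!r}")
        for v in self.beta.values():
            if not np.isfinite(v):
                raise InvalidSpecError("betas must be finite")


_DEFAULT_GCODE = {2: 0.0, 4: 1.0, 8: 2.0}


def probit_agent(schedule: ExperimentSchedule, spec: AgentSpec,
                 participant: str = "agent") -> pd.DataFrame:
    """Generate a trial table from a probit agent with known history effects."""
    rng = np.random.default_rng(spec.seed)
    beta = {name: float(spec.beta.get(name, 0.0)) for name in SUPPORTED_BETAS}
    gcode = spec.granularity_coding or _DEFAULT_GCODE
    dist = schedule.stimulus_distribution
    rows = []
    counter = 0
    for block in schedule.blocks:
        stimuli = dist.sample(block.n_trials, rng)
        z = (stimuli - dist.mean) / dist.sd
        x_prev = 0.0
        z_prev = 0.0
        g_prev_code = 0.0
        have_history = False
        for t in range(block.n_trials):
            G = int(block.granularities[t])
            eta = beta["intercept"] + beta["stimulus"] * z[t]
            if have_history:
                eta += (beta["prev_choice"] * x_prev
                        + beta["prev_choice_x_G"] * x_prev * g_prev_code
                        + beta["prev_stimulus"] * z_prev
                        + beta["prev_stimulus_x_G"] * z_prev * g_prev_code)
            p_upper = norm.cdf(eta)
            upper = rng.random() < p_upper
            half = G // 2
            choice = int(rng.integers(half) + (half if upper else 0)) + 1
            rt = float(np.exp(rng.normal(-0.4 + 0.1 * np.log2(G), 0.3)))
            rows.append({
                "participant": participant,
                "trial": counter,
                "block": block.block_id,
                "trial_in_block": t,
                "task": "classification",
                "G": G,
                "stimulus": float(stimuli[t]),
                "choice": choice,
                "response": float(choice),
                "rt": rt,
                "modality": block.modality,
                "iti": block.iti[t] if block.iti is not None else None,
                "hand": block.hand[t] if block.hand is not None else None,
            })
            x_prev = 1.0 if upper else -1.0
            z_prev = float(z[t])
            g_prev_code = float(gcode.get(G, 0.0))
            have_history = True
            counter += 1
    return pd.DataFrame(rows)
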