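"""Bayesian observers with parallel belief updating in stimulus and DV spaces.

The standard observer maintains two prior beliefs that evolve independently
across trials:

* a Gaussian-dominated prior over raw stimulus magnitudes, attracted each
  trial toward a noisy memory of the previous stimulus; and
* a prior over the decision variable (DV) -- the stimulus's quantile within
  its population distribution, bounded in [0, 1] -- narrowed by each decision
  commitment to the chosen class's subinterval and blurred by a memory leak.

A trial proceeds by (i) sensing ``m_s ~ N(s, sigma_s)`` and inferring the
stimulus MAP ``s_hat`` under the current stimulus prior, (ii) mapping
``s_hat`` through the prior's CDF (probability integral transform) into a DV
measurement ``m_v``, (iii) inferring the DV MAP ``v_hat`` under the current
DV prior with the reflected-diffusion likelihood B(., sigma_v), and
(iv) answering the task: the class containing ``v_hat`` (classification),
``v_hat`` itself (scaling), or ``s_hat`` (reproduction).

Four variants remove or relocate parts of this machinery (sensory
adaptation; stimulus-prior updating by the stimulus or by the choice;
DV-prior updating only), each using the parameter subset that its internal
model requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beliefs import (
    DEFAULT_BOUND,
    DV_GRID_SIZE,
    STIM_GRID_SIZE,
    GridBelief,
    _npdf,
    bounded_density,
    dv_grid,
    dv_likelihood,
    gaussian_belief,
    leak_convolve,
    refine_argmax,
    stimulus_grid,
    uniform_dv_belief,
)
from .errors import (
    DegeneratePriorError,
    InvalidArgumentError,
    OutOfSupportError,
)

__all__ = [
    "VARIANTS",
    "VARIANT_PARAMS",
    "ObserverParams",
    "ObserverState",
    "TrialResponse",
    "infer_stimulus",
    "stimulus_to_dv_measurement",
    "infer_dv",
    "classify_dv",
    "update_stimulus_prior",
    "update_dv_prior",
    "adaptation_gain",
    "condition_stimulus_prior_on_choice",
    "initial_state",
    "run_trial",
    "simulate_session",
]

VARIANTS = (
    "standard",
    "sensory_adaptation",
    "stim_prior_by_stimulus",
    "stim_prior_by_choice",
    "dv_prior_by_choice",
)

#: free-parameter subset per variant (s0 and b are shared structural values)
VARIANT_PARAMS = {
    "standard": ("sigma_s0", "sigma_s", "sigma_mms", "sigma_leak", "sigma_v"),
    "sensory_adaptation": ("sigma_s0", "sigma_s", "g"),
    "stim_prior_by_stimulus": ("sigma_s0", "sigma_s", "sigma_mms"),
    "stim_prior_by_choice": ("sigma_s0", "sigma_s", "sigma_mms", "sigma_leak"),
    "dv_prior_by_choice": ("sigma_s0", "sigma_s", "sigma_leak", "sigma_v"),
}

_ALL_FREE = ("sigma_s0", "sigma_s", "sigma_mms", "sigma_leak", "sigma_v", "g")

TASKS = ("classification", "scaling", "reproduction")


@dataclass(frozen=True)
class ObserverParams:
    """Generative-model parameters of an observer variant.

    Attributes
    ----------
    s0, sigma_s0 : float
        Mean and SD of the base stimulus prior N(s0, sigma_s0).
    sigma_s : float
        Sensory-noise SD of the stimulus measurement.
    sigma_mms : float
        Memory-diffusion SD; the memory trace of a stimulus carries total
        noise ``sigma_s_prime = sqrt(sigma_s**2 + sigma_mms**2)``.
    sigma_v : float
        DV-measurement diffusion SD on the [0, 1] scale.
    sigma_leak : float
        SD of the Gaussian leak applied to a choice-conditioned prior.
    g : float
        Gain-suppression strength (sensory-adaptation variant only).
    b : float
        Effective bound of the DV construction space (fixed at 4).
    variant : str
        One of ``VARIANTS``; validation enforces that exactly the variant's
        parameter subset is supplied.
    """

    variant: str = "standard"
    s0: float = 0.0
    sigma_s0: float | None = None
    sigma_s: float | None = None
    sigma_mms: float | None = None
    sigma_leak: float | None = None
    sigma_v: float | None = None
    g: float | None = None
    b: float = DEFAULT_BOUND
    stim_update_mode: str = "one_back"      # or "recursive"
    dv_update_mode: str = "recursive"       # or "one_back"
    dv_likelihood_convention: str = "generative"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidArgumentError(f"unknown variant {self.variant!r}")
        needed = VARIANT_PARAMS[self.variant]
        for name in _ALL_FREE:
            val = getattr(self, name)
            if name in needed:
                if val is None:
                    raise InvalidArgumentError(
                        f"variant {self.variant!r} requires {name}")
                if not np.isfinite(val) or (val <= 0 and name != "g") or (
                        name == "g" and val < 0):
                    raise InvalidArgumentError(f"invalid value for {name}: {val}")
            elif val is not None:
                raise InvalidArgumentError(
                    f"variant {self.variant!r} does not use {name}")
        if self.stim_update_mode not in ("one_back", "recursive"):
            raise InvalidArgumentError("stim_update_mode must be one_back|recursive")
        if self.dv_update_mode not in ("recursive", "one_back"):
            raise InvalidArgumentError("dv_update_mode must be recursive|one_back")

    @property
    def sigma_s_prime(self) -> float:
        """Combined sensory + memory diffusion SD of the memory trace."""
        if self.sigma_mms is None:
            raise InvalidArgumentError(
                f"variant {self.variant!r} has no memory diffusion")
        return math.sqrt(self.sigma_s ** 2 + self.sigma_mms ** 2)

    @property
    def updates_stimulus_prior(self) -> bool:
        return self.variant in ("standard", "stim_prior_by_stimulus",
                                "stim_prior_by_choice")

    @property
    def updates_dv_prior(self) -> bool:
        return self.variant in ("standard", "dv_prior_by_choice")

    @property
    def infers_dv(self) -> bool:
        """Whether the variant runs probabilistic inference in DV space."""
        return self.variant in ("standard", "dv_prior_by_choice")


@dataclass
class ObserverState:
    """Per-trial evolving beliefs and history carried by an observer."""

    stimulus_prior: GridBelief
    dv_prior: GridBelief
    last_memory_measurement: float | None = None
    last_stimulus_measurement: float | None = None
    last_choice: tuple[int, int] | None = None   # (class, G)


@dataclass(frozen=True)
class TrialResponse:
    """Internal quantities and the emitted report of one trial."""

    task: str
    s_hat: float
    m_s: float
    m_v: float
    v_hat: float | None
    choice_class: int | None
    report: float


def initial_state(params: ObserverParams,
                  n_stim_grid: int = STIM_GRID_SIZE,
                  n_dv_grid: int = DV_GRID_SIZE) -> ObserverState:
    """Fresh state: base stimulus prior N(s0, sigma_s0), uniform DV prior."""
    grid = stimulus_grid(params.s0, params.sigma_s0, n_stim_grid)
    return ObserverState(
        stimulus_prior=gaussian_belief(params.s0, params.sigma_s0, grid),
        dv_prior=uniform_dv_belief(n_dv_grid),
    )


# ---------------------------------------------------------------------------
# inference operations


def infer_stimulus(m_s: float, stimulus_prior: GridBelief, sigma_s: float,
                   gain: np.ndarray | None = None) -> float:
    """MAP stimulus estimate: argmax of N(m_s; s, sigma_s) * prior(s).

    The grid argmax is refined by quadratic interpolation; for conjugate
    Gaussian inputs the result matches the closed-form posterior mode to
    well below one grid step.  ``gain`` optionally modulates the likelihood
    (sensory adaptation).
    """
    if not np.isfinite(m_s):
        raise InvalidArgumentError("m_s must be finite")
    grid = stimulus_prior.support
    if not grid[0] <= m_s <= grid[-1]:
        raise OutOfSupportError(f"measurement {m_s} outside belief support")
    like = _npdf(grid, m_s, sigma_s)
    if gain is not None:
        like = like * gain
    return refine_argmax(grid, like * stimulus_prior.density)


def stimulus_to_dv_measurement(s_hat: float,
                               stimulus_prior: GridBelief) -> float:
    """Probability integral transform: the prior's CDF at ``s_hat``."""
    return stimulus_prior.cdf_at(s_hat)


def infer_dv(m_v: float, dv_prior: GridBelief, sigma_v: float,
             convention: str = "generative", b: float = DEFAULT_BOUND) -> float:
    """MAP DV estimate under the reflected-diffusion likelihood."""
    if not 0.0 <= m_v <= 1.0:
        raise InvalidArgumentError("m_v must lie in [0, 1]")
    like = dv_likelihood(m_v, sigma_v, grid=dv_prior.support, b=b,
                         convention=convention)
    return refine_argmax(dv_prior.support, like * dv_prior.density,
                         lo=0.0, hi=1.0)


def classify_dv(v_hat: float, G: int) -> int:
    """Class k with (k-1)/G < v_hat <= k/G; v_hat = 0 maps to class 1."""
    if G < 2:
        raise InvalidArgumentError("granularity must be at least 2")
    if not 0.0 <= v_hat <= 1.0:
        raise InvalidArgumentError("v_hat must lie in [0, 1]")
    return min(G, max(1, int(math.ceil(v_hat * G))))


# ---------------------------------------------------------------------------
# belief-updating operations


def update_stimulus_prior(state: ObserverState, mm: float,
                          sigma_s_prime: float,
                          mode: str = "one_back",
                          base_prior: GridBelief | None = None) -> GridBelief:
    """Attract the stimulus prior toward the memory trace ``mm``.

    ``one_back`` multiplies the *base* prior by the memory likelihood
    N(mm, sigma_s_prime) -- each trial's prior reflects only the single most
    recent stimulus.  ``recursive`` chains the update onto the current prior,
    which sharpens it without bound over a long session.
    """
    if not np.isfinite(mm):
        raise InvalidArgumentError("mm must be finite")
    if sigma_s_prime <= 0:
        raise InvalidArgumentError("sigma_s_prime must be positive")
    if mode == "one_back":
        if base_prior is None:
            raise InvalidArgumentError("one_back mode needs the base prior")
        prior = base_prior
    elif mode == "recursive":
        prior = state.stimulus_prior
    else:
        raise InvalidArgumentError(f"unknown update mode {mode!r}")
    like = _npdf(prior.support, mm, sigma_s_prime)
    return GridBelief(prior.support, prior.density * like,
                      "stimulus").normalized()


def update_dv_prior(dv_prior: GridBelief, choice: int, G: int,
                    sigma_leak: float) -> GridBelief:
    """Condition the DV prior on a committed class, then leak.

    The prior is masked to the chosen bin [(choice-1)/G, choice/G],
    renormalized, convolved with N(0, sigma_leak) and folded back into
    [0, 1].
    """
    if G < 2 or not 1 <= choice <= G:
        raise InvalidArgumentError(f"choice {choice} incompatible with G={G}")
    lo, hi = (choice - 1) / G, choice / G
    grid = dv_prior.support
    mask = (grid >= lo - 1e-12) & (grid <= hi + 1e-12)
    masked = np.where(mask, dv_prior.density, 0.0)
    if np.trapezoid(masked, grid) <= 0:
        raise DegeneratePriorError(
            f"no prior mass in the chosen bin [{lo}, {hi}]")
    conditioned = GridBelief(grid, masked, "dv").normalized()
    return leak_convolve(conditioned, sigma_leak, fold=True)


def adaptation_gain(grid: np.ndarray, m_s_prev: float, g: float,
                    sigma_s: float) -> np.ndarray:
    """Suppressed-gain profile f_s(x) = 1 - g * N(x; m_s_prev, sigma_s).

    Multiplying the stimulus likelihood by this profile dents it around the
    previous measurement.  The profile is clamped at 0 from below, since for
    small sigma_s the subtracted density can exceed 1.
    """
    if g < 0:
        raise InvalidArgumentError("gain strength g must be nonnegative")
    return np.maximum(0.0, 1.0 - g * _npdf(grid, m_s_prev, sigma_s))


def condition_stimulus_prior_on_choice(stimulus_prior_updated: GridBelief,
                                       choice: int, G: int,
                                       sigma_leak: float) -> GridBelief:
    """Mask the stimulus prior to its own inter-quantile choice interval.

    The interval is [Q((choice-1)/G), Q(choice/G)] where Q is the quantile
    function of the updated prior itself; after masking and renormalizing,
    the prior is blurred with N(0, sigma_leak) (no folding -- stimulus space
    is unbounded).
    """
    if G < 2 or not 1 <= choice <= G:
        raise InvalidArgumentError(f"choice {choice} incompatible with G={G}")
    prior = stimulus_prior_updated
    lo = prior.quantile((choice - 1) / G)
    hi = prior.quantile(choice / G)
    mask = (prior.support >= lo) & (prior.support <= hi)
    masked = np.where(mask, prior.density, 0.0)
    if np.trapezoid(masked, prior.support) <= 0:
        raise DegeneratePriorError(
            f"zero-mass quantile interval [{lo:.4g}, {hi:.4g}]")
    conditioned = GridBelief(prior.support, masked, "stimulus").normalized()
    return leak_convolve(conditioned, sigma_leak, fold=False)


# ---------------------------------------------------------------------------
# trial execution


def _observe(state: ObserverState, params: ObserverParams, stimulus: float,
             rng: np.random.Generator):
    """Sense a stimulus and run the variant's inference chain."""
    m_s = float(stimulus + params.sigma_s * rng.standard_normal())
    grid = state.stimulus_prior.support
    m_s = float(np.clip(m_s, grid[0], grid[-1]))
    gain = None
    if params.variant == "sensory_adaptation" and \
            state.last_stimulus_measurement is not None:
        gain = adaptation_gain(grid, state.last_stimulus_measurement,
                               params.g, params.sigma_s)
    s_hat = infer_stimulus(m_s, state.stimulus_prior, params.sigma_s, gain=gain)
    m_v = stimulus_to_dv_measurement(s_hat, state.stimulus_prior)
    if params.infers_dv:
        v_hat = infer_dv(m_v, state.dv_prior, params.sigma_v,
                         convention=params.dv_likelihood_convention,
                         b=params.b)
    else:
        # no informative DV prior: the DV estimate is the measurement itself
        v_hat = m_v
    return m_s, s_hat, m_v, v_hat


def _commit_updates(state: ObserverState, params: ObserverParams,
                    stimulus: float, m_s: float, choice: int | None, G: int,
                    base_prior: GridBelief,
                    rng: np.random.Generator) -> ObserverState:
    """Post-response belief updates; ``choice`` is None when no commitment
    occurred this trial (scaling/reproduction-only trials)."""
    stim_prior = state.stimulus_prior
    dv_prior = state.dv_prior
    mm = state.last_memory_measurement
    if params.updates_stimulus_prior:
        mm = float(stimulus + params.sigma_s_prime * rng.standard_normal())
        stim_prior = update_stimulus_prior(
            state, mm, params.sigma_s_prime, mode=params.stim_update_mode,
            base_prior=base_prior)
        if params.variant == "stim_prior_by_choice" and choice is not None:
            stim_prior = condition_stimulus_prior_on_choice(
                stim_prior, choice, G, params.sigma_leak)
    if params.updates_dv_prior and choice is not None:
        prior = dv_prior if params.dv_update_mode == "recursive" \
            else uniform_dv_belief(dv_prior.support.size)
        dv_prior = update_dv_prior(prior, choice, G, params.sigma_leak)
    return ObserverState(
        stimulus_prior=stim_prior,
        dv_prior=dv_prior,
        last_memory_measurement=mm,
        last_stimulus_measurement=m_s,
        last_choice=(choice, G) if choice is not None else state.last_choice,
    )


def run_trial(state: ObserverState, params: ObserverParams, stimulus: float,
              task: str, G: int, rng: np.random.Generator,
              base_prior: GridBelief | None = None):
    """Execute one trial: observe, respond, update beliefs.

    Returns ``(TrialResponse, new_state)``.  Belief conditioning on the
    committed class happens only on classification trials; scaling and
    reproduction trials read the DV prior without conditioning it.
    """
    if task not in TASKS:
        raise InvalidArgumentError(f"unknown task {task!r}")
    if base_prior is None:
        base_prior = gaussian_belief(params.s0, params.sigma_s0,
                                     state.stimulus_prior.support)
    m_s, s_hat, m_v, v_hat = _observe(state, params, stimulus, rng)
    choice = None
    if task == "classification":
        choice = classify_dv(v_hat, G)
        report = float(choice)
    elif task == "scaling":
        report = v_hat
    else:
        report = s_hat
    response = TrialResponse(task=task, s_hat=s_hat, m_s=m_s, m_v=m_v,
                             v_hat=v_hat if task != "reproduction" else v_hat,
                             choice_class=choice, report=report)
    new_state = _commit_updates(state, params, stimulus, m_s, choice, G,
                                base_prior, rng)
    return response, new_state


def simulate_session(params: ObserverParams, schedule, seed: int,
                     n_stim_grid: int = STIM_GRID_SIZE,
                     n_dv_grid: int = DV_GRID_SIZE) -> pd.DataFrame:
    """Run an observer through an experiment schedule.

    ``schedule`` is a :class:`~dvbelief.synth.ExperimentSchedule`.  The state
    is reset at the start of every block (blocks differ in instructions and
    granularity, so history never crosses a block boundary).  The same
    ``(params, schedule, seed)`` triple always reproduces the identical
    trial table.

    Blocks whose task tuple contains several tasks are run in ``joint`` mode:
    one stimulus per trial, with every listed task answered from the same
    internal states and the classification commitment driving the belief
    updates (extra columns ``scaling_response``/``reproduction_response``).
    ``pair`` mode (two independently drawn stimuli per trial, classification
    on the first, the partner task on the second) mirrors the paired-trial
    experiment designs and is selected by ``schedule.pairing``.
    """
    rng = np.random.default_rng(seed)
    base_prior = None
    rows = []
    trial_counter = 0
    for block in schedule.blocks:
        state = initial_state(params, n_stim_grid, n_dv_grid)
        if base_prior is None:
            base_prior = gaussian_belief(params.s0, params.sigma_s0,
                                         state.stimulus_prior.support)
        g_seq = block.granularities
        stimuli = schedule.stimulus_distribution.sample(
            block.n_trials * (2 if block.mode == "pair" else 1), rng)
        for t in range(block.n_trials):
            G = int(g_seq[t])
            if block.mode == "pair":
                s_cls, s_second = float(stimuli[2 * t]), float(stimuli[2 * t + 1])
                resp, state = run_trial(state, params, s_cls,
                                        "classification", G, rng, base_prior)
                second_task = [tk for tk in block.tasks
                               if tk != "classification"][0]
                resp2, state = run_trial(state, params, s_second,
                                         second_task, G, rng, base_prior)
                rows.append(_row(trial_counter, block, t, G, s_cls, resp,
                                 second=(second_task, s_second, resp2),
                                 seed=seed))
            elif len(block.tasks) > 1:
                s = float(stimuli[t])
                m_s, s_hat, m_v, v_hat = _observe(state, params, s, rng)
                choice = classify_dv(v_hat, G) \
                    if "classification" in block.tasks else None
                resp = TrialResponse(task="classification", s_hat=s_hat,
                                     m_s=m_s, m_v=m_v, v_hat=v_hat,
                                     choice_class=choice,
                                     report=float(choice) if choice else v_hat)
                state = _commit_updates(state, params, s, m_s, choice, G,
                                        base_prior, rng)
                rows.append(_row(trial_counter, block, t, G, s, resp,
                                 joint=True, seed=seed))
            else:
                s = float(stimuli[t])
                resp, state = run_trial(state, params, s, block.tasks[0], G,
                                        rng, base_prior)
                rows.append(_row(trial_counter, block, t, G, s, resp,
                                 seed=seed))
            trial_counter += 1
    return pd.DataFrame(rows)


def _row(counter, block, t, G, stimulus, resp: TrialResponse,
         second=None, joint=False, seed=None):
    row = {
        "trial": counter,
        "block": block.block_id,
        "trial_in_block": t,
        "task": resp.task,
        "G": G,
        "stimulus": stimulus,
        "m_s": resp.m_s,
        "s_hat": resp.s_hat,
        "m_v": resp.m_v,
        "v_hat": resp.v_hat,
        "choice": resp.choice_class,
        "report": resp.report,
        "modality": block.modality,
        "seed": seed,
    }
    if joint:
        row["scaling_response"] = resp.v_hat
        row["reproduction_response"] = resp.s_hat
    if second is not None:
        task2, s2, resp2 = second
        row["second_task"] = task2
        row["second_stimulus"] = s2
        row["second_report"] = resp2.report
    return row
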