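"""Choice-conditioned distributions and KL-divergence history measures.

For each state of the current choice, the distributions of the previous
choice, the previous stimulus and the current stimulus are estimated while
conditioning concurrently on the other history variables, and their
Kullback-Leibler divergence from the uniform distribution quantifies how
much each variable constrains the current choice.  Dividing the previous-
choice and previous-stimulus divergences by the current-stimulus divergence
yields a normalized influence measure: 0 means no influence, 1 an influence
as strong as the current stimulus itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "ConditionalTable",
    "KLResult",
    "bin_values",
    "build_conditional_table",
    "conditional_distribution",
    "kl_from_uniform",
    "normalized_history_kl",
]

_TARGET_AXES = {"current_choice": 0, "current_stimulus": 1,
                "prev_choice": 2, "prev_stimulus": 3}


def bin_values(values, n_bins: int = 8) -> np.ndarray:
    """Equal-probability (quantile) bins of the pooled sample; indices 1..n."""
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be at least 2")
    values = np.asarray(values, dtype=float)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size - 1 < n_bins:
        # massive ties collapse quantile edges; fall back to the distinct
        # values (identity mapping for already-discrete data)
        idx = np.searchsorted(edges[1:-1], values, side="left") + 1
        return idx
    idx = np.searchsorted(edges[1:-1], values, side="left") + 1
    return np.clip(idx, 1, n_bins)


@dataclass
class ConditionalTable:
    """4-way contingency of (current choice, current stimulus bin,
    previous choice, previous stimulus bin)."""

    counts: np.ndarray          # shape (n_ct, n_st, n_ct, n_st)
    n_ct: int
    n_st: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 4:
            raise InvalidArgumentError("counts must be a 4-way table")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be nonnegative")


def build_conditional_table(trials: pd.DataFrame, G: int,
                            n_stim_bins: int = 8) -> ConditionalTable:
    """Tabulate consecutive same-block classification trials of one G."""
    sub = trials[(trials["G"] == G) & trials["choice"].notna()]
    if sub.empty:
        raise InsufficientDataError(f"no trials at G={G}")
    counts = np.zeros((G, n_stim_bins, G, n_stim_bins), dtype=int)
    sbin_all = bin_values(sub["stimulus"].to_numpy(), n_stim_bins)
    sub = sub.assign(_sbin=sbin_all)
    group_cols = ["block"]
    if "participant" in sub.columns:
        group_cols = ["participant", "block"]
    for _, grp in sub.groupby(group_cols, sort=False):
        ct = grp["choice"].to_numpy(dtype=int)
        sb = grp["_sbin"].to_numpy(dtype=int)
        for t in range(1, len(grp)):
            counts[ct[t] - 1, sb[t] - 1, ct[t - 1] - 1, sb[t - 1] - 1] += 1
    return ConditionalTable(counts, n_ct=G, n_st=n_stim_bins)


def conditional_distribution(table: ConditionalTable, target: str,
                             current_choice_state: int) -> np.ndarray:
    """p(target | current choice = k), averaged over conditioning cells.

    Within every occupied cell of the two non-target history variables the
    conditional distribution of the target is formed; these conditionals are
    then averaged uniformly over the occupied cells and renormalized (empty
    cells are skipped -- their conditionals are undefined).
    """
    if target not in ("prev_choice", "prev_stimulus", "current_stimulus"):
        raise InvalidArgumentError(f"unknown target {target!r}")
    k = current_choice_state
    if not 1 <= k <= table.n_ct:
        raise InvalidArgumentError(f"choice state {k} outside 1..{table.n_ct}")
    slice_k = table.counts[k - 1]          # axes: (st, ct-1, st-1)
    if slice_k.sum() == 0:
        raise InsufficientDataError(f"no trials with current choice {k}")
    t_ax = {"current_stimulus": 0, "prev_choice": 1, "prev_stimulus": 2}[target]
    moved = np.moveaxis(slice_k, t_ax, 0)   # (target, cond1, cond2)
    flat = moved.reshape(moved.shape[0], -1).astype(float)
    cell_totals = flat.sum(axis=0)
    occupied = cell_totals > 0
    conds = flat[:, occupied] / cell_totals[occupied]
    p = conds.mean(axis=1)
    return p / p.sum()


def kl_from_uniform(p) -> float:
    """KL(p || uniform) = sum p log(p K), with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise InvalidArgumentError("probabilities must be nonnegative")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-8):
        raise InvalidArgumentError("probability vector must sum to 1")
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] * p.size)))


@dataclass
class KLResult:
    """Per-current-choice-state history KL measures at one granularity."""

    G: int
    kl_current_stimulus: np.ndarray
    kl_prev_choice: np.ndarray
    kl_prev_stimulus: np.ndarray
    normalized_prev_choice: np.ndarray
    normalized_prev_stimulus: np.ndarray
    degenerate: np.ndarray      # states where KL(s_t | ct=k) = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "G": self.G,
            "choice_state": np.arange(1, self.kl_prev_choice.size + 1),
            "kl_current_stimulus": self.kl_current_stimulus,
            "kl_prev_choice": self.kl_prev_choice,
            "kl_prev_stimulus": self.kl_prev_stimulus,
            "normalized_prev_choice": self.normalized_prev_choice,
            "normalized_prev_stimulus": self.normalized_prev_stimulus,
        })


def normalized_history_kl(trials: pd.DataFrame, G: int,
                          n_stim_bins: int = 8) -> KLResult:
    """History-effect strength per current-choice state, on the scale of
    the current stimulus's own influence."""
    table = build_conditional_table(trials, G, n_stim_bins)
    n = table.n_ct
    kl_st = np.full(n, np.nan)
    kl_c = np.full(n, np.nan)
    kl_s = np.full(n, np.nan)
    for k in range(1, n + 1):
        try:
            kl_st[k - 1] = kl_from_uniform(
                conditional_distribution(table, "current_stimulus", k))
            kl_c[k - 1] = kl_from_uniform(
                conditional_distribution(table, "prev_choice", k))
            kl_s[k - 1] = kl_from_uniform(
                conditional_distribution(table, "prev_stimulus", k))
        except InsufficientDataError:
            continue
    degenerate = kl_st == 0
    denom = np.where(degenerate, np.nan, kl_st)
    return KLResult(
        G=G,
        kl_current_stimulus=kl_st,
        kl_prev_choice=kl_c,
        kl_prev_stimulus=kl_s,
        normalized_prev_choice=kl_c / denom,
        normalized_prev_stimulus=kl_s / denom,
        degenerate=degenerate,
    )
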