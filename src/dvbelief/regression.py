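"""Choice-history regressions with orthogonally decomposed choice codes.

The regressand is the binarized current choice (or a continuous scaling /
reproduction response); the regressors are the previous choices decomposed
into up to three ordered binary components -- halves, quarters-within-halves,
eighths-within-quarters -- so that the first-order component measures the
previous-choice influence on a footing comparable across granularities,
together with previous stimuli, the current stimulus, and interactions with
granularity codes, response times and inter-trial interval.  Non-interaction
regressors are standardized to mean 0 / SD 1 within each block; interaction
columns are products of the standardized factors with the (unstandardized)
granularity or ITI codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateColumnError,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidSpecError,
)

__all__ = [
    "DesignSpec",
    "PRESETS",
    "HistoryDesign",
    "RegressionResult",
    "PsychometricSummary",
    "decompose_choice",
    "code_granularity",
    "standardize_blockwise",
    "build_design_matrix",
    "fit_history_model",
    "fdr_adjust",
    "individual_level_tests",
    "psychometric_summary",
]

_G_CODES = {
    "three_level": {2: 0.0, 4: 1.0, 8: 2.0},
    "binary": {2: 0.0, 8: 1.0},
    "iti": {"short": -0.5, "long": 0.5},
}


def decompose_choice(choice: int, G: int) -> tuple[int, int, int]:
    """Ordered binary decomposition of a class among G.

    The code is the binary expansion of ``choice - 1`` over log2(G) bits,
    most-significant bit first, zero-padded in the trailing positions: the
    first component says which half the choice fell in, the second which
    half within that half, the third which half within that quarter.
    """
    if G < 2 or (G & (G - 1)) != 0:
        raise InvalidArgumentError("G must be a power of two >= 2")
    if not 1 <= choice <= G:
        raise InvalidArgumentError(f"choice {choice} outside 1..{G}")
    nbits = G.bit_length() - 1
    bits = [(choice - 1) >> (nbits - 1 - k) & 1 for k in range(nbits)]
    return tuple(bits + [0] * (3 - nbits))[:3]


def code_granularity(values, scheme: str):
    """Map granularity levels (or ITI labels) to their regression codes."""
    if scheme not in _G_CODES:
        raise InvalidArgumentError(f"unknown coding scheme {scheme!r}")
    table = _G_CODES[scheme]
    out = []
    for v in values:
        if v not in table:
            raise InvalidArgumentError(
                f"value {v!r} outside the domain of scheme {scheme!r}")
        out.append(table[v])
    return np.asarray(out, dtype=float)


def standardize_blockwise(values, blocks, ddof: int = 1,
                          name: str = "column") -> np.ndarray:
    """Standardize to mean 0 / SD 1 within each block (sample SD)."""
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    out = np.empty_like(values)
    for b in pd.unique(blocks):
        idx = blocks == b
        v = values[idx]
        sd = v.std(ddof=ddof) if v.size > ddof else 0.0
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateColumnError(name, block=b)
        out[idx] = (v - v.mean()) / sd
    return out


def _standardize_tolerant(values, blocks, ddof: int = 1) -> np.ndarray:
    """Blockwise standardization that centres (to zero) columns constant
    within a block instead of raising -- needed for higher-order choice
    codes, which are identically zero in coarse-granularity blocks."""
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    out = np.empty_like(values)
    for b in pd.unique(blocks):
        idx = blocks == b
        v = values[idx]
        sd = v.std(ddof=ddof) if v.size > ddof else 0.0
        if sd == 0 or not np.isfinite(sd):
            out[idx] = 0.0
        else:
            out[idx] = (v - v.mean()) / sd
    return out


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of a history regression.

    ``granularity_target`` chooses whether interactions carry the previous
    or the current trial's granularity code.  The reducible interaction of
    the third-order choice code with granularity is always dropped; under
    the binary coding with a current-trial target the second-order
    interaction is dropped as well.
    """

    response: str = "choice"             # choice | scaling | reproduction
    max_lag: int = 1
    include_rt_prev: bool = False
    include_rt_cur: bool = False
    include_iti: bool = False
    include_granularity: bool = True
    granularity_scheme: str = "three_level"
    granularity_target: str = "current"  # current | previous
    current_g_filter: int | None = None
    name: str = "custom"

    def __post_init__(self):
        if self.response not in ("choice", "scaling", "reproduction"):
            raise InvalidSpecError(f"unknown response {self.response!r}")
        if self.granularity_target not in ("current", "previous"):
            raise InvalidSpecError("granularity_target must be current|previous")
        if self.max_lag < 1:
            raise InvalidSpecError("max_lag must be >= 1")

    @property
    def link(self) -> str:
        return "linear" if self.response == "reproduction" else "probit"

    @property
    def drop_c2_x_g(self) -> bool:
        return (self.include_granularity
                and self.granularity_scheme == "binary"
                and self.granularity_target == "current")


PRESETS: dict[str, DesignSpec] = {
    "eq1": DesignSpec("choice", 10, True, True, name="eq1"),
    "eq1_lag7": DesignSpec("choice", 7, True, True, name="eq1_lag7"),
    "eq1_lag1": DesignSpec("choice", 1, True, True, name="eq1_lag1"),
    "eq2": DesignSpec("choice", 1, True, True,
                      granularity_scheme="binary",
                      granularity_target="previous", name="eq2"),
    "eq2_current": DesignSpec("choice", 1, True, True,
                              granularity_scheme="binary",
                              granularity_target="current",
                              name="eq2_current"),
    "eq3": DesignSpec("reproduction", 1, True, False,
                      granularity_scheme="binary",
                      granularity_target="previous", name="eq3"),
    "eq3_scaling": DesignSpec("scaling", 1, True, False,
                              granularity_scheme="binary",
                              granularity_target="previous",
                              name="eq3_scaling"),
    "eq4": DesignSpec("choice", 1, True, True, include_granularity=False,
                      name="eq4"),
    "eq5": DesignSpec("choice", 1, True, True, include_iti=True,
                      granularity_scheme="binary",
                      granularity_target="previous", name="eq5"),
    # response-time-free forms used for simulated observers (they produce
    # no response times), restricted to current-granularity-2 trials
    "eq2_sim": DesignSpec("choice", 1, granularity_scheme="binary",
                          granularity_target="previous",
                          current_g_filter=2, name="eq2_sim"),
    "eq3_sim": DesignSpec("reproduction", 1, granularity_scheme="binary",
                          granularity_target="previous",
                          current_g_filter=2, name="eq3_sim"),
    "eq3_sim_scaling": DesignSpec("scaling", 1, granularity_scheme="binary",
                                  granularity_target="previous",
                                  current_g_filter=2, name="eq3_sim_scaling"),
}


@dataclass
class HistoryDesign:
    """Assembled regression problem: regressand, columns, and row metadata."""

    y: np.ndarray
    X: pd.DataFrame
    spec: DesignSpec
    meta: pd.DataFrame
    dropped_columns: list = field(default_factory=list)

    @property
    def column_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_obs(self) -> int:
        return int(self.y.size)

    def counts(self) -> dict[str, int]:
        """Coefficient counts under the different tallying conventions."""
        cols = self.column_names
        history = [c for c in cols
                   if c.startswith(("c1_", "c2_", "c3_", "s_l"))]
        return {
            "total": len(cols),
            "non_intercept": len(cols) - ("const" in cols),
            "history": len(history),
        }


@dataclass
class RegressionResult:
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    q_values: pd.Series
    model_tag: str
    n_obs: int
    fitted: object = field(default=None, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.fitted.predict(X))


def _resolve_response(df: pd.DataFrame, response: str) -> pd.Series:
    """Locate the regressand column for non-choice responses across the
    three trial-table dialects (single-task, joint, paired)."""
    joint_col = f"{response}_response"
    if joint_col in df.columns:
        return df[joint_col]
    if "second_task" in df.columns:
        return df["second_report"].where(df["second_task"] == response)
    if "task" in df.columns:
        col = "response" if "response" in df.columns else "report"
        return df[col].where(df["task"] == response)
    raise InvalidSpecError(
        f"cannot locate a {response!r} response in the trial table")


def build_design_matrix(trials: pd.DataFrame, spec: DesignSpec,
                        ) -> HistoryDesign:
    """Assemble the decomposed, standardized history design matrix.

    Trials must be sorted within participant x block; history regressors use
    only same-block predecessors, and the first ``max_lag`` trials of each
    block (or trials whose lag window contains a missing choice) serve only
    as history.
    """
    df = trials.copy()
    if "participant" not in df.columns:
        df["participant"] = "pooled"
    paired = "second_task" in df.columns
    if paired and spec.max_lag != 1:
        raise InvalidSpecError("paired-trial tables support max_lag=1 only")
    if (spec.include_rt_prev or spec.include_rt_cur) and \
            ("rt" not in df.columns or df["rt"].isna().all()):
        raise InvalidSpecError(
            "response-time interactions requested but the trial table has "
            "no response times (simulated observers do not produce them)")
    if spec.include_iti and ("iti" not in df.columns or df["iti"].isna().all()):
        raise InvalidSpecError("ITI interactions requested without ITI data")

    parts = []
    for (_, _), grp in df.groupby(["participant", "block"], sort=False):
        parts.append(_block_frame(grp, spec, paired))
    base = pd.concat(parts, ignore_index=True)
    base = base.dropna(subset=[c for c in base.columns
                               if c.startswith("_raw_") or c == "_y"])
    if spec.current_g_filter is not None:
        base = base[base["_G_cur"] == spec.current_g_filter]
    if base.empty:
        raise InsufficientDataError("no usable rows after history trimming")

    blocks = base["_blockkey"].to_numpy()
    std = {}
    for col in base.columns:
        if col.startswith("_raw_"):
            std[col[5:]] = _standardize_tolerant(base[col].to_numpy(), blocks)
    y = base["_y"].to_numpy(dtype=float)
    if spec.response == "reproduction":
        y = _standardize_tolerant(y, blocks)

    gcol = "_gcode_prev" if spec.granularity_target == "previous" \
        else "_gcode_cur"
    gcode = base[gcol].to_numpy(dtype=float)
    tcode = base["_iti_code"].to_numpy(dtype=float) if spec.include_iti \
        else None

    X = {}

    def add_factor(stem: str, vals: np.ndarray, rt_prev_col: str | None,
                   drop_g: bool = False):
        X[stem] = vals
        if spec.include_granularity and not drop_g:
            X[f"{stem}xG"] = vals * gcode
        if spec.include_rt_prev and rt_prev_col is not None:
            X[f"{stem}xRTprev"] = vals * std[rt_prev_col]
        if spec.include_rt_cur:
            X[f"{stem}xRTcur"] = vals * std["rt_cur"]
        if tcode is not None:
            X[f"{stem}xT"] = vals * tcode
            if spec.include_granularity and not drop_g:
                X[f"{stem}xGxT"] = vals * gcode * tcode

    for i in range(1, spec.max_lag + 1):
        for j in (1, 2, 3):
            drop_g = (j == 3) or (j == 2 and spec.drop_c2_x_g)
            add_factor(f"c{j}_l{i}", std[f"c{j}_l{i}"], f"rt_l{i}",
                       drop_g=drop_g)
        add_factor(f"s_l{i}", std[f"s_l{i}"], f"rt_l{i}")
    # current-stimulus terms: no previous-RT interaction by construction
    X["s_cur"] = std["s_cur"]
    if spec.include_granularity:
        X["s_curxG"] = std["s_cur"] * gcode
    if spec.include_rt_cur:
        X["s_curxRTcur"] = std["s_cur"] * std["rt_cur"]
    if tcode is not None:
        X["s_curxT"] = std["s_cur"] * tcode
        if spec.include_granularity:
            X["s_curxGxT"] = std["s_cur"] * gcode * tcode
    X["const"] = np.ones_like(y)
    # columns identically zero (e.g. third-order choice codes when no
    # granularity-8 blocks exist) or exactly reducible to earlier columns
    # (e.g. c2 x G when only two granularity levels are present) carry no
    # separate information and are dropped, base terms taking precedence
    X = {k: v for k, v in X.items() if np.any(v != 0)}
    X, dropped = _prune_dependent(X)

    meta = base[["_G_cur", "_G_prev", "_choice_prev", "_s_cur", "_s_prev",
                 "_participant", "_blockkey"]].reset_index(drop=True)
    meta.columns = ["G", "G_prev", "choice_prev", "s_cur", "s_prev",
                    "participant", "block"]
    return HistoryDesign(y=y, X=pd.DataFrame(X), spec=spec, meta=meta,
                         dropped_columns=dropped)


def _prune_dependent(X: dict, rtol: float = 1e-9) -> tuple[dict, list[str]]:
    """Drop columns exactly linearly dependent on the preceding ones
    (Gram-Schmidt with a relative residual threshold)."""
    keep: dict = {}
    dropped: list[str] = []
    basis: list[np.ndarray] = []
    for name, col in X.items():
        v = col.astype(float)
        r = v.copy()
        for q in basis:
            r = r - (q @ r) * q
        if np.linalg.norm(r) <= rtol * max(np.linalg.norm(v), 1.0):
            dropped.append(name)
            continue
        keep[name] = col
        basis.append(r / np.linalg.norm(r))
    return keep, dropped


def _block_frame(grp: pd.DataFrame, spec: DesignSpec,
                 paired: bool) -> pd.DataFrame:
    """Raw (pre-standardization) regressor values for one block."""
    grp = grp.reset_index(drop=True)
    n = len(grp)
    out = {"_blockkey": [f"{p}|{b}" for p, b in
                         zip(grp["participant"], grp["block"])]}
    gmap = _G_CODES[spec.granularity_scheme]
    G_cur = grp["G"].to_numpy()
    choice = grp["choice"].to_numpy(dtype=float)
    stim = grp["stimulus"].to_numpy(dtype=float)
    rt = grp["rt"].to_numpy(dtype=float) if "rt" in grp.columns \
        else np.full(n, np.nan)

    def codes_for(ch, g):
        if not np.isfinite(ch):
            return (np.nan, np.nan, np.nan)
        return decompose_choice(int(ch), int(g))

    if paired:
        # within a trial pair the classification decision precedes the
        # second-task response, so lag 1 is the same row's classification
        c_codes = [codes_for(c, g) for c, g in zip(choice, G_cur)]
        lag = {
            "c_l1": np.array(c_codes, dtype=float),
            "s_l1": stim,
            "rt_l1": rt,
            "choice_prev": choice,
            "G_prev": G_cur,
        }
    else:
        lag = {}
        for i in range(1, spec.max_lag + 1):
            ch_i = np.full(n, np.nan)
            g_i = np.full(n, np.nan)
            s_i = np.full(n, np.nan)
            rt_i = np.full(n, np.nan)
            ch_i[i:] = choice[:-i]
            g_i[i:] = G_cur[:-i]
            s_i[i:] = stim[:-i]
            rt_i[i:] = rt[:-i]
            lag[f"codes{i}"] = np.array(
                [codes_for(c, g) if np.isfinite(g) else (np.nan,) * 3
                 for c, g in zip(ch_i, g_i)], dtype=float)
            lag[f"s{i}"] = s_i
            lag[f"rt{i}"] = rt_i
            if i == 1:
                lag["choice_prev"] = ch_i
                lag["G_prev"] = g_i

    # regressand and current-stimulus terms
    if spec.response == "choice":
        y = np.where(np.isfinite(choice), (choice > G_cur / 2).astype(float),
                     np.nan)
        s_cur = stim
    else:
        resp = _resolve_response(grp, spec.response).to_numpy(dtype=float)
        y = resp
        s_cur = grp["second_stimulus"].to_numpy(dtype=float) if paired \
            else stim

    out["_y"] = y
    out["_raw_s_cur"] = s_cur
    out["_s_cur"] = s_cur
    out["_G_cur"] = G_cur
    out["_participant"] = grp["participant"]
    if spec.include_rt_cur:
        out["_raw_rt_cur"] = rt

    if paired:
        for j in (1, 2, 3):
            out[f"_raw_c{j}_l1"] = lag["c_l1"][:, j - 1]
        out["_raw_s_l1"] = lag["s_l1"]
        out["_s_prev"] = lag["s_l1"]
        if spec.include_rt_prev:
            out["_raw_rt_l1"] = lag["rt_l1"]
        out["_choice_prev"] = lag["choice_prev"]
        out["_G_prev"] = lag["G_prev"]
        gprev = lag["G_prev"]
    else:
        for i in range(1, spec.max_lag + 1):
            for j in (1, 2, 3):
                out[f"_raw_c{j}_l{i}"] = lag[f"codes{i}"][:, j - 1]
            out[f"_raw_s_l{i}"] = lag[f"s{i}"]
            if spec.include_rt_prev:
                out[f"_raw_rt_l{i}"] = lag[f"rt{i}"]
        out["_s_prev"] = lag["s1"]
        out["_choice_prev"] = lag["choice_prev"]
        out["_G_prev"] = lag["G_prev"]
        gprev = lag["G_prev"]

    out["_gcode_cur"] = np.array(
        [gmap.get(int(g), np.nan) if np.isfinite(g) else np.nan
         for g in G_cur], dtype=float)
    out["_gcode_prev"] = np.array(
        [gmap.get(int(g), np.nan) if np.isfinite(g) else np.nan
         for g in gprev], dtype=float)
    if spec.include_iti:
        out["_iti_code"] = code_granularity(grp["iti"], "iti")
    else:
        out["_iti_code"] = np.zeros(n)
    frame = pd.DataFrame(out)
    if spec.include_granularity:
        gcol = "_gcode_prev" if spec.granularity_target == "previous" \
            else "_gcode_cur"
        frame = frame.dropna(subset=[gcol])
    return frame


def fit_history_model(design: HistoryDesign) -> RegressionResult:
    """Fit the assembled design by ML probit (binary or bounded response)
    or ordinary least squares (reproduction)."""
    X = design.X
    y = design.y.astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design is rank deficient ({rank} < {X.shape[1]} columns)")
    try:
        if design.spec.link == "probit":
            yy = y
            if not set(np.unique(yy)) <= {0.0, 1.0}:
                eps = 1e-4  # bounded continuous response: quasi-probit
                yy = np.clip(yy, eps, 1 - eps)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(yy, X, family=sm.families.Binomial(
                    link=sm.families.links.Probit()))
                fit = model.fit(maxiter=200, tol=1e-8)
            tag = "probit"
        else:
            fit = sm.OLS(y, X).fit()
            tag = "linear"
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ConvergenceError(f"model fit failed: {exc}") from exc
    if design.spec.link == "probit" and not np.all(np.isfinite(fit.bse)):
        bad = [c for c, se in zip(X.columns, fit.bse) if not np.isfinite(se)]
        raise ConvergenceError(f"non-finite standard errors for {bad}")
    p = pd.Series(fit.pvalues, index=X.columns)
    return RegressionResult(
        coefficients=pd.Series(fit.params, index=X.columns),
        std_errors=pd.Series(fit.bse, index=X.columns),
        p_values=p,
        q_values=pd.Series(fdr_adjust(p.to_numpy()), index=X.columns),
        model_tag=tag,
        n_obs=design.n_obs,
        fitted=fit,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty p-value vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def individual_level_tests(per_participant_coefficients: pd.DataFrame,
                           ) -> pd.DataFrame:
    """One-sample t-tests of per-participant coefficients against zero.

    Returns mean, t, p and BH-adjusted q per coefficient.  Zero-variance
    columns get p = 1 when the common value is 0 (no evidence of effect).
    """
    df = per_participant_coefficients
    if len(df) < 2:
        raise InsufficientDataError("need at least two participants")
    means, ts, ps = [], [], []
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        m = v.mean()
        if v.std(ddof=1) == 0:
            ts.append(0.0 if m == 0 else np.inf)
            ps.append(1.0 if m == 0 else 0.0)
        else:
            t, p = stats.ttest_1samp(v, 0.0)
            ts.append(float(t))
            ps.append(float(p))
        means.append(float(m))
    out = pd.DataFrame({"mean": means, "t": ts, "p": ps}, index=df.columns)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


@dataclass
class PsychometricSummary:
    table: pd.DataFrame      # one row per (bin, prev-choice class, G) cell
    r_squared: float
    conditioning: str


def psychometric_summary(design: HistoryDesign, fitted: RegressionResult,
                         conditioning: str = "current_stimulus",
                         n_bins: int = 8) -> PsychometricSummary:
    """Observed vs model-predicted response proportions per cell.

    The conditioning stimulus (current or previous) is cut into
    equal-probability octiles; cells are its bins crossed with the previous
    choice class and the granularity level.  R-squared is computed across
    occupied cells as 1 - SSE/SST.
    """
    if conditioning not in ("current_stimulus", "previous_stimulus"):
        raise InvalidArgumentError(f"unknown conditioning {conditioning!r}")
    if fitted.n_obs != design.n_obs:
        raise InvalidArgumentError("fitted model does not match the design")
    meta = design.meta
    svals = meta["s_cur"] if conditioning == "current_stimulus" \
        else meta["s_prev"]
    bins = pd.qcut(svals, n_bins, labels=False, duplicates="drop") + 1
    pred = fitted.predict(design.X)
    df = pd.DataFrame({
        "bin": bins,
        "prev_choice": meta["choice_prev"].astype(int),
        "G": meta["G_prev"].astype(int),
        "observed": design.y,
        "predicted": pred,
    })
    cells = df.groupby(["G", "prev_choice", "bin"], observed=True).agg(
        observed=("observed", "mean"),
        predicted=("predicted", "mean"),
        n=("observed", "size"),
    ).reset_index()
    obs = cells["observed"].to_numpy()
    prd = cells["predicted"].to_numpy()
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum((obs - prd) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return PsychometricSummary(table=cells, r_squared=r2,
                               conditioning=conditioning)
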