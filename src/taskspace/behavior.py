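"""Behavioral analyses: factorial stay probabilities, the task-structure
index, lagged-state and factor logistic regressions, the economic-choice
psychometric fit, and the value-variable regression taxonomy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "StayTable",
    "stay_table",
    "pool_stay_tables",
    "ts_index",
    "ts_index_variance",
    "lagged_state_regression",
    "factor_regression",
    "PsychometricModel",
    "PsychometricResults",
    "value_variables",
    "value_regression_taxonomy",
    "VALUE_VARIABLES",
]


# ---------------------------------------------------------------------------
# Two-stage factorial analysis

_STATE_KEYS = ("CR", "CN", "RR", "RN")


@dataclass
class StayTable:
    """Stay probabilities conditioned on the previous trial's state.

    States combine transition (common/rare) and outcome (rewarded/not):
    CR, CN, RR, RN. ``counts`` holds (stays, total) per cell.
    """

    probs: dict
    counts: dict

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.probs[k] for k in _STATE_KEYS})


def _trial_state(common: int, reward: int) -> str:
    return ("C" if common else "R") + ("R" if reward else "N")


def stay_table(log: pd.DataFrame) -> StayTable:
    """Empirical p(stay | previous-trial state) for a two-stage log."""
    if "intermediate" not in log.columns or "common" not in log.columns:
        raise ValueError("stay analysis requires a two-stage log with intermediates")
    choice = log["choice"].to_numpy(dtype=int)
    common = log["common"].to_numpy(dtype=float)
    reward = log["reward"].to_numpy(dtype=float)
    stays = {k: [0, 0] for k in _STATE_KEYS}
    for t in range(len(choice) - 1):
        if not np.isfinite(common[t]):
            continue
        key = _trial_state(int(common[t]), int(reward[t]))
        stays[key][1] += 1
        stays[key][0] += int(choice[t + 1] == choice[t])
    probs = {k: (s / n if n else np.nan) for k, (s, n) in stays.items()}
    counts = {k: tuple(v) for k, v in stays.items()}
    return StayTable(probs=probs, counts=counts)


def pool_stay_tables(tables: list[StayTable]) -> StayTable:
    """Combine stay counts across sessions (e.g. replicate seeds)."""
    stays = {k: [0, 0] for k in _STATE_KEYS}
    for t in tables:
        for k in _STATE_KEYS:
            s, n = t.counts[k]
            stays[k][0] += s
            stays[k][1] += n
    probs = {k: (s / n if n else np.nan) for k, (s, n) in stays.items()}
    return StayTable(probs=probs, counts={k: tuple(v) for k, v in stays.items()})


def ts_index(table: StayTable) -> float:
    """Normalized contrast (CR + RN - CN - RR) / (CR + RN + CN + RR).

    Positive values mean the agent exploits the transition structure;
    always lies in [-1, 1].
    """
    p = table.probs
    denom = p["CR"] + p["RN"] + p["CN"] + p["RR"]
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("task-structure index undefined: zero denominator")
    return (p["CR"] + p["RN"] - p["CN"] - p["RR"]) / denom


def ts_index_variance(table: StayTable) -> float:
    """Delta-method sampling variance of the task-structure index.

    Each cell probability is binomial with its observed trial count; the
    gradient of the index with respect to the aligned (CR, RN) cells is
    (D - N)/D^2 and for the opposed (CN, RR) cells -(D + N)/D^2.
    """
    p = table.probs
    N = p["CR"] + p["RN"] - p["CN"] - p["RR"]
    D = p["CR"] + p["RN"] + p["CN"] + p["RR"]
    if D == 0:
        raise ValueError("task-structure index undefined: zero denominator")
    var = 0.0
    for key in _STATE_KEYS:
        _, n = table.counts[key]
        if n == 0:
            continue
        grad = (D - N) / D ** 2 if key in ("CR", "RN") else -(D + N) / D ** 2
        var += grad ** 2 * p[key] * (1 - p[key]) / n
    return var


# ---------------------------------------------------------------------------
# Logistic regressions on two-stage choices


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> pd.DataFrame:
    """Logit fit with a regularized fallback under separation."""
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError
        return pd.DataFrame({"coef": res.params, "se": res.bse, "p": res.pvalues})
    except Exception:
        warnings.warn("logistic regression ill-conditioned; using L2 fallback")
        res = model.fit_regularized(alpha=1.0, disp=0, maxiter=500)
        return pd.DataFrame({
            "coef": res.params,
            "se": np.full(len(res.params), np.nan),
            "p": np.full(len(res.params), np.nan),
        })


def lagged_state_regression(log: pd.DataFrame, lags: int = 10) -> pd.DataFrame:
    """Regress the current choice on the four trial states (intermediate
    x outcome) at each of the past ``lags`` trials.

    Because exactly one state occurs per trial, the four indicators at a
    lag are collinear; the fit uses sum-to-zero (deviation) coding with
    an intercept and reconstructs the fourth state's coefficient and
    standard error from the constraint, so every (state, lag) cell is
    reported on a common scale.
    """
    inter = log["intermediate"].to_numpy(dtype=float)
    reward = log["reward"].to_numpy(dtype=float)
    choice = log["choice"].to_numpy(dtype=int)
    valid = np.isfinite(inter)
    if valid.sum() <= lags * 4:
        raise ValueError("log too short for the requested number of lags")
    state = (inter * 2 + (1 - reward)).astype(int)   # B1R,B1N,B2R,B2N = 0..3
    names = ["B1R", "B1N", "B2R", "B2N"]
    rows, ys = [], []
    start = np.flatnonzero(valid).min() + lags
    for t in range(start, len(choice)):
        feats = {"const": 1.0}
        for lag in range(1, lags + 1):
            s_t = state[t - lag]
            for s in range(3):                       # deviation-coded contrasts
                feats[f"{names[s]}_lag{lag}"] = (
                    1.0 if s_t == s else (-1.0 if s_t == 3 else 0.0)
                )
        rows.append(feats)
        ys.append(int(choice[t] == 0))
    X = pd.DataFrame(rows)
    model = sm.Logit(np.asarray(ys), X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200)
    cov = res.cov_params()
    out_rows = []
    for lag in range(1, lags + 1):
        cols = [f"{names[s]}_lag{lag}" for s in range(3)]
        coefs = res.params[cols].to_numpy()
        ses = res.bse[cols].to_numpy()
        for s in range(3):
            z = coefs[s] / ses[s]
            out_rows.append({"state": names[s], "lag": lag, "coef": coefs[s],
                             "se": ses[s], "p": 2 * stats.norm.sf(abs(z))})
        # fourth state: coefficient -(b1+b2+b3), variance 1' Sigma 1
        b4 = -coefs.sum()
        var4 = float(np.ones(3) @ cov.loc[cols, cols].to_numpy() @ np.ones(3))
        se4 = np.sqrt(var4)
        z4 = b4 / se4 if se4 > 0 else np.nan
        out_rows.append({"state": names[3], "lag": lag, "coef": b4, "se": se4,
                         "p": 2 * stats.norm.sf(abs(z4))})
    return pd.DataFrame(out_rows)


def factor_regression(log: pd.DataFrame) -> pd.DataFrame:
    """Five-factor logistic regression of the current choice.

    Factors (all +/-1 coded in the direction of choosing option A1):
    Correct (choose the currently better option), Reward (repeat if the
    last trial was rewarded, switch otherwise), Stay (repeat), Transition
    (repeat after common, switch after rare), TransXOut (repeat after
    common-rewarded or rare-unrewarded; switch otherwise).
    """
    choice = log["choice"].to_numpy(dtype=int)
    common = log["common"].to_numpy(dtype=float)
    reward = log["reward"].to_numpy(dtype=float)
    block_type = log["block_type"].astype(str).to_numpy()
    rows, ys = [], []
    for t in range(1, len(choice)):
        if not np.isfinite(common[t - 1]):
            continue
        c_prev = 1.0 if choice[t - 1] == 0 else -1.0
        trans = 2.0 * common[t - 1] - 1.0
        out = 2.0 * reward[t - 1] - 1.0
        rows.append({
            "Correct": 1.0 if block_type[t] == "B1" else -1.0,
            "Reward": c_prev * out,
            "Stay": c_prev,
            "Transition": c_prev * trans,
            "TransXOut": c_prev * trans * out,
        })
        ys.append(int(choice[t] == 0))
    X = pd.DataFrame(rows)
    out = _fit_logit(np.asarray(ys), X)
    out.index.name = "factor"
    return out


# ---------------------------------------------------------------------------
# Economic choice: psychometric model


class PsychometricModel:
    """Logistic choice model p(choose B) = sigma(a + b log(m_B/m_A)).

    Fitted on non-forced trials (both offers positive); the indifference
    point exp(-a/b) estimates the relative value of A in units of B.
    """

    def __init__(self, offer_A: np.ndarray, offer_B: np.ndarray, choice: np.ndarray):
        self.offer_A = np.asarray(offer_A, dtype=float)
        self.offer_B = np.asarray(offer_B, dtype=float)
        self.choice = np.asarray(choice, dtype=int)

    @classmethod
    def from_log(cls, log: pd.DataFrame) -> "PsychometricModel":
        return cls(log["offer_A"], log["offer_B"], log["choice"])

    def fit(self) -> "PsychometricResults":
        mask = (self.offer_A > 0) & (self.offer_B > 0)
        if mask.sum() < 10 or len(np.unique(self.offer_B[mask] / self.offer_A[mask])) < 2:
            raise ValueError("no interior offers: psychometric fit is degenerate")
        x = np.log(self.offer_B[mask] / self.offer_A[mask])
        y = (self.choice[mask] == 1).astype(int)
        X = sm.add_constant(pd.DataFrame({"log_ratio": x}))
        res = _fit_logit(y, X)
        a, b = res["coef"]["const"], res["coef"]["log_ratio"]
        if b <= 0:
            warnings.warn("non-increasing psychometric slope; estimate unreliable")
        fractions = (
            pd.DataFrame({
                "offer_A": self.offer_A, "offer_B": self.offer_B,
                "chose_B": (self.choice == 1).astype(float),
            })
            .groupby(["offer_A", "offer_B"])  # per offer pair, for plotting
            .agg(p_choose_B=("chose_B", "mean"), n=("chose_B", "size"))
            .reset_index()
        )
        return PsychometricResults(
            intercept=float(a), slope=float(b),
            relative_value=float(np.exp(-a / b)) if b != 0 else np.nan,
            nobs=int(mask.sum()), choice_fractions=fractions, model=self,
        )


@dataclass
class PsychometricResults:
    intercept: float
    slope: float
    relative_value: float       # value of one unit of A, in units of B
    nobs: int
    choice_fractions: pd.DataFrame
    model: PsychometricModel

    def summary(self) -> str:
        return (
            "Psychometric choice fit\n"
            f"  n trials (non-forced): {self.nobs}\n"
            f"  intercept a: {self.intercept:+.4f}\n"
            f"  slope b:     {self.slope:+.4f}\n"
            f"  relative value (1A = rho B): rho = {self.relative_value:.3f}\n"
        )


# ---------------------------------------------------------------------------
# Value-variable taxonomy

VALUE_VARIABLES = [
    "total value", "chosen value", "other value", "value difference",
    "value ratio", "offer value A", "offer value B", "chosen juice",
    "value A chosen", "value B chosen",
]


def value_variables(log: pd.DataFrame, gamma: float = 2.0) -> pd.DataFrame:
    """The ten per-trial value regressors of the economic-choice taxonomy.

    Option values are relative-value weighted magnitudes (value of A =
    gamma * m_A). 'value ratio' is other/chosen and is undefined (NaN)
    when the chosen value is zero; 'value A chosen'/'value B chosen' are
    defined only on the trials where that juice was chosen.
    """
    v_a = gamma * log["offer_A"].to_numpy(dtype=float)
    v_b = log["offer_B"].to_numpy(dtype=float)
    chose_a = log["choice"].to_numpy(dtype=int) == 0
    chosen = np.where(chose_a, v_a, v_b)
    other = np.where(chose_a, v_b, v_a)
    ratio = np.where(chosen > 0, other / np.where(chosen > 0, chosen, 1.0), np.nan)
    return pd.DataFrame({
        "total value": v_a + v_b,
        "chosen value": chosen,
        "other value": other,
        "value difference": chosen - other,
        "value ratio": ratio,
        "offer value A": v_a,
        "offer value B": v_b,
        "chosen juice": (~chose_a).astype(float),
        "value A chosen": np.where(chose_a, v_a, np.nan),
        "value B chosen": np.where(~chose_a, v_b, np.nan),
    })


def value_regression_taxonomy(
    window_rates: np.ndarray, variables: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify each neuron by the value variable that best explains it.

    Per neuron and variable, an ordinary linear regression rate = a*var+b
    is evaluated through the slope's t-test; a variable qualifies at
    p < alpha Bonferroni-corrected across the ten variables, and the
    neuron is assigned to the qualifying variable with the highest R^2.

    Returns (per-neuron frame, counts of classified neurons per category).
    """
    R = np.asarray(window_rates, dtype=float)
    n_neurons = R.shape[1]
    n_vars = len(variables.columns)
    r2 = np.full((n_vars, n_neurons), np.nan)
    pvals = np.full((n_vars, n_neurons), np.nan)
    for j, name in enumerate(variables.columns):
        v = variables[name].to_numpy(dtype=float)
        mask = np.isfinite(v)
        if mask.sum() < 3 or np.nanstd(v[mask]) == 0:
            warnings.warn(f"constant or empty regressor {name!r}; skipped")
            continue
        vv = v[mask]
        rr = R[mask]
        vc = vv - vv.mean()
        rc = rr - rr.mean(axis=0)
        denom = np.sqrt((vc ** 2).sum() * (rc ** 2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (vc @ rc) / denom
        corr = np.clip(corr, -1.0, 1.0)
        n = mask.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = corr * np.sqrt((n - 2) / np.maximum(1e-300, 1 - corr ** 2))
        pvals[j] = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        r2[j] = corr ** 2
    qualified = pvals * n_vars < alpha
    best = np.where(qualified, r2, -np.inf).argmax(axis=0)
    classified = qualified.any(axis=0)
    labels = np.where(
        classified, np.array(variables.columns, dtype=object)[best], "unclassified"
    )
    frame = pd.DataFrame({
        "neuron": np.arange(n_neurons),
        "category": labels,
        "best_r2": np.where(classified, r2[best, np.arange(n_neurons)], np.nan),
    })
    counts = (
        frame.loc[frame["category"] != "unclassified", "category"]
        .value_counts()
        .reindex(variables.columns, fill_value=0)
    )
    return frame, counts
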