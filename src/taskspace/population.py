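"""Population-activity analyses: selectivity classification and PCA.

Selectivity follows the standard single-unit convention: a neuron is
labelled by its preferred task condition if a one-way ANOVA across
conditions is significant and every pairwise comparison of the preferred
condition against each other condition survives Bonferroni correction
(Welch t-tests). For the reversal task, neurons that fail the
conjunction test may still carry a single input factor (choice identity
or outcome), and are then labelled 'A'/'B'/'R'/'N' by the significant
marginal contrast.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_selectivity",
    "classify_reversal_selectivity",
    "group_category",
    "PCAResult",
    "population_pca",
    "stimulus_epoch",
]


def stimulus_epoch(times: np.ndarray, onset: float, offset: float) -> slice:
    """Index slice of ``times`` covering the input-presentation period.

    The condition-trace PCA is evaluated on this epoch by default: it is
    where the task events drive the state and the condition trajectories
    separate.
    """
    times = np.asarray(times)
    lo = int(np.searchsorted(times, onset, side="right"))
    hi = int(np.searchsorted(times, offset, side="right"))
    return slice(lo, hi)


def _pairwise_pref_pvalues(groups: list[np.ndarray], pref: np.ndarray) -> np.ndarray:
    """Welch t-test p-values of the preferred condition vs each other, (C-1, N)."""
    C = len(groups)
    N = groups[0].shape[1]
    ps = np.ones((C, C, N))
    for a in range(C):
        for b in range(C):
            if a == b:
                continue
            ps[a, b] = stats.ttest_ind(
                groups[a], groups[b], axis=0, equal_var=False
            ).pvalue
    out = np.ones((C - 1, N))
    for n_idx in range(N):
        others = [c for c in range(C) if c != pref[n_idx]]
        out[:, n_idx] = ps[pref[n_idx], others, n_idx]
    return out


def classify_selectivity(
    rates: np.ndarray,
    conditions: np.ndarray,
    alpha: float = 0.05,
    condition_order: list[str] | None = None,
) -> pd.DataFrame:
    """Label each neuron by its preferred condition, if defensible.

    Parameters
    ----------
    rates : (n_trials, N) decision-time rates.
    conditions : (n_trials,) condition label per trial.
    alpha : significance level for the omnibus ANOVA and the
        Bonferroni-corrected pairwise tests.

    Returns a frame with columns ``neuron, preferred, selective, label,
    p_omnibus, f_stat``; ``label`` is 'unselective' where the conjunction
    of tests fails.
    """
    rates = np.asarray(rates, dtype=float)
    conditions = np.asarray(conditions)
    names = condition_order or sorted(pd.unique(conditions))
    groups = [rates[conditions == c] for c in names]
    if len(groups) < 2 or any(g.shape[0] < 2 for g in groups):
        raise ValueError("need >= 2 conditions with >= 2 trials each")
    f_stat, p_omni = stats.f_oneway(*groups, axis=0)
    means = np.stack([g.mean(axis=0) for g in groups])
    pref = means.argmax(axis=0)
    pair_p = _pairwise_pref_pvalues(groups, pref)
    n_comp = len(groups) - 1
    significant = (
        (p_omni < alpha)
        & np.all(pair_p * n_comp < alpha, axis=0)
        # the preferred mean must be strictly greatest
        & (np.sort(means, axis=0)[-1] > np.sort(means, axis=0)[-2])
    )
    labels = np.where(significant, np.array(names, dtype=object)[pref], "unselective")
    return pd.DataFrame({
        "neuron": np.arange(rates.shape[1]),
        "preferred": np.array(names, dtype=object)[pref],
        "selective": significant,
        "label": labels,
        "p_omnibus": p_omni,
        "f_stat": f_stat,
    })


def classify_reversal_selectivity(
    rates: np.ndarray, conditions: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Reversal-task scheme over the four input combinations AR/AN/BR/BN.

    Conjunction-selective neurons keep their condition label; the rest
    are tested on the two marginal input factors (A vs B trials, R vs N
    trials, Bonferroni over the two contrasts) and labelled by the
    significant factor's higher side, e.g. a neuron driven by input A in
    both AR and AN trials becomes 'A'.
    """
    frame = classify_selectivity(rates, conditions, alpha,
                                 condition_order=["AN", "AR", "BN", "BR"])
    conditions = np.asarray(conditions)
    choice_is_a = np.char.startswith(conditions.astype(str), "A")
    rewarded = np.char.endswith(conditions.astype(str), "R")
    rates = np.asarray(rates, dtype=float)

    marg = {}
    for name, mask in [("choice", choice_is_a), ("outcome", rewarded)]:
        t = stats.ttest_ind(rates[mask], rates[~mask], axis=0, equal_var=False)
        marg[name] = (t.pvalue, rates[mask].mean(0) - rates[~mask].mean(0))

    labels = frame["label"].to_numpy(dtype=object)
    for i in np.flatnonzero(~frame["selective"].to_numpy()):
        p_c, d_c = marg["choice"][0][i], marg["choice"][1][i]
        p_o, d_o = marg["outcome"][0][i], marg["outcome"][1][i]
        sig_c, sig_o = p_c * 2 < alpha, p_o * 2 < alpha
        if sig_c and (not sig_o or p_c <= p_o):
            labels[i] = "A" if d_c > 0 else "B"
        elif sig_o:
            labels[i] = "R" if d_o > 0 else "N"
    frame["label"] = labels
    return frame


_TWOSTAGE_CONDITIONS = [
    f"A{a}B{b}{o}" for a in (1, 2) for b in (1, 2) for o in ("R", "N")
]


def group_category(preferred: str) -> tuple[str, str]:
    """Map an eight-way two-stage condition to its evidence categories.

    A condition supports "A1 leads to reward" (category A1R) when A1
    co-occurs with reward or A2 with non-reward; the analogous rule gives
    the B-side category. Every condition falls in exactly one A-category
    (A1R or A1N) and one B-category (B1R or B1N).
    """
    if preferred not in _TWOSTAGE_CONDITIONS:
        raise ValueError(f"unknown two-stage condition {preferred!r}")
    a = preferred[1]        # '1' or '2'
    b = preferred[3]
    rewarded = preferred[4] == "R"
    a_cat = "A1R" if (a == "1") == rewarded else "A1N"
    b_cat = "B1R" if (b == "1") == rewarded else "B1N"
    return a_cat, b_cat


@dataclass
class PCAResult:
    components: np.ndarray          # (k, N) loadings over neurons
    variance_ratio: np.ndarray      # per-component fraction, non-increasing
    projections: np.ndarray         # (C, T, k) condition-by-time trajectories
    condition_names: list[str]

    def cumulative_variance(self, k: int) -> float:
        return float(self.variance_ratio[:k].sum())


def population_pca(
    mean_traces: dict[str, np.ndarray] | np.ndarray,
    n_components: int = 10,
    decision_only: bool = False,
    epoch: slice | None = None,
) -> PCAResult:
    """PCA of condition-averaged, time-resolved population activity.

    ``mean_traces`` maps condition label -> (T, N) mean rate trace (or is
    a (C, T, N) array). Rows (condition x time) are stacked, centred over
    the neuron dimension's ensemble of rows, and decomposed; variance
    fractions refer to this matrix. ``decision_only`` restricts each
    condition to its final sample; ``epoch`` slices the time axis first
    (e.g. the post-stimulus period).
    """
    if isinstance(mean_traces, dict):
        names = sorted(mean_traces)
        X3 = np.stack([np.asarray(mean_traces[c], dtype=float) for c in names])
    else:
        X3 = np.asarray(mean_traces, dtype=float)
        names = [str(i) for i in range(X3.shape[0])]
    if X3.shape[0] < 2:
        raise ValueError("need at least two conditions")
    if epoch is not None:
        X3 = X3[:, epoch]
    if decision_only:
        X3 = X3[:, -1:]
    C, T, N = X3.shape
    k = min(n_components, C * T, N)
    X = X3.reshape(C * T, N)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    return PCAResult(
        components=pca.components_,
        variance_ratio=pca.explained_variance_ratio_,
        projections=scores.reshape(C, T, k),
        condition_names=names,
    )
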