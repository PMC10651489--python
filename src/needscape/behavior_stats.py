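"""Behavioural statistics of choice under conflicting needs.

Every operation here works on plain per-trial session tables (columns
``session_id``, ``trial_time_s``, ``label``, ``outcome``) and therefore
applies identically to simulated sessions and to externally supplied data
in the same format.  The central operational quantities:

* **behavioural thirst / hunger**: the number of water / food rewards a
  subject will still collect before the end of the session, normalized by
  the dataset-median total of that reward type;
* **relative need**: (thirst - hunger) / (thirst + hunger), in [-1, +1];
* **bouts**: run lengths of consecutive identical rewarded choices, whose
  pooled distribution is geometric under a two-state Markov process;
* **goal value**: a per-trial scalar position along the food-to-water goal
  axis (model simulations supply the true projection).

Bootstrap confidence intervals resample at the session level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "behavioral_needs",
    "median_reward_totals",
    "selectivity_index",
    "persistence_fit",
    "BoutSummary",
    "run_lengths",
    "choice_probability_vs_need",
    "self_transition_regression",
    "transition_matrix_mle",
    "transition_vs_interval",
    "choice_predictor_comparison",
    "stim_choice_density",
    "goal_switch_analysis",
    "phase_portrait",
    "compare_phase_portraits",
    "PhasePortrait",
]

_REWARDS = ("water", "food")


def _require_columns(df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"session table is missing columns: {missing}")


def median_reward_totals(sessions: pd.DataFrame) -> Tuple[float, float]:
    """Median per-session totals of (water, food) rewards across the dataset."""
    _require_columns(sessions, ["session_id", "outcome"])
    tot = sessions.groupby("session_id")["outcome"].agg(
        water=lambda o: (o == "water").sum(),
        food=lambda o: (o == "food").sum(),
    )
    return float(tot["water"].median()), float(tot["food"].median())


def behavioral_needs(sessions: pd.DataFrame,
                     median_totals: Optional[Tuple[float, float]] = None,
                     ) -> pd.DataFrame:
    """Annotate each trial with behavioural thirst, hunger and relative need.

    Thirst at a trial is the session's total water-reward count minus the
    water rewards collected before that trial, divided by the dataset
    median total (``median_totals`` overrides the dataset medians, e.g.
    when annotating a single session against a larger reference set).
    Relative need is left NaN where thirst + hunger = 0.
    """
    _require_columns(sessions, ["session_id", "trial_time_s", "outcome"])
    if median_totals is None:
        median_totals = median_reward_totals(sessions)
    med_w, med_f = median_totals
    if med_w <= 0 or med_f <= 0:
        raise ValueError("median reward totals must be positive")

    out = sessions.copy()
    is_w = (out["outcome"] == "water").astype(int)
    is_f = (out["outcome"] == "food").astype(int)
    # rewards collected strictly before the current trial
    cw = is_w.groupby(out["session_id"]).cumsum() - is_w
    cf = is_f.groupby(out["session_id"]).cumsum() - is_f
    tot_w = is_w.groupby(out["session_id"]).transform("sum")
    tot_f = is_f.groupby(out["session_id"]).transform("sum")
    out["remaining_water"] = tot_w - cw
    out["remaining_food"] = tot_f - cf
    out["thirst"] = out["remaining_water"] / med_w
    out["hunger"] = out["remaining_food"] / med_f
    denom = out["thirst"] + out["hunger"]
    out["relative_need"] = np.where(
        denom > 0, (out["thirst"] - out["hunger"]) / denom, np.nan)
    return out


def selectivity_index(sessions: pd.DataFrame) -> pd.Series:
    """Per-session (water - food) / (water + food) cumulative choice index."""
    _require_columns(sessions, ["session_id", "outcome"])
    def one(o: pd.Series) -> float:
        w = (o == "water").sum()
        f = (o == "food").sum()
        return np.nan if w + f == 0 else (w - f) / (w + f)
    return sessions.groupby("session_id")["outcome"].apply(one)


# ---------------------------------------------------------------------------
# Choice persistence (bouts)
# ---------------------------------------------------------------------------

def run_lengths(outcomes: Sequence[str]) -> np.ndarray:
    """Run lengths of identical consecutive rewarded choices."""
    seq = [o for o in outcomes if o in _REWARDS]
    if not seq:
        return np.empty(0, dtype=int)
    arr = np.asarray(seq)
    change = np.flatnonzero(arr[1:] != arr[:-1])
    edges = np.concatenate([[-1], change, [arr.size - 1]])
    return np.diff(edges).astype(int)


@dataclass
class BoutSummary:
    """Pooled bout lengths with a geometric fit and bootstrap CI."""

    per_session: Dict[str, np.ndarray]
    pooled: np.ndarray
    p_hat: float
    ci: Tuple[float, float]

    @property
    def mean_length(self) -> float:
        return float(self.pooled.mean())


def persistence_fit(sessions: pd.DataFrame, n_boot: int = 1000,
                    seed: int = 0) -> BoutSummary:
    """Geometric MLE of the pooled bout-length distribution.

    The MLE shape parameter of a geometric distribution on {1, 2, ...} is
    1 / mean(run length); the 95% CI resamples sessions with replacement.
    """
    _require_columns(sessions, ["session_id", "outcome"])
    per = {sid: run_lengths(d["outcome"].to_numpy())
           for sid, d in sessions.groupby("session_id", sort=False)}
    per = {sid: r for sid, r in per.items() if r.size}
    if not per:
        raise ValueError("no rewarded choices in any session")
    pooled = np.concatenate(list(per.values()))
    p_hat = 1.0 / pooled.mean()
    rng = np.random.default_rng(seed)
    sids = list(per)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(len(sids), len(sids), replace=True)
        res = np.concatenate([per[sids[i]] for i in pick])
        reps[b] = 1.0 / res.mean()
    ci = tuple(np.percentile(reps, [2.5, 97.5]))
    return BoutSummary(per_session=per, pooled=pooled, p_hat=float(p_hat), ci=ci)


# ---------------------------------------------------------------------------
# Need-conditioned choice probabilities
# ---------------------------------------------------------------------------

def _ols(x: np.ndarray, y: np.ndarray):
    import statsmodels.api as sm

    # has_constant="add" keeps a 2-parameter fit even for degenerate
    # (constant) predictors; the pseudo-inverse then splits the mean
    model = sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()
    return model


def _percentile_bins(values: np.ndarray, width_pct: float = 5.0) -> np.ndarray:
    """Stable quantile-bin assignment over pooled values."""
    q = np.arange(0.0, 100.0 + width_pct / 2, width_pct)
    edges = np.unique(np.percentile(values, q))
    return np.clip(np.searchsorted(edges, values, side="right") - 1,
                   0, len(edges) - 2), edges


def _binned_mle(values: np.ndarray, indicator: np.ndarray,
                session_ids: np.ndarray, n_boot: int, seed: int,
                width_pct: float = 5.0) -> pd.DataFrame:
    bins, edges = _percentile_bins(values, width_pct)
    rng = np.random.default_rng(seed)
    sids = np.unique(session_ids)
    rows = []
    boot = np.full((n_boot, edges.size - 1), np.nan)
    for b in range(n_boot):
        pick = rng.choice(sids, sids.size, replace=True)
        mask = np.concatenate([np.flatnonzero(session_ids == s) for s in pick])
        vb, ib = bins[mask], indicator[mask]
        for k in range(edges.size - 1):
            m = vb == k
            if m.any():
                boot[b, k] = ib[m].mean()
    for k in range(edges.size - 1):
        m = bins == k
        if not m.any():
            continue
        lo, hi = np.nanpercentile(boot[:, k], [2.5, 97.5])
        rows.append({
            "bin_center": values[m].mean(), "bin_lo": edges[k],
            "bin_hi": edges[k + 1], "mle": indicator[m].mean(),
            "ci_lo": lo, "ci_hi": hi, "n": int(m.sum()),
        })
    return pd.DataFrame(rows)


@dataclass
class NeedRegression:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: Tuple[float, float]
    binned: pd.DataFrame
    n: int


def choice_probability_vs_need(annotated: pd.DataFrame, n_boot: int = 1000,
                               seed: int = 0) -> NeedRegression:
    """Marginal probability of choosing water as a function of relative need.

    Linear regression of the binary water-choice indicator on relative
    need over rewarded Go trials, plus per-5-percentile-bin MLE fractions
    with session-bootstrap CIs.
    """
    _require_columns(annotated, ["session_id", "outcome", "relative_need"])
    d = annotated[annotated["outcome"].isin(_REWARDS)].dropna(subset=["relative_need"])
    x = d["relative_need"].to_numpy()
    y = (d["outcome"] == "water").to_numpy(float)
    model = _ols(x, y)
    rng = np.random.default_rng(seed)
    sids = d["session_id"].to_numpy()
    uniq = np.unique(sids)
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(uniq, uniq.size, replace=True)
        mask = np.concatenate([np.flatnonzero(sids == s) for s in pick])
        slopes[b] = _ols(x[mask], y[mask]).params[1]
    binned = _binned_mle(x, y, sids, n_boot=max(n_boot // 4, 50), seed=seed + 1)
    return NeedRegression(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_ci=tuple(np.percentile(slopes, [2.5, 97.5])),
        binned=binned, n=len(d))


def _reward_pairs(annotated: pd.DataFrame) -> pd.DataFrame:
    """Consecutive rewarded choices within session, tagged with the
    previous choice and the elapsed time; intervening No-Go cues and
    misses do not contribute choices but do add elapsed time."""
    parts = []
    for sid, d in annotated.groupby("session_id", sort=False):
        r = d[d["outcome"].isin(_REWARDS)].copy()
        if len(r) < 2:
            continue
        r["prev_choice"] = r["outcome"].shift(1)
        r["dt_s"] = r["trial_time_s"].diff()
        # whether any miss occurred between the two rewarded choices
        go = d[d["label"] == "Go"]
        miss_times = go.loc[go["outcome"] == "miss", "trial_time_s"].to_numpy()
        prev_t = r["trial_time_s"].shift(1).to_numpy()
        cur_t = r["trial_time_s"].to_numpy()
        n_miss = np.array([
            np.sum((miss_times > a) & (miss_times < b)) if np.isfinite(a) else 0
            for a, b in zip(prev_t, cur_t)])
        r["miss_between"] = n_miss > 0
        parts.append(r.iloc[1:])
    if not parts:
        return pd.DataFrame(columns=list(annotated.columns)
                            + ["prev_choice", "dt_s", "miss_between"])
    return pd.concat(parts, ignore_index=True)


def self_transition_regression(annotated: pd.DataFrame,
                               min_remaining: int = 10,
                               n_boot: int = 500, seed: int = 0,
                               ) -> Dict[str, NeedRegression]:
    """Repeat-of-previous-choice probability regressed on relative need.

    Separate linear fits for water and food previous choices.  Trials with
    fewer than ``min_remaining`` remaining rewards of either type are
    excluded (sampling-floor exclusion).
    """
    _require_columns(annotated, ["session_id", "outcome", "relative_need",
                                 "remaining_water", "remaining_food"])
    pairs = _reward_pairs(annotated).dropna(subset=["relative_need"])
    pairs = pairs[(pairs["remaining_water"] >= min_remaining)
                  & (pairs["remaining_food"] >= min_remaining)]
    out: Dict[str, NeedRegression] = {}
    for choice in _REWARDS:
        sub = pairs[pairs["prev_choice"] == choice]
        x = sub["relative_need"].to_numpy()
        y = (sub["outcome"] == choice).to_numpy(float)
        model = _ols(x, y)
        rng = np.random.default_rng(seed)
        sids = sub["session_id"].to_numpy()
        uniq = np.unique(sids)
        slopes = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(uniq, uniq.size, replace=True)
            mask = np.concatenate([np.flatnonzero(sids == s) for s in pick])
            slopes[b] = _ols(x[mask], y[mask]).params[1]
        binned = _binned_mle(x, y, sids, n_boot=max(n_boot // 4, 50), seed=seed + 1)
        out[choice] = NeedRegression(
            slope=float(model.params[1]), intercept=float(model.params[0]),
            r_squared=float(model.rsquared),
            slope_ci=tuple(np.percentile(slopes, [2.5, 97.5])),
            binned=binned, n=len(sub))
    return out


def transition_matrix_mle(annotated: pd.DataFrame,
                          need_window: Tuple[float, float] = (-0.25, 0.25),
                          n_boot: int = 1000, seed: int = 0):
    """MLE Markov transition matrix between reward choices.

    Counts consecutive rewarded-choice transitions restricted to trials
    whose relative need lies inside ``need_window``; rows (from food,
    from water) are normalized to 1.  Returns ``(matrix, ci_lo, ci_hi)``
    as DataFrames indexed by previous choice.
    """
    pairs = _reward_pairs(annotated).dropna(subset=["relative_need"])
    lo, hi = need_window
    pairs = pairs[(pairs["relative_need"] >= lo) & (pairs["relative_need"] <= hi)]

    def mat_of(p: pd.DataFrame) -> np.ndarray:
        m = np.zeros((2, 2))
        for i, prev in enumerate(("food", "water")):
            sub = p[p["prev_choice"] == prev]
            if len(sub):
                m[i, 0] = (sub["outcome"] == "food").mean()
                m[i, 1] = (sub["outcome"] == "water").mean()
        return m

    point = mat_of(pairs)
    rng = np.random.default_rng(seed)
    sids = pairs["session_id"].to_numpy()
    uniq = np.unique(sids)
    boots = np.empty((n_boot, 2, 2))
    for b in range(n_boot):
        pick = rng.choice(uniq, uniq.size, replace=True)
        mask = np.concatenate([np.flatnonzero(sids == s) for s in pick])
        boots[b] = mat_of(pairs.iloc[mask])
    ci_lo, ci_hi = np.percentile(boots, [2.5, 97.5], axis=0)
    idx = pd.Index(["food", "water"], name="previous")
    cols = ["food", "water"]
    return (pd.DataFrame(point, index=idx, columns=cols),
            pd.DataFrame(ci_lo, index=idx, columns=cols),
            pd.DataFrame(ci_hi, index=idx, columns=cols))


def transition_vs_interval(annotated: pd.DataFrame,
                           geom=None, params=None,
                           need_window: Tuple[float, float] = (-0.25, 0.25),
                           bin_edges: Sequence[float] = (0, 5, 10, 15, 20, 30, 45, 60),
                           ) -> pd.DataFrame:
    """Switch probability versus elapsed time between rewarded choices.

    Restricted to consecutive rewarded choices with no intervening miss
    and balanced needs.  When ``geom``/``params`` are given, overlays the
    closed-form two-state switch probability evaluated per pair at its own
    (thirst, hunger, elapsed time) and reports the per-bin theory mean.
    """
    from .landscape import NeedState

    pairs = _reward_pairs(annotated).dropna(subset=["relative_need"])
    pairs = pairs[~pairs["miss_between"]]
    lo, hi = need_window
    pairs = pairs[(pairs["relative_need"] >= lo) & (pairs["relative_need"] <= hi)]
    switch = (pairs["outcome"] != pairs["prev_choice"]).to_numpy(float)
    dt = pairs["dt_s"].to_numpy()

    theory = None
    if geom is not None and params is not None:
        from .theory import kramers_rates, self_transition_probs

        theory = np.empty(len(pairs))
        for i, (_, row) in enumerate(pairs.iterrows()):
            T = max(row["thirst"], 1e-6)
            H = max(row["hunger"], 1e-6)
            w_wf, w_fw = kramers_rates(NeedState(T, H), geom, params)
            P_ww, P_ff = self_transition_probs(row["dt_s"], w_wf, w_fw)
            theory[i] = 1.0 - (P_ww if row["prev_choice"] == "water" else P_ff)

    rows = []
    for a, b in zip(bin_edges[:-1], bin_edges[1:]):
        m = (dt >= a) & (dt < b)
        if m.sum() == 0:
            continue
        n = int(m.sum())
        p = switch[m].mean()
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        row = {"t_lo": a, "t_hi": b, "t_mean": dt[m].mean(),
               "p_switch": p, "se": se, "n": n}
        if theory is not None:
            row["p_theory"] = theory[m].mean()
        rows.append(row)
    out = pd.DataFrame(rows)
    if theory is not None and len(out) > 1:
        resid = out["p_switch"] - out["p_theory"]
        ss_tot = np.sum((out["p_switch"] - out["p_switch"].mean()) ** 2)
        out.attrs["r_squared"] = float(1.0 - np.sum(resid ** 2) / ss_tot)
    return out


# ---------------------------------------------------------------------------
# Upcoming-choice predictiveness: needs vs previous choice
# ---------------------------------------------------------------------------

def choice_predictor_comparison(annotated: pd.DataFrame, seed: int = 0,
                                ) -> pd.DataFrame:
    """Held-out AUC of needs-only vs previous-choice-only SVM classifiers.

    Per session, RBF-kernel SVMs (C = 1, kernel width scaled by feature
    variance) are fit on a random 50% split to predict the upcoming
    rewarded choice from (i) behavioural thirst and hunger and (ii) the
    previous-choice indicator alone; both are scored by ROC AUC on the
    held-out half.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.svm import SVC

    _require_columns(annotated, ["session_id", "outcome", "thirst", "hunger"])
    rng = np.random.default_rng(seed)
    rows = []
    for sid, d in annotated.groupby("session_id", sort=False):
        r = d[d["outcome"].isin(_REWARDS)].copy()
        r["prev_choice"] = r["outcome"].shift(1)
        r = r.dropna(subset=["prev_choice"])
        if len(r) < 20:
            continue
        y = (r["outcome"] == "water").to_numpy(int)
        feats = {
            "needs": r[["thirst", "hunger"]].to_numpy(),
            "previous": (r["prev_choice"] == "water").to_numpy(int)[:, None].astype(float),
        }
        idx = rng.permutation(len(r))
        half = len(r) // 2
        train, test = idx[:half], idx[half:]
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            continue
        aucs = {}
        for name, X in feats.items():
            clf = SVC(C=1.0, kernel="rbf", gamma="scale")
            clf.fit(X[train], y[train])
            aucs[name] = roc_auc_score(y[test], clf.decision_function(X[test]))
        rows.append({"session_id": sid, "auc_needs": aucs["needs"],
                     "auc_previous": aucs["previous"],
                     "difference": aucs["previous"] - aucs["needs"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optogenetic choice-time densities
# ---------------------------------------------------------------------------

def stim_choice_density(sessions: pd.DataFrame, stim_onsets: Sequence[float],
                        window: Tuple[float, float] = (-30.0, 30.0),
                        grid_points: int = 121,
                        ) -> Dict[str, pd.DataFrame]:
    """Kernel density of choice times relative to the nearest stimulation onset.

    Gaussian KDE (Scott bandwidth) per outcome class over offsets within
    ``window``; each returned density integrates to 1 over the window's
    support.  Outcome classes with fewer than 2 events are omitted.
    """
    _require_columns(sessions, ["trial_time_s", "outcome"])
    onsets = np.sort(np.asarray(stim_onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("need at least one stimulation onset")
    grid = np.linspace(window[0], window[1], grid_points)
    out: Dict[str, pd.DataFrame] = {}
    for choice in _REWARDS:
        t = sessions.loc[sessions["outcome"] == choice, "trial_time_s"].to_numpy()
        if t.size == 0:
            continue
        nearest = onsets[np.clip(np.searchsorted(onsets, t) - 1, 0, onsets.size - 1)]
        alt = onsets[np.clip(np.searchsorted(onsets, t), 0, onsets.size - 1)]
        off = np.where(np.abs(t - nearest) <= np.abs(t - alt), t - nearest, t - alt)
        off = off[(off >= window[0]) & (off <= window[1])]
        if off.size < 2 or np.ptp(off) == 0:
            continue
        kde = sps.gaussian_kde(off)
        out[choice] = pd.DataFrame({"offset_s": grid, "density": kde(grid)})
    return out


# ---------------------------------------------------------------------------
# Goal-dimension analyses
# ---------------------------------------------------------------------------

@dataclass
class GoalSwitchAnalysis:
    auc_by_distance: pd.DataFrame     # choice AUC by trials-until-switch
    auc_all: float                    # choice AUC over all rewarded trials
    switch_prob: pd.DataFrame         # per-trial LDA-rescaled switch probability
    switch_auc: float                 # AUC predicting switches from |goal|


def goal_switch_analysis(trials: pd.DataFrame, midpoint: float = 0.0,
                         max_distance: int = 4) -> GoalSwitchAnalysis:
    """Predictiveness of the per-trial goal value around switches.

    ``trials`` needs columns ``session_id``, ``outcome`` and ``goal``.
    Computes (i) the AUC for predicting the upcoming choice from the goal
    value, stratified by the number of trials until the next switch;
    (ii) the switch probability on each trial as a monotone (1-D linear
    discriminant) rescaling of the distance |goal - midpoint|; and
    (iii) the AUC for predicting switches from that distance (scored as
    -|goal - midpoint|: switches happen near the midpoint).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.metrics import roc_auc_score

    _require_columns(trials, ["session_id", "outcome", "goal"])
    parts = []
    for sid, d in trials.groupby("session_id", sort=False):
        r = d[d["outcome"].isin(_REWARDS)].copy()
        if len(r) < 3:
            continue
        r["switch"] = (r["outcome"] != r["outcome"].shift(1))
        r.loc[r.index[0], "switch"] = False
        # distance (in rewarded trials) until the next switch trial
        sw_pos = np.flatnonzero(r["switch"].to_numpy())
        pos = np.arange(len(r))
        if sw_pos.size:
            nxt = np.searchsorted(sw_pos, pos, side="left")
            dist = np.where(nxt < sw_pos.size, sw_pos[np.clip(nxt, 0, sw_pos.size - 1)] - pos,
                            np.iinfo(np.int32).max)
        else:
            dist = np.full(len(r), np.iinfo(np.int32).max)
        r["trials_to_switch"] = dist
        parts.append(r)
    pooled = pd.concat(parts, ignore_index=True)
    y_choice = (pooled["outcome"] == "water").to_numpy(int)
    g = pooled["goal"].to_numpy()

    rows = []
    for k in range(max_distance + 1):
        m = pooled["trials_to_switch"].to_numpy() == k
        if m.sum() >= 10 and len(np.unique(y_choice[m])) == 2:
            rows.append({"trials_to_switch": k,
                         "auc": roc_auc_score(y_choice[m], g[m]),
                         "n": int(m.sum())})
    m_far = pooled["trials_to_switch"].to_numpy() > max_distance
    if m_far.sum() >= 10 and len(np.unique(y_choice[m_far])) == 2:
        rows.append({"trials_to_switch": max_distance + 1,
                     "auc": roc_auc_score(y_choice[m_far], g[m_far]),
                     "n": int(m_far.sum())})
    auc_all = roc_auc_score(y_choice, g)

    # upcoming-switch prediction from proximity to the midpoint
    dist_mid = np.abs(g - midpoint)
    y_next_switch = np.zeros(len(pooled), dtype=int)
    for sid, d in pooled.groupby("session_id", sort=False):
        idx = d.index.to_numpy()
        y_next_switch[idx[:-1]] = d["switch"].to_numpy()[1:]
    if np.ptp(dist_mid) > 0 and len(np.unique(y_next_switch)) == 2:
        lda = LinearDiscriminantAnalysis()
        lda.fit(dist_mid[:, None], y_next_switch)
        prob = lda.predict_proba(dist_mid[:, None])[:, 1]
        switch_auc = roc_auc_score(y_next_switch, -dist_mid)
    else:
        # degenerate goal signal: fall back to the base switch rate
        prob = np.full(len(pooled), y_next_switch.mean())
        switch_auc = 0.5
    switch_prob = pd.DataFrame({
        "session_id": pooled["session_id"], "goal": g,
        "p_switch": prob, "next_switch": y_next_switch})
    return GoalSwitchAnalysis(
        auc_by_distance=pd.DataFrame(rows), auc_all=float(auc_all),
        switch_prob=switch_prob, switch_auc=float(switch_auc))


@dataclass
class PhasePortrait:
    """Stay/switch scatter in (goal position, trial-to-trial velocity)."""

    points: pd.DataFrame              # position, velocity, switch
    zone_halfwidth: float
    velocity_edges: np.ndarray
    stay_density: np.ndarray          # normalized over zone bins
    switch_density: np.ndarray
    resampled_switch_density: np.ndarray   # (n_resample, n_bins)


def phase_portrait(trials: pd.DataFrame, zone_halfwidth: float = 3.75,
                   n_resample: int = 1000,
                   target_switch_fraction: Optional[float] = None,
                   n_bins: int = 12, seed: int = 0) -> PhasePortrait:
    """Phase portrait of per-trial goal position and velocity.

    For each rewarded trial the position is the goal value and the
    velocity is the change in goal value from the previous rewarded trial;
    a trial is a switch when its choice differs from the previous one.
    Velocity densities of stay and switch trials within the transition
    zone (|position| < ``zone_halfwidth``) are normalized to sum to 1;
    switch points are additionally resampled ``n_resample`` times to a
    target switch fraction to control for dataset-level switch-rate bias.
    """
    _require_columns(trials, ["session_id", "outcome", "goal"])
    parts = []
    for sid, d in trials.groupby("session_id", sort=False):
        r = d[d["outcome"].isin(_REWARDS)]
        if len(r) < 2:
            continue
        g = r["goal"].to_numpy()
        sw = (r["outcome"].to_numpy()[1:] != r["outcome"].to_numpy()[:-1])
        parts.append(pd.DataFrame({
            "session_id": sid, "position": g[1:], "velocity": np.diff(g),
            "switch": sw}))
    pts = pd.concat(parts, ignore_index=True)

    vmax = max(np.abs(pts["velocity"]).max(), 1e-9)
    edges = np.linspace(-vmax, vmax, n_bins + 1)
    zone = np.abs(pts["position"].to_numpy()) < zone_halfwidth

    def density(mask):
        h, _ = np.histogram(pts.loc[mask, "velocity"], bins=edges)
        tot = h.sum()
        return h / tot if tot else h.astype(float)

    stay_d = density(zone & ~pts["switch"].to_numpy())
    switch_d = density(zone & pts["switch"].to_numpy())

    rng = np.random.default_rng(seed)
    n_total = len(pts)
    frac = (target_switch_fraction if target_switch_fraction is not None
            else pts["switch"].mean())
    n_sw = max(int(round(frac * n_total)), 1)
    sw_idx = np.flatnonzero(pts["switch"].to_numpy())
    res = np.zeros((n_resample, n_bins))
    if sw_idx.size:
        for b in range(n_resample):
            pick = rng.choice(sw_idx, n_sw, replace=True)
            sub = pts.iloc[pick]
            m = np.abs(sub["position"].to_numpy()) < zone_halfwidth
            h, _ = np.histogram(sub.loc[m, "velocity"], bins=edges)
            tot = h.sum()
            res[b] = h / tot if tot else h
    return PhasePortrait(points=pts, zone_halfwidth=zone_halfwidth,
                         velocity_edges=edges, stay_density=stay_d,
                         switch_density=switch_d,
                         resampled_switch_density=res)


def compare_phase_portraits(a: PhasePortrait, b: PhasePortrait):
    """Two-sample KS test on switch-trial |velocity| between two models.

    Returns ``(statistic, p_value)``; a small p rejects the hypothesis
    that the two switch mechanisms produce the same velocity profile.
    """
    va = np.abs(a.points.loc[a.points["switch"], "velocity"])
    vb = np.abs(b.points.loc[b.points["switch"], "velocity"])
    stat, p = sps.ks_2samp(va, vb)
    return float(stat), float(p)
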