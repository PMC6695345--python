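"""Habit-bias scores and the downstream group statistics.

The habit bias (slips-of-action score) is the proportion of go responses to
devalued stimuli minus the proportion to valued stimuli: near zero means
habitual responding (no devaluation sensitivity), strongly negative means
goal-directed control.  Downstream analyses: stepwise regression of habit
bias on group status, learning parameters and optional white-matter
covariates; ANCOVA for the group effect with learning rate as covariate;
and Pearson correlations compared across groups with Fisher's z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class HabitBiasRecord:
    subject_id: object
    group: str
    p_respond_devalued: float
    p_respond_valued: float

    @property
    def habit_bias(self) -> float:
        return self.p_respond_devalued - self.p_respond_valued


def habit_bias(dev_trials: pd.DataFrame, per_block: bool = False) -> HabitBiasRecord:
    """Habit bias for one subject's devaluation-phase trials.

    ``response`` codes: 2 = go, 3 = no-go (misses, if any, are dropped).
    Proportions are pooled across blocks by default; ``per_block=True``
    computes them within each block and averages the block values instead.
    """
    df = dev_trials[dev_trials["phase"] == "devaluation"]
    df = df[df["response"].isin([2, 3])]
    dev = df[df["devalued_flag"] == 1]
    val = df[df["devalued_flag"] == 0]
    if len(dev) == 0 or len(val) == 0:
        raise ValueError("need at least one devalued and one valued trial")
    if per_block:
        p_dev = float(dev.groupby("block")["response"].apply(
            lambda r: (r == 2).mean()).mean())
        p_val = float(val.groupby("block")["response"].apply(
            lambda r: (r == 2).mean()).mean())
    else:
        p_dev = float((dev["response"] == 2).mean())
        p_val = float((val["response"] == 2).mean())
    return HabitBiasRecord(
        subject_id=df["subject_id"].iloc[0] if "subject_id" in df else None,
        group=str(df["group"].iloc[0]) if "group" in df else "",
        p_respond_devalued=p_dev,
        p_respond_valued=p_val)


def habit_bias_table(trial_log: pd.DataFrame) -> pd.DataFrame:
    """Per-subject habit-bias scores for a whole cohort trial log."""
    rows = []
    for sid, sub in trial_log.groupby("subject_id", sort=True):
        rec = habit_bias(sub)
        rows.append((sid, rec.group, rec.p_respond_devalued,
                     rec.p_respond_valued, rec.habit_bias))
    return pd.DataFrame(rows, columns=["subject_id", "group",
                                       "p_respond_devalued", "p_respond_valued",
                                       "habit_bias"])


@dataclass
class StepwiseResult:
    selected: list[str]
    entry_order: list[str]
    coefficients: dict[str, float]   # standardized betas
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    steps: list[str]


def stepwise_regression(outcome: np.ndarray, candidates: pd.DataFrame,
                        entry_p: float = 0.05,
                        removal_p: float = 0.10) -> StepwiseResult:
    """Forward-entry / backward-removal regression on partial-F p-values.

    At each step the candidate with the smallest entry p-value below
    ``entry_p`` joins the model; any included predictor whose p-value rises
    above ``removal_p`` is dropped.  Predictors and outcome are z-scored, so
    coefficients are standardized betas.
    """
    y = np.asarray(outcome, dtype=float)
    X = candidates.astype(float)
    n = len(y)
    if n <= X.shape[1] + 2:
        raise ValueError("too few observations for stepwise selection")
    if (X.std(axis=0) == 0).any():
        bad = list(X.columns[X.std(axis=0) == 0])
        raise ValueError(f"constant predictors: {bad}")
    ys = (y - y.mean()) / y.std()
    Xs = (X - X.mean()) / X.std()

    included: list[str] = []
    order: list[str] = []
    steps: list[str] = []
    seen: set[frozenset] = {frozenset()}
    while True:
        changed = False
        # forward entry
        excluded = [c for c in Xs.columns if c not in included]
        best_p, best_c = 1.0, None
        for c in excluded:
            model = sm.OLS(ys, sm.add_constant(Xs[included + [c]])).fit()
            p = model.pvalues[c]
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < entry_p:
            included.append(best_c)
            order.append(best_c)
            steps.append(f"enter {best_c} (p={best_p:.4g})")
            changed = True
        # backward removal
        if included:
            model = sm.OLS(ys, sm.add_constant(Xs[included])).fit()
            pvals = model.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > removal_p:
                included.remove(worst)
                steps.append(f"remove {worst} (p={pvals[worst]:.4g})")
                changed = True
        if not changed:
            break
        state = frozenset(included)
        if state in seen:  # enter/remove cycle: stop at the revisited model
            steps.append("cycle detected; stopping")
            break
        seen.add(state)

    if included:
        fit = sm.OLS(ys, sm.add_constant(Xs[included])).fit()
        cond = np.linalg.cond(Xs[included].to_numpy())
        if cond > 1e4:
            import warnings
            warnings.warn(f"collinear candidates: condition number {cond:.3g}")
        coefs = {c: float(fit.params[c]) for c in included}
        return StepwiseResult(included, order, coefs, float(fit.rsquared),
                              float(fit.fvalue), int(fit.df_model),
                              int(fit.df_resid), steps)
    return StepwiseResult([], [], {}, 0.0, math.nan, 0, n - 1, steps)


@dataclass
class AncovaResult:
    f_group: float
    p_group: float
    df_num: int
    df_den: int


def ancova_habit_bias(habit_bias: np.ndarray, group: np.ndarray,
                      covariates: pd.DataFrame | None = None) -> AncovaResult:
    """Partial F-test for the group effect, adjusting for covariates."""
    y = np.asarray(habit_bias, dtype=float)
    g = pd.Series(group)
    if g.nunique() < 2:
        raise ValueError("need at least 2 groups")
    gd = pd.get_dummies(g, drop_first=True).astype(float)
    parts = [gd]
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.astype(float).reset_index(drop=True)
        for c in cov.columns:
            if np.allclose(cov[c], y):
                raise ValueError(f"covariate {c!r} is identical to the outcome")
        parts.append(cov)
    X = sm.add_constant(pd.concat(parts, axis=1))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design")
    full = sm.OLS(y, X).fit()
    restricted_cols = [c for c in X.columns if c not in gd.columns]
    restricted = sm.OLS(y, X[restricted_cols]).fit()
    df_num = gd.shape[1]
    df_den = int(full.df_resid)
    f = ((restricted.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return AncovaResult(float(f), p, df_num, df_den)


@dataclass
class FisherCompareResult:
    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p_one_tailed: float


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> FisherCompareResult:
    """Compare two independent Pearson correlations via Fisher's transform.

    Z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); the one-tailed p
    is the upper tail for Z > 0 (testing r1 > r2).
    """
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 per sample")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return FisherCompareResult(r1, r2, n1, n2, z, float(sps.norm.sf(z)))


def correlation_with_fisher_compare(x1, y1, x2, y2) -> FisherCompareResult:
    """Pearson r per group plus the Fisher-z comparison of the two."""
    for v in (x1, y1, x2, y2):
        if np.std(np.asarray(v, dtype=float)) == 0:
            raise ValueError("zero-variance input")
    r1 = float(sps.pearsonr(x1, y1).statistic)
    r2 = float(sps.pearsonr(x2, y2).statistic)
    return fisher_z_compare(r1, len(x1), r2, len(x2))
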