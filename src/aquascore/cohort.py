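"""Cohort-level inference on patient scores and survival.

Covers the downstream statistics of the scoring pipeline: two-stage
location/scale batch adjustment, ROC cutoff optimisation by Youden's J,
group assignment, Kaplan-Meier / log-rank comparison, univariate and
multivariate Cox proportional-hazards models (Efron ties, via lifelines),
a log(-log S) versus log t proportional-hazards diagnostic, quantile
grouping, BCL2 x MYC cross-classification, conventional-versus-AQUA
reclassification analysis, and AUROC comparison of scoring methods.

No multiple-testing correction is applied; subgroup p-values are
descriptive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .types import ConfigurationError, CutoffResult, SurvivalResult

__all__ = [
    "adjust_batch",
    "optimal_cutoff",
    "assign_groups",
    "km_logrank",
    "cox_fit",
    "ph_diagnostic",
    "quantile_groups",
    "cross_classify",
    "reclassification_analysis",
    "compare_methods_auroc",
    "binary_endpoint",
]


def adjust_batch(scores, batch) -> np.ndarray:
    """Remove per-batch location and scale from a score vector.

    Stage 1 regresses scores on batch indicators and subtracts the fitted
    per-batch means, restoring the grand mean. Stage 2 divides each
    batch's centered residuals by that batch's standard deviation and
    restores the pooled standard deviation. After adjustment every batch
    has (numerically) the same mean and sd; within-batch rank order is
    unchanged because the map is affine per batch with positive slope.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(batch)
    if x.shape != labels.shape:
        raise ConfigurationError("scores and batch labels must align")
    uniq, inverse = np.unique(labels, return_inverse=True)
    counts = np.bincount(inverse)
    if np.any(counts < 2):
        bad = uniq[counts < 2]
        raise ConfigurationError(
            f"batch adjustment needs >= 2 patients per batch; offending "
            f"batch(es): {list(bad)}"
        )
    if len(uniq) == 1:
        return x.copy()

    grand_mean = x.mean()
    batch_means = np.bincount(inverse, weights=x) / counts
    centered = x - batch_means[inverse]

    # Within-batch sd of the centered residuals (ddof=1).
    ss = np.bincount(inverse, weights=centered**2)
    batch_sd = np.sqrt(ss / (counts - 1))
    if np.any(batch_sd == 0):
        bad = uniq[batch_sd == 0]
        raise ConfigurationError(
            f"batch(es) {list(bad)} have zero within-batch variance; "
            f"scale adjustment undefined"
        )
    pooled_sd = float(np.std(centered, ddof=1))
    return grand_mean + centered / batch_sd[inverse] * pooled_sd


def _roc_counts(scores: np.ndarray, outcome: np.ndarray):
    """True-positive / true-negative counts at every observed threshold
    (classification rule: score >= t is positive)."""
    thresholds = np.unique(scores)
    pos_sorted = np.sort(scores[outcome == 1])
    neg_sorted = np.sort(scores[outcome == 0])
    # #values >= t via searchsorted on the sorted arrays.
    tp = len(pos_sorted) - np.searchsorted(pos_sorted, thresholds, side="left")
    tn = np.searchsorted(neg_sorted, thresholds, side="left")
    return thresholds, tp, tn, len(pos_sorted), len(neg_sorted)


def _roc_points(scores: np.ndarray, outcome: np.ndarray):
    """Sensitivity/specificity at every observed threshold (rule: score >= t)."""
    thresholds, tp, tn, n_pos, n_neg = _roc_counts(scores, outcome)
    return thresholds, tp / n_pos, tn / n_neg


def _auroc(scores: np.ndarray, outcome: np.ndarray) -> float:
    """Trapezoidal AUROC (equals the Mann-Whitney statistic with ties at 1/2)."""
    _, sens, spec = _roc_points(scores, outcome)
    # Walk thresholds from high to low so TPR and FPR are nondecreasing,
    # then close the staircase at (0, 0) and (1, 1).
    tpr = np.concatenate(([0.0], sens[::-1], [1.0]))
    fpr = np.concatenate(([0.0], 1.0 - spec[::-1], [1.0]))
    return float(np.trapezoid(tpr, fpr))


def optimal_cutoff(
    scores, binary_outcome, outcome_definition: str = "unspecified"
) -> CutoffResult:
    """ROC-optimal score cutoff by Youden's J = sensitivity + specificity - 1.

    Scores at or above the cutoff are called positive. Every observed
    score is tried as a threshold; ties in J are broken toward the lower
    cutoff, resolved in exact integer arithmetic (J is maximized via its
    integer numerator TP*N_neg + TN*N_pos) so floating-point rounding
    cannot flip a tie. AUROC is the trapezoidal area under the empirical
    ROC curve.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(binary_outcome, dtype=int)
    if x.shape != y.shape:
        raise ConfigurationError("scores and outcome must align")
    if len(np.unique(y)) < 2:
        raise ConfigurationError(
            "cutoff optimisation needs both outcome classes present"
        )
    thresholds, tp, tn, n_pos, n_neg = _roc_counts(x, y)
    j_numerator = tp.astype(np.int64) * n_neg + tn.astype(np.int64) * n_pos
    best = int(np.argmax(j_numerator))  # thresholds ascending -> lowest wins ties
    return CutoffResult(
        cutoff=float(thresholds[best]),
        auroc=_auroc(x, y),
        sensitivity=float(tp[best] / n_pos),
        specificity=float(tn[best] / n_neg),
        outcome_definition=outcome_definition,
        n_positive=int(y.sum()),
        n_negative=int((1 - y).sum()),
    )


def assign_groups(scores, cutoff: float) -> np.ndarray:
    """Dichotomize scores at a cutoff: ``high`` iff score >= cutoff."""
    if not np.isfinite(cutoff):
        raise ConfigurationError("cutoff must be finite")
    x = np.asarray(scores, dtype=float)
    return np.where(x >= cutoff, "high", "low")


def km_logrank(times, events, groups) -> SurvivalResult:
    """Kaplan-Meier curves per group and the k-group log-rank test."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.shape == e.shape == g.shape) or t.size == 0:
        raise ConfigurationError(
            "times, events and groups must be equal-length and nonempty"
        )
    curves: dict = {}
    for label in np.unique(g):
        sel = g == label
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel], label=str(label))
        surv = kmf.survival_function_
        curves[str(label)] = pd.DataFrame({
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": kmf.event_table["at_risk"].reindex(surv.index).to_numpy(),
        })
    if len(curves) >= 2:
        lr = multivariate_logrank_test(t, g, e)
        stat, p = float(lr.test_statistic), float(lr.p_value)
    else:
        stat, p = 0.0, 1.0
    return SurvivalResult(km_curves=curves, logrank_stat=stat, logrank_p=p)


def cox_fit(
    covariates: pd.DataFrame, times, events, which: str = "multivariate"
) -> SurvivalResult:
    """Cox proportional-hazards regression (Efron tie handling).

    ``which="multivariate"`` fits all columns of ``covariates`` jointly;
    ``which="univariate"`` fits each column in its own single-covariate
    model. Categorical columns are one-hot encoded against their first
    level. The summary has one row per coefficient: log-HR, HR, Wald 95%
    CI and p.
    """
    if which not in ("univariate", "multivariate"):
        raise ConfigurationError(f"which must be uni/multivariate, got {which!r}")
    cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
    nunique = cov.nunique()
    constant = nunique[nunique <= 1].index.tolist()
    if constant:
        raise ConfigurationError(f"constant covariate(s): {constant}")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if int(e.sum()) < cov.shape[1]:
        raise ConfigurationError(
            f"{int(e.sum())} events for {cov.shape[1]} covariates; model "
            f"under-determined"
        )

    def _fit(frame: pd.DataFrame) -> pd.DataFrame:
        df = frame.copy()
        df["_time"] = t
        df["_event"] = e
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_time", event_col="_event")
        s = cph.summary
        return pd.DataFrame({
            "covariate": s.index,
            "log_hr": s["coef"].to_numpy(),
            "hr": s["exp(coef)"].to_numpy(),
            "ci_lower": s["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": s["exp(coef) upper 95%"].to_numpy(),
            "p": s["p"].to_numpy(),
        })

    if which == "multivariate":
        summary = _fit(cov)
    else:
        summary = pd.concat(
            [_fit(cov[[c]]) for c in cov.columns], ignore_index=True
        )
    summary["model"] = which
    return SurvivalResult(cox_summary=summary.reset_index(drop=True))


def ph_diagnostic(times, events, groups, n_grid: int = 50) -> SurvivalResult:
    """log(-log S) versus log t curves per group, plus a parallelism summary.

    Under proportional hazards the transformed survival curves are
    vertically parallel; the summary is the standard deviation of the
    between-group vertical gaps over a common log-time grid (averaged over
    group pairs when there are more than two). The grid is restricted to
    the region where every curve has survival in [0.05, 0.95] — outside
    it the Kaplan-Meier tails are too noisy to judge parallelism. Groups
    without events, or with a single usable point, are omitted with a
    note.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    notes: list[str] = []
    curves: dict = {}
    for label in np.unique(g):
        sel = g == label
        if e[sel].sum() == 0:
            notes.append(f"group {label!r} has no events; curve omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        surv = kmf.survival_function_.iloc[:, 0]
        usable = (surv > 0) & (surv < 1) & (surv.index > 0)
        if usable.sum() < 1:
            notes.append(f"group {label!r}: no usable survival points; omitted")
            continue
        curves[str(label)] = pd.DataFrame({
            "log_time": np.log(surv.index[usable].to_numpy(dtype=float)),
            "loglog_surv": np.log(-np.log(surv[usable].to_numpy(dtype=float))),
        })

    gap_sd = None
    lo_ll = np.log(-np.log(0.95))
    hi_ll = np.log(-np.log(0.05))
    trimmed = {
        k: c[(c["loglog_surv"] >= lo_ll) & (c["loglog_surv"] <= hi_ll)]
        for k, c in curves.items()
    }
    multi_point = {k: c for k, c in trimmed.items() if len(c) >= 2}
    if len(multi_point) >= 2:
        lo = max(c["log_time"].min() for c in multi_point.values())
        hi = min(c["log_time"].max() for c in multi_point.values())
        if hi > lo:
            grid = np.linspace(lo, hi, n_grid)
            interp = {
                k: np.interp(grid, c["log_time"], c["loglog_surv"])
                for k, c in multi_point.items()
            }
            keys = sorted(interp)
            sds = [
                float(np.std(interp[a] - interp[b]))
                for i, a in enumerate(keys)
                for b in keys[i + 1:]
            ]
            gap_sd = float(np.mean(sds))
        else:
            notes.append("no overlapping time range; parallelism summary skipped")
    else:
        notes.append("fewer than 2 multi-point curves; parallelism summary skipped")
    return SurvivalResult(ph_curves=curves, ph_gap_sd=gap_sd, notes=notes)


def quantile_groups(scores, probs: tuple[float, ...] = (0.1, 0.5, 0.9)) -> np.ndarray:
    """Ordinal group labels from quantile breakpoints of the score.

    With the default 10th/50th/90th quantiles this yields four ordered
    groups (``Q1``..``Q4``); a score exactly at a breakpoint joins the
    upper group. Quantiles use linear interpolation.
    """
    x = np.asarray(scores, dtype=float)
    if len(np.unique(x)) < len(probs) + 1:
        raise ConfigurationError(
            f"need more distinct scores than groups ({len(probs) + 1})"
        )
    breaks = np.quantile(x, probs, method="linear")
    if len(np.unique(breaks)) < len(breaks):
        raise ConfigurationError("degenerate quantile breakpoints (tied values)")
    idx = np.sum(x[:, None] >= breaks[None, :], axis=1)
    return np.array([f"Q{i + 1}" for i in idx])


def cross_classify(bcl2_groups, myc_groups, patient_ids=None) -> np.ndarray:
    """Joint BCL2 x MYC label: ``<bcl2>/<myc>`` in {low, high}^2."""
    b = np.asarray(bcl2_groups)
    m = np.asarray(myc_groups)
    if b.shape != m.shape:
        raise ConfigurationError("group vectors must align")
    if patient_ids is not None:
        ids = np.asarray(patient_ids)
        if ids.shape != b.shape or len(np.unique(ids)) != len(ids):
            raise ConfigurationError("patient ids must align and be unique")
    return np.array([f"{x}/{y}" for x, y in zip(b, m)])


def reclassification_analysis(
    conventional_calls, aqua_groups, times, events
) -> dict:
    """Concordance of conventional and AQUA classifications, with survival.

    Builds the 2x2 table of conventional (proportion-only) calls against
    AQUA groups, then — within each conventional stratum — compares
    survival of AQUA-low versus AQUA-high patients by log-rank. A stratum
    with fewer than two patients in either AQUA group is skipped with a
    warning note. This quantifies whether patients the AQUA score
    reclassifies downward (conventional-high, AQUA-low) indeed behave like
    low-risk patients.
    """
    conv = np.asarray(conventional_calls, dtype=bool)
    aq = np.asarray(aqua_groups)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)

    table = {
        "conventional_high_aqua_high": int(np.sum(conv & (aq == "high"))),
        "conventional_high_aqua_low": int(np.sum(conv & (aq == "low"))),
        "conventional_low_aqua_high": int(np.sum(~conv & (aq == "high"))),
        "conventional_low_aqua_low": int(np.sum(~conv & (aq == "low"))),
    }
    out: dict = {"table": table, "within_stratum": {}, "warnings": []}
    for name, stratum in (("conventional_high", conv), ("conventional_low", ~conv)):
        groups_here = aq[stratum]
        if (np.sum(groups_here == "low") < 2) or (np.sum(groups_here == "high") < 2):
            out["warnings"].append(
                f"{name}: a stratum arm has < 2 patients; comparison skipped"
            )
            continue
        res = km_logrank(t[stratum], e[stratum], groups_here)
        med = {}
        for glabel in ("low", "high"):
            sel = stratum & (aq == glabel)
            kmf = KaplanMeierFitter().fit(t[sel], e[sel])
            med[glabel] = float(kmf.median_survival_time_)
        out["within_stratum"][name] = {
            "logrank_stat": res.logrank_stat,
            "logrank_p": res.logrank_p,
            "median_survival": med,
            "mean_time_aqua_low": float(t[stratum & (aq == "low")].mean()),
            "mean_time_aqua_high": float(t[stratum & (aq == "high")].mean()),
            "event_rate_aqua_low": float(e[stratum & (aq == "low")].mean()),
            "event_rate_aqua_high": float(e[stratum & (aq == "high")].mean()),
        }
    return out


def compare_methods_auroc(
    score_sets: dict, binary_outcome, n_boot: int = 500, seed: int = 0
) -> pd.DataFrame:
    """AUROC of each scoring method on a common outcome, with bootstrap CI.

    ``score_sets`` maps method name to a score vector over the same
    patients. Percentile bootstrap (patient resampling) gives the 95% CI.
    """
    y = np.asarray(binary_outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ConfigurationError("AUROC needs both outcome classes present")
    rng = np.random.default_rng(seed)
    n = len(y)
    rows = []
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    for name, scores in score_sets.items():
        x = np.asarray(scores, dtype=float)
        if x.shape != y.shape:
            raise ConfigurationError(f"scores for {name!r} do not align with outcome")
        point = _auroc(x, y)
        boots = []
        for idx in boot_idx:
            yb = y[idx]
            if yb.min() == yb.max():
                continue
            boots.append(_auroc(x[idx], yb))
        lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
        rows.append({
            "method": name, "auroc": point,
            "ci_lower": float(lo), "ci_upper": float(hi),
        })
    return pd.DataFrame(rows)


def binary_endpoint(
    clinical: pd.DataFrame, kind: str = "os_5y"
) -> tuple[np.ndarray, np.ndarray, str]:
    """Derive a binary outcome from survival data for ROC analysis.

    ``os_5y``: death within 60 months, evaluable only for patients who
    died earlier or were followed at least 60 months. ``efs_2y``: any
    event within 24 months, evaluable analogously. Returns (evaluable
    mask, binary outcome over evaluable patients, definition string).
    """
    if kind == "os_5y":
        horizon, tcol, ecol = 60.0, "os_months", "os_event"
        label = "death within 5 years (OS)"
    elif kind == "efs_2y":
        horizon, tcol, ecol = 24.0, "efs_months", "efs_event"
        label = "event within 2 years (EFS)"
    else:
        raise ConfigurationError(f"unknown endpoint kind {kind!r}")
    t = clinical[tcol].to_numpy(dtype=float)
    e = clinical[ecol].to_numpy(dtype=int)
    evaluable = (t >= horizon) | (e == 1)
    outcome = ((e == 1) & (t <= horizon))[evaluable].astype(int)
    return evaluable, outcome, f"{label}, horizon {horizon} months"
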