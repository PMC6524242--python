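"""Survival evaluation battery.

Time-dependent ROC (cumulative cases / dynamic controls with
Kaplan-Meier inverse-censoring weights), Youden-optimal cutoffs,
Kaplan-Meier / log-rank comparisons, the random-gene-signature
bootstrap null, subsample robustness of competing signatures, paired
bootstrap AUC comparison, uni-/multivariate Cox adjustment, stratified
cohorts, the drug-response surrogate classification, and risk-score
comparisons across mutation/subtype strata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .datatypes import AnalysisConfig, Cohort, GeneSignature, ValidationError
from .signature import CoxEffect, apply_signature

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------


@dataclass
class TdRocResult:
    horizon: float
    auc: float
    cutoff: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_cases: int
    n_controls: int
    n_excluded: int


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimator of the censoring survival function G.

    Returns ``G(t, left=False)``; ``left=True`` evaluates the left limit
    G(t-), needed to weight a case that died exactly at t.
    """
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    cens = 1 - event[order]
    uniq = np.unique(t)
    n = len(t)
    surv = np.empty(len(uniq))
    g = 1.0
    for i, u in enumerate(uniq):
        at_risk = n - np.searchsorted(t, u, side="left")
        d = int(cens[(t == u)].sum())
        if at_risk > 0:
            g *= 1.0 - d / at_risk
        surv[i] = g

    def G(x: float, left: bool = False) -> float:
        side = "left" if left else "right"
        i = np.searchsorted(uniq, x, side=side) - 1
        return 1.0 if i < 0 else float(surv[i])

    return G


def _weighted_auc(s_cases, w_cases, s_controls, w_controls) -> float:
    """Weighted probability that a case outscores a control (ties 0.5)."""
    order = np.argsort(s_controls, kind="mergesort")
    sc = np.asarray(s_controls)[order]
    wc = np.asarray(w_controls)[order]
    cum = np.concatenate([[0.0], np.cumsum(wc)])
    lo = np.searchsorted(sc, s_cases, side="left")
    hi = np.searchsorted(sc, s_cases, side="right")
    below = cum[lo]
    ties = cum[hi] - cum[lo]
    num = float(np.sum(np.asarray(w_cases) * (below + 0.5 * ties)))
    denom = float(np.sum(w_cases) * np.sum(w_controls))
    return num / denom


def time_dependent_roc(
    rs: np.ndarray | pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
) -> TdRocResult:
    """Cumulative/dynamic time-dependent ROC at a horizon.

    Cases: event by the horizon; controls: still at risk beyond it;
    patients censored before the horizon are excluded from the ROC but
    inform the Kaplan-Meier censoring weights.  The cutoff maximizes the
    Youden index sensitivity + specificity - 1.
    """
    rs = np.asarray(rs, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    is_case = (time <= horizon) & (event == 1)
    is_control = time > horizon
    excluded = (~is_case) & (~is_control)
    if is_case.sum() == 0 or is_control.sum() == 0:
        raise ValidationError(
            f"no cases or no controls at horizon {horizon}: "
            f"{int(is_case.sum())} cases, {int(is_control.sum())} controls"
        )
    G = _censoring_km(time, event)
    w_cases = np.array([1.0 / max(G(t, left=True), 1e-12) for t in time[is_case]])
    g_h = max(G(horizon), 1e-12)
    w_controls = np.full(int(is_control.sum()), 1.0 / g_h)
    s_cases = rs[is_case]
    s_controls = rs[is_control]

    auc = _weighted_auc(s_cases, w_cases, s_controls, w_controls)

    thresholds = np.unique(rs[is_case | is_control])
    wc_tot = w_cases.sum()
    wd_tot = w_controls.sum()
    sens = np.array([w_cases[s_cases >= c].sum() / wc_tot for c in thresholds])
    spec = np.array([w_controls[s_controls < c].sum() / wd_tot for c in thresholds])
    youden = sens + spec - 1.0
    cutoff = float(thresholds[int(np.argmax(youden))])
    return TdRocResult(
        horizon=float(horizon), auc=float(auc), cutoff=cutoff,
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        n_cases=int(is_case.sum()), n_controls=int(is_control.sum()),
        n_excluded=int(excluded.sum()),
    )


def overall_survival_horizon(cohort: Cohort, quantile: float = 0.75) -> float:
    """Operational horizon for 'overall survival' AUCs: a quantile of the
    observed follow-up times (default 75th percentile)."""
    return float(np.quantile(cohort.time, quantile))


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def km_logrank(
    time: np.ndarray,
    event: np.ndarray,
    groups: np.ndarray,
) -> dict:
    """Product-limit curves per group plus the two-sided log-rank test."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"log-rank comparison needs exactly 2 nonempty groups, got {len(labels)}")
    curves = {}
    sizes = {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValidationError(f"group {lab!r} is empty")
        km = KaplanMeierFitter(label=str(lab))
        km.fit(time[mask], event[mask])
        curves[str(lab)] = km
        sizes[str(lab)] = int(mask.sum())
    a, b = labels
    res = logrank_test(
        time[groups == a], time[groups == b],
        event_observed_A=event[groups == a], event_observed_B=event[groups == b],
    )
    return {
        "curves": curves,
        "chi2": float(res.test_statistic),
        "p": float(res.p_value),
        "group_sizes": sizes,
    }


def split_by_cutoff(rs: pd.Series | np.ndarray, cutoff: float) -> np.ndarray:
    """High-/low-risk labels from a risk-score cutoff (>= cutoff is high)."""
    rs = np.asarray(rs, dtype=float)
    return np.where(rs >= cutoff, "high", "low")


# ---------------------------------------------------------------------------
# Bootstrap random-signature null
# ---------------------------------------------------------------------------


@dataclass
class NullDistributionResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_empirical: float        # #{AUC_b >= AUC_obs} / B
    p_add_one: float          # (1 + #) / (B + 1), conservative
    B: int
    k: int
    seed: int | None
    n_resampled: int = 0


def _fast_cox_scores(
    learning: Cohort, validation: Cohort, genes: list[str]
) -> np.ndarray:
    """Fit an unpenalized Cox model on the learning cohort and return the
    linear predictor on the validation cohort."""
    Xl = learning.expression.loc[genes].T.to_numpy(dtype=float)
    Xv = validation.expression.loc[genes].T.to_numpy(dtype=float)
    y = Surv.from_arrays(event=learning.event.astype(bool), time=learning.time)
    model = CoxPHSurvivalAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xl, y)
    return Xv @ model.coef_


def random_signature_null(
    learning: Cohort,
    validation: Cohort,
    observed_sig: GeneSignature,
    k: int = 12,
    B: int = 1000,
    horizon: float | None = None,
    gene_universe: list[str] | None = None,
    seed: int | None = None,
    cfg: AnalysisConfig | None = None,
) -> NullDistributionResult:
    """Empirical null of validation AUCs from random k-gene signatures.

    Each draw samples k genes without replacement from the universe,
    refits an unpenalized Cox model on the learning cohort, scores the
    validation cohort and records the AUC at the horizon (default: the
    'overall survival' quantile horizon).  Non-converging draws are
    resampled (logged, capped at 2B attempts).
    """
    cfg = cfg or AnalysisConfig()
    if gene_universe is None:
        gene_universe = sorted(
            set(learning.expression.index) & set(validation.expression.index)
        )
    if len(gene_universe) < k:
        raise ValidationError("gene universe smaller than signature size k")
    if horizon is None:
        horizon = overall_survival_horizon(validation, cfg.overall_horizon_quantile)
    rng = np.random.default_rng(seed)

    rs_obs = apply_signature(observed_sig, validation, cfg).scores
    observed = time_dependent_roc(rs_obs, validation.time, validation.event, horizon).auc

    null_aucs = np.empty(B)
    attempts = 0
    n_resampled = 0
    b = 0
    while b < B:
        if attempts >= 2 * B:
            raise ValidationError("too many non-converging null draws")
        attempts += 1
        genes = list(rng.choice(gene_universe, size=k, replace=False))
        try:
            scores = _fast_cox_scores(learning, validation, genes)
            auc = time_dependent_roc(scores, validation.time, validation.event, horizon).auc
        except (ValidationError, np.linalg.LinAlgError, ValueError, ArithmeticError):
            n_resampled += 1
            log.info("null draw %d resampled (non-convergence)", b)
            continue
        null_aucs[b] = auc
        b += 1
    n_ge = int(np.sum(null_aucs >= observed))
    return NullDistributionResult(
        observed_auc=float(observed), null_aucs=null_aucs,
        p_empirical=n_ge / B, p_add_one=(1 + n_ge) / (B + 1),
        B=B, k=k, seed=seed, n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------
# Robustness subsampling and AUC comparisons
# ---------------------------------------------------------------------------


@dataclass
class RobustnessResult:
    aucs: dict                      # signature -> horizon -> np.ndarray of B AUCs
    wilcoxon_p: dict                # signature -> horizon -> one-tailed p vs reference
    reference: str
    fraction: float
    B: int


def robustness_subsample(
    validation: Cohort,
    risk_scores: dict[str, pd.Series],
    fraction: float = 0.5,
    B: int = 100,
    horizons: tuple[float, ...] = (3.0, 5.0),
    seed: int | None = None,
) -> RobustnessResult:
    """Paired subsample AUC distributions for competing signatures.

    Each of the B replicates subsamples ``fraction`` of the patients
    without replacement; every signature is scored on the same
    subsample.  One-tailed Wilcoxon rank-sum p-values compare the first
    (reference) signature's AUC distribution against each other.
    """
    names = list(risk_scores)
    if not names:
        raise ValidationError("no signatures given")
    n = validation.n_patients
    size = int(round(fraction * n))
    if size < 20:
        raise ValidationError("subsample too small (fraction * n < 20)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(validation.expression.columns)
    time, event = validation.time, validation.event
    pos = {pid: i for i, pid in enumerate(ids)}
    score_mat = {name: np.asarray(risk_scores[name].loc[ids]) for name in names}

    aucs = {name: {h: np.empty(B) for h in horizons} for name in names}
    b = 0
    attempts = 0
    while b < B:
        if attempts >= 10 * B:
            raise ValidationError("too many degenerate subsamples")
        attempts += 1
        take = rng.choice(n, size=size, replace=False)
        try:
            for name in names:
                for h in horizons:
                    aucs[name][h][b] = time_dependent_roc(
                        score_mat[name][take], time[take], event[take], h
                    ).auc
        except ValidationError:
            log.info("replicate %d redrawn (horizon without cases/controls)", b)
            continue
        b += 1

    ref = names[0]
    wilcoxon_p: dict[str, dict[float, float]] = {}
    for name in names[1:]:
        wilcoxon_p[name] = {}
        for h in horizons:
            stat = stats.mannwhitneyu(
                aucs[ref][h], aucs[name][h], alternative="greater"
            )
            wilcoxon_p[name][h] = float(stat.pvalue)
    return RobustnessResult(
        aucs=aucs, wilcoxon_p=wilcoxon_p, reference=ref, fraction=fraction, B=B
    )


def compare_auc_bootstrap(
    rs_a: np.ndarray | pd.Series,
    rs_b: np.ndarray | pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float,
    B: int = 1000,
    seed: int | None = None,
) -> dict:
    """One-sided paired-bootstrap test that score A outperforms score B.

    p = fraction of resamples with AUC_a < AUC_b, ties counted half.
    """
    rs_a = np.asarray(rs_a, dtype=float)
    rs_b = np.asarray(rs_b, dtype=float)
    if rs_a.shape != rs_b.shape:
        raise ValidationError("scores must cover the same patients")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(rs_a)
    rng = np.random.default_rng(seed)
    auc_a = time_dependent_roc(rs_a, time, event, horizon).auc
    auc_b = time_dependent_roc(rs_b, time, event, horizon).auc
    worse = 0.0
    b = 0
    attempts = 0
    while b < B:
        if attempts >= 10 * B:
            raise ValidationError("too many degenerate bootstrap resamples")
        attempts += 1
        take = rng.integers(0, n, size=n)
        try:
            a = time_dependent_roc(rs_a[take], time[take], event[take], horizon).auc
            v = time_dependent_roc(rs_b[take], time[take], event[take], horizon).auc
        except ValidationError:
            continue
        if a < v:
            worse += 1.0
        elif a == v:
            worse += 0.5
        b += 1
    return {"auc_a": float(auc_a), "auc_b": float(auc_b), "p": worse / B, "B": B}


# ---------------------------------------------------------------------------
# Multivariate adjustment, stratified cohorts, drug response, group tests
# ---------------------------------------------------------------------------


def _covariate_frame(cohort: Cohort, scores: dict[str, pd.Series]) -> pd.DataFrame:
    """Binary-encoded clinicopathologic covariates plus signature scores."""
    clin = cohort.clinical
    df = pd.DataFrame(index=clin.index)
    if "age" in clin:
        df["age_ge60"] = (clin["age"] >= 60).astype(float)
    if "gender" in clin:
        df["male"] = (clin["gender"] == "Male").astype(float)
    if "grade" in clin:
        df["grade_high"] = (clin["grade"] == 2).astype(float)
    for name, rs in scores.items():
        df[name] = rs.loc[clin.index].astype(float)
    return df


def _cox_effects(cph: CoxPHFitter, variables: list[str]) -> list[CoxEffect]:
    out = []
    for v in variables:
        s = cph.summary.loc[v]
        out.append(
            CoxEffect(
                v, float(s["coef"]), float(s["exp(coef)"]),
                float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"]),
                float(s["p"]), True,
            )
        )
    return out


def multivariate_cox(
    cohort: Cohort, scores: dict[str, pd.Series]
) -> dict[str, list[CoxEffect]]:
    """Univariate fits per variable and one joint multivariate Cox fit.

    Variables: age >= 60, male vs female, high vs low grade, plus each
    signature score as a continuous covariate.  Patients with missing
    values are dropped listwise (logged).  Collinear variable pairs are
    an error naming the pair.
    """
    df = _covariate_frame(cohort, scores)
    df["time"] = cohort.clinical["survival_time"]
    df["event"] = cohort.clinical["event"]
    complete = df.notna().all(axis=1)
    if (~complete).any():
        log.info("dropping %d patients with missing covariates", int((~complete).sum()))
    df = df[complete]
    variables = [c for c in df.columns if c not in ("time", "event")]
    for v in variables:
        if df[v].nunique() < 2:
            raise ValidationError(f"variable {v!r} has a single level")
    corr = df[variables].corr().abs()
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            if corr.loc[a, b] > 0.999:
                raise ValidationError(f"collinear variables: ({a}, {b})")

    univariate = []
    for v in variables:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[[v, "time", "event"]], duration_col="time", event_col="event")
        univariate.extend(_cox_effects(cph, [v]))
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return {"univariate": univariate, "multivariate": _cox_effects(cph, variables)}


_STRATIFIERS = {
    "age": lambda clin: np.where(clin["age"] <= 60, "age<=60", "age>60"),
    "grade": lambda clin: np.where(clin["grade"] == 2, "high_grade", "low_grade"),
    "pharmaceutical": lambda clin: clin["pharmaceutical"].to_numpy(),
    "radiotherapy": lambda clin: clin["radiotherapy"].to_numpy(),
}


def stratified_km(
    cohort: Cohort,
    stratifier: str,
    rs: pd.Series,
    horizon: float,
    min_per_side: int = 10,
) -> dict[str, dict]:
    """Per-stratum Youden cutoff, K-M curves and log-rank test.

    Strata: age <=60 / >60, low/high grade, or yes/no therapy flags
    (patients with 'unknown' flags are dropped per stratum).
    """
    if stratifier not in _STRATIFIERS:
        raise ValidationError(f"unknown stratifier {stratifier!r}")
    labels = np.asarray(_STRATIFIERS[stratifier](cohort.clinical))
    rs = rs.loc[cohort.clinical.index]
    out: dict[str, dict] = {}
    for stratum in pd.unique(labels):
        if stratum == "unknown":
            continue
        mask = labels == stratum
        if mask.sum() == 0:
            log.info("stratum %s empty, skipped", stratum)
            continue
        t = cohort.time[mask]
        e = cohort.event[mask]
        s = rs.to_numpy()[mask]
        try:
            roc = time_dependent_roc(s, t, e, horizon)
        except ValidationError as exc:
            log.info("stratum %s skipped: %s", stratum, exc)
            continue
        groups = split_by_cutoff(s, roc.cutoff)
        sizes = pd.Series(groups).value_counts()
        if (sizes < min_per_side).any():
            log.warning("stratum %s has a risk group below %d patients", stratum, min_per_side)
        if len(sizes) < 2:
            log.info("stratum %s skipped: single risk group", stratum)
            continue
        res = km_logrank(t, e, groups)
        res["cutoff"] = roc.cutoff
        res["n"] = int(mask.sum())
        out[str(stratum)] = res
    return out


def drug_response_classification(
    cohort: Cohort,
    rs: pd.Series,
    horizon: float,
) -> dict:
    """Surrogate drug-response analysis on the targeted-therapy subset.

    Survival status at the horizon stands in for the latent response
    (alive = sensitive, dead = resistant); patients censored before the
    horizon are excluded (logged).  Classification uses the Youden
    cutoff of the horizon's time-dependent ROC (low risk score =
    predicted sensitive); reports K-M/log-rank of the predicted groups
    and the AUC against the surrogate labels.
    """
    if "targeted_therapy" not in cohort.clinical:
        raise ValidationError("cohort lacks targeted_therapy flag")
    ids = cohort.clinical.index[cohort.clinical["targeted_therapy"] == "yes"]
    if len(ids) == 0:
        raise ValidationError("no targeted-therapy patients")
    sub = cohort.subset(list(ids))
    s = rs.loc[sub.clinical.index].to_numpy(dtype=float)
    t, e = sub.time, sub.event

    labeled = ~((t <= horizon) & (e == 0))
    n_excluded = int((~labeled).sum())
    if n_excluded:
        log.info("excluding %d patients censored before the horizon", n_excluded)
    status_dead = (t <= horizon) & (e == 1)
    if status_dead[labeled].all() or (~status_dead[labeled]).all():
        raise ValidationError("single-class surrogate labels at this horizon")
    labels = np.where(status_dead, "resistant", "sensitive")  # observed outcome

    roc = time_dependent_roc(s, t, e, horizon)
    predicted = np.where(s >= roc.cutoff, "resistant", "sensitive")
    km = km_logrank(t, e, predicted)

    auc = _weighted_auc(
        s[labeled & status_dead], np.ones(int((labeled & status_dead).sum())),
        s[labeled & ~status_dead], np.ones(int((labeled & ~status_dead).sum())),
    )
    return {
        "labels": pd.Series(labels[labeled], index=sub.clinical.index[labeled]),
        "predicted": pd.Series(predicted, index=sub.clinical.index),
        "cutoff": roc.cutoff,
        "km": km,
        "auc": float(auc),
        "n_excluded_censored": n_excluded,
    }


def riskscore_group_comparison(
    rs: pd.Series, annotation: pd.Series, min_group: int = 3
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests of the risk score
    between annotation groups (e.g. IDH1 status or molecular subtype)."""
    annotation = annotation.loc[rs.index]
    counts = annotation.value_counts()
    groups = [g for g in counts.index if counts[g] >= min_group]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups with enough patients")
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            xa = rs[annotation == a]
            xb = rs[annotation == b]
            if xa.nunique() == 1 and xb.nunique() == 1 and xa.iloc[0] == xb.iloc[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
            rows.append({"group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb), "p": p})
    return pd.DataFrame(rows)
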