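"""Risk-signature learning and application.

The central operation is :func:`fit_lasso_cox`: an L1-penalized Cox
proportional-hazards fit over a descending lambda grid with tenfold
cross-validated partial-likelihood deviance (Verweij-van Houwelingen),
selecting lambda at the minimum mean deviance (ties resolved toward the
larger, i.e. sparser, lambda).  The nonzero coefficients at that lambda
are used directly as risk coefficients, without post-selection refit.

Also here: per-gene univariate Cox effects, risk-score application, the
published combined signature, and the two comparison baselines (LASSO
on the full DEG list; correlation-network node-strength selection
followed by an unpenalized Cox refit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from . import published
from .datatypes import AnalysisConfig, Cohort, GeneSignature, ValidationError
from .network import CellGeneNode, _aligned_values

log = logging.getLogger(__name__)


@dataclass
class CoxEffect:
    """One Cox regression effect: beta, HR = exp(beta), 95% CI, Wald p."""

    variable: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool = True


@dataclass
class LassoCoxFit:
    """Full record of a cross-validated L1 Cox path."""

    candidates: list[str]
    alphas: np.ndarray
    coef_path: pd.DataFrame  # genes x alphas
    cv_mean: np.ndarray
    cv_se: np.ndarray
    best_alpha: float
    best_index: int
    lambda_min: float = float("nan")
    lambda_1se: float = float("nan")
    seed: int | None = None
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def log_best_alpha(self) -> float:
        return float(np.log(self.best_alpha))


@dataclass
class RiskScoreResult:
    scores: pd.Series
    signature: str
    missing_genes: list[str]


def _design_matrix(cohort: Cohort, genes: list[str], cfg: AnalysisConfig) -> pd.DataFrame:
    present = set(cohort.expression.index)
    missing = [g for g in genes if g not in present]
    if missing:
        raise ValidationError(f"candidate gene(s) absent from expression: {missing}")
    X = cohort.expression.loc[genes].T.astype(float)
    if cfg.log_transform_expression:
        X = np.log2(X + 1.0)
    return X


def _breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow tie handling."""
    order = np.argsort(-time, kind="mergesort")
    eta_o = eta[order]
    t_o = time[order]
    e_o = event[order].astype(bool)
    m = eta_o.max() if len(eta_o) else 0.0
    cs = np.cumsum(np.exp(eta_o - m))
    # risk-set sum for each subject = cumsum at the last index of its tie run
    last = np.searchsorted(-t_o, -t_o, side="right") - 1
    log_risk = m + np.log(cs[last])
    return float(np.sum(eta_o[e_o]) - np.sum(log_risk[e_o]))


def fit_lasso_cox(
    cohort: Cohort,
    candidates: list[str],
    cfg: AnalysisConfig | None = None,
    name: str = "lasso_cox",
    alphas: np.ndarray | None = None,
) -> tuple[LassoCoxFit, GeneSignature]:
    """L1-penalized Cox fit with tenfold cross-validated lambda selection.

    ``alphas`` overrides the data-derived descending lambda grid (100
    values down to 1e-3 of lambda_max).
    """
    cfg = cfg or AnalysisConfig()
    if not candidates:
        raise ValidationError("candidate gene list is empty")
    if cohort.event.sum() == 0:
        raise ValidationError("cohort has zero events")
    n_events = int(cohort.event.sum())
    if n_events < 10 * cfg.cv_folds:
        log.warning("only %d events for %d-fold CV", n_events, cfg.cv_folds)

    X = _design_matrix(cohort, list(candidates), cfg)
    constant = [g for g in X.columns if X[g].std() == 0.0]
    if constant:
        log.info("dropping %d constant candidate genes", len(constant))
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        fit = LassoCoxFit(
            candidates=list(candidates), alphas=np.array([]),
            coef_path=pd.DataFrame(), cv_mean=np.array([]), cv_se=np.array([]),
            best_alpha=float("nan"), best_index=-1, seed=cfg.rng_seed,
            dropped_constant=constant,
        )
        return fit, GeneSignature(name=name, terms={}, learning_set=cohort.name)

    time, event = cohort.time, cohort.event
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    Xv = X.to_numpy(dtype=float)

    # glmnet-style descending grid from the data-derived lambda_max
    if alphas is None:
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=100, alpha_min_ratio=1e-3, normalize=True,
            max_iter=100000,
        )
    else:
        alphas = np.sort(np.asarray(alphas, dtype=float))[::-1]
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, normalize=True, max_iter=100000
        )
    path.fit(Xv, y)
    alphas = np.asarray(path.alphas_)

    skf = StratifiedKFold(
        n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.rng_seed
    )
    fold_dev = np.full((cfg.cv_folds, len(alphas)), np.nan)
    ll_all_cache: dict[int, float] = {}
    for k, (train, _test) in enumerate(skf.split(Xv, event)):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, normalize=True, max_iter=100000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xv[train], y[train])
        fitted = np.asarray(model.alphas_)
        coefs = np.asarray(model.coef_)  # p x n_fitted
        for j, alpha in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted - alpha)))
            beta = coefs[:, jj]
            eta_all = Xv @ beta
            ll_full = _breslow_loglik(eta_all, time, event)
            ll_train = _breslow_loglik(eta_all[train], time[train], event[train])
            fold_dev[k, j] = -2.0 * (ll_full - ll_train)
    cv_mean = np.nanmean(fold_dev, axis=0)
    cv_se = np.nanstd(fold_dev, axis=0, ddof=1) / np.sqrt(cfg.cv_folds)
    index_min = int(np.argmin(cv_mean))  # grid is descending: first min = larger lambda
    # 1-SE rule: largest lambda within one SE of the minimum (sparser support)
    within = np.flatnonzero(cv_mean <= cv_mean[index_min] + cv_se[index_min])
    index_1se = int(within[0])
    if cfg.lambda_rule == "min":
        best_index = index_min
    elif cfg.lambda_rule == "1se":
        best_index = index_1se
    else:
        raise ValidationError(f"unknown lambda_rule {cfg.lambda_rule!r}")
    best_alpha = float(alphas[best_index])

    coef_path = pd.DataFrame(np.asarray(path.coef_), index=X.columns, columns=alphas)
    beta_best = coef_path.iloc[:, best_index]
    terms = {g: float(b) for g, b in beta_best.items() if b != 0.0}
    fit = LassoCoxFit(
        candidates=list(candidates), alphas=alphas, coef_path=coef_path,
        cv_mean=cv_mean, cv_se=cv_se, best_alpha=best_alpha, best_index=best_index,
        lambda_min=float(alphas[index_min]), lambda_1se=float(alphas[index_1se]),
        seed=cfg.rng_seed, dropped_constant=constant,
    )
    sig = GeneSignature(
        name=name, terms=terms,
        lambda_=best_alpha if terms else None, learning_set=cohort.name,
    )
    return fit, sig


def univariate_cox_per_gene(
    cohort: Cohort, genes: list[str], cfg: AnalysisConfig | None = None
) -> list[CoxEffect]:
    """One single-covariate Cox PH fit per gene (HR per unit expression)."""
    cfg = cfg or AnalysisConfig()
    X = _design_matrix(cohort, list(genes), cfg)
    effects = []
    for g in genes:
        df = pd.DataFrame(
            {"x": X[g].to_numpy(), "time": cohort.time, "event": cohort.event}
        )
        if df["x"].std() == 0.0:
            effects.append(CoxEffect(g, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        try:
            cph = CoxPHFitter()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["x"]
            effects.append(
                CoxEffect(
                    g, float(s["coef"]), float(s["exp(coef)"]),
                    float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"]),
                    float(s["p"]), True,
                )
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            effects.append(CoxEffect(g, np.nan, np.nan, np.nan, np.nan, np.nan, False))
    return effects


def apply_signature(sig: GeneSignature, cohort: Cohort, cfg: AnalysisConfig | None = None) -> RiskScoreResult:
    """Per-patient risk score RS = sum_g beta_g x_g over present genes.

    Absent signature genes contribute zero and are reported; no present
    gene at all is an error.
    """
    cfg = cfg or AnalysisConfig()
    present = [g for g in sig.terms if g in cohort.expression.index]
    missing = [g for g in sig.terms if g not in cohort.expression.index]
    if not present:
        raise ValidationError(f"no signature gene of {sig.name!r} present in cohort")
    if missing:
        log.info("signature %s: %d genes absent, contributing 0", sig.name, len(missing))
    X = _design_matrix(cohort, present, cfg)
    beta = np.array([sig.terms[g] for g in present])
    rs = pd.Series(X.to_numpy() @ beta, index=cohort.expression.columns, name="risk_score")
    return RiskScoreResult(scores=rs, signature=sig.name, missing_genes=missing)


def combined_signature(age, grade_code, rs_sig1, rs_sig3):
    """Published combined signature CS over age, grade code (1 or 2) and the
    macrophage (signature 1) and Cheng et al. (signature 3) risk scores."""
    grade = np.asarray(grade_code)
    if not np.isin(grade, (1, 2)).all():
        raise ValidationError("grade_code must be 1 (lower grade) or 2 (high grade)")
    c = published.COMBINED_SIGNATURE_COEFFICIENTS
    return (
        c["age"] * np.asarray(age)
        + c["grade"] * grade
        + c["signature_1"] * np.asarray(rs_sig1)
        + c["signature_3"] * np.asarray(rs_sig3)
    )


def cox_refit_signature(
    cohort: Cohort, genes: list[str], name: str, cfg: AnalysisConfig | None = None
) -> GeneSignature:
    """Unpenalized multivariate Cox fit on a fixed gene list.

    This is how comparison signatures published only as gene lists are
    turned into risk scores on a learning cohort.
    """
    cfg = cfg or AnalysisConfig()
    present = [g for g in genes if g in cohort.expression.index]
    if not present:
        raise ValidationError(f"no gene of signature {name!r} present in cohort")
    dropped = [g for g in genes if g not in cohort.expression.index]
    if dropped:
        log.info("signature %s: dropping %d absent genes", name, len(dropped))
    X = _design_matrix(cohort, present, cfg)
    df = X.copy()
    df["time"] = cohort.time
    df["event"] = cohort.event
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        log.info("signature %s: refit with small ridge after non-convergence", name)
        cph = CoxPHFitter(penalizer=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    terms = {g: float(cph.params_[g]) for g in present}
    return GeneSignature(name=name, terms=terms, learning_set=cohort.name)


def baseline_lasso_all_degs(
    cohort: Cohort, all_deg_genes: list[str], cfg: AnalysisConfig | None = None
) -> tuple[LassoCoxFit, GeneSignature]:
    """Comparison baseline: LASSO Cox trained on the full DEG list."""
    if not all_deg_genes:
        raise ValidationError("DEG gene list is empty")
    return fit_lasso_cox(cohort, all_deg_genes, cfg, name="lasso_all_degs")


def baseline_node_strength_signature(
    exp_norm,
    deg_genes: dict[str, list[str]],
    cohort: Cohort,
    k: int = 12,
    cfg: AnalysisConfig | None = None,
    symbol_map: dict[str, str] | None = None,
) -> tuple[list[tuple[CellGeneNode, float]], GeneSignature]:
    """Comparison baseline: node-strength ranking in an unthresholded
    weighted correlation network over the full Veh+Ep+Reb sample set.

    Node strength is the sum of |PCC| with every other DEG node (both
    compartments, no edge threshold).  The top-k nodes (ties broken
    lexicographically) give a gene set refit by unpenalized Cox on the
    learning cohort.
    """
    cfg = cfg or AnalysisConfig()
    pair_ids = exp_norm.pair_ids()
    values = _aligned_values(exp_norm, deg_genes, pair_ids).dropna()
    nodes = [CellGeneNode(g, c) for g, c in values.index]
    if k > len(nodes):
        raise ValidationError(f"k={k} exceeds node count {len(nodes)}")
    mat = values.to_numpy(dtype=float)
    keep = mat.std(axis=1) > 0
    r = np.corrcoef(mat[keep])
    strengths_kept = np.abs(r).sum(axis=1) - 1.0  # drop the self-correlation
    strengths = np.zeros(len(nodes))
    strengths[np.flatnonzero(keep)] = strengths_kept
    ranking = sorted(
        zip(nodes, strengths), key=lambda t: (-t[1], t[0].gene, t[0].compartment)
    )
    top = ranking[:k]
    if symbol_map is not None:
        symbol_map = {a.upper(): b.upper() for a, b in symbol_map.items()}
        symbols = list(dict.fromkeys(
            symbol_map[n.gene.upper()] for n, _ in top if n.gene.upper() in symbol_map
        ))
    else:
        symbols = list(dict.fromkeys(n.gene.upper() for n, _ in top))
    sig = cox_refit_signature(cohort, symbols, name="node_strength", cfg=cfg)
    return ranking, sig
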