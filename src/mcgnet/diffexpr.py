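"""Vehicle-normalized differential expression between Rebound and Endpoint.

Per compartment, every sample value is divided by the gene's mean over
the Vehicle samples of that compartment; Rebound-vs-Endpoint fold
changes are ratios of group means of the normalized values, and p-values
come from a Welch t-test on log2(normalized + eps), BH-adjusted within
compartment.  A DEG satisfies |FC| > 1.5 (strict, symmetric on the log
scale) and adjusted p < 0.05 (strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import AnalysisConfig, CompartmentExperiment, ValidationError

log = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "compartment", "fc", "log2_fc", "p", "adj_p", "is_deg"]


def vehicle_normalize(exp: CompartmentExperiment) -> CompartmentExperiment:
    """Divide each gene's values by its Vehicle-group mean, per compartment.

    Genes whose Vehicle mean is zero in a compartment are dropped there
    (their values become NaN in that compartment's columns, logged).
    """
    expr = exp.expression.copy().astype(float)
    for comp in ("TC", "TAM"):
        veh_cols = exp.sample_ids(compartment=comp, group="Veh")
        if not veh_cols:
            raise ValidationError(f"no Vehicle samples in compartment {comp}")
        comp_cols = exp.sample_ids(compartment=comp)
        veh_mean = exp.expression[veh_cols].mean(axis=1)
        zero = veh_mean == 0
        if zero.any():
            log.info(
                "dropping %d genes with zero Vehicle mean in %s", int(zero.sum()), comp
            )
        denom = veh_mean.replace(0, np.nan)
        expr[comp_cols] = exp.expression[comp_cols].div(denom, axis=0)
    return CompartmentExperiment(expression=expr, samples=exp.samples.copy(), normalized=True)


def select_degs(exp_norm: CompartmentExperiment, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Rebound-vs-Endpoint DEG table, sorted by |log2 FC| descending.

    Returns a DataFrame with one row per (gene, compartment): ratio-scale
    fold change, Welch-t p on log2(normalized + eps), BH-adjusted p
    within compartment, and the DEG flag.
    """
    cfg = cfg or AnalysisConfig()
    eps = cfg.log2_epsilon
    frames = []
    for comp in ("TC", "TAM"):
        reb_cols = exp_norm.sample_ids(compartment=comp, group="Reb")
        ep_cols = exp_norm.sample_ids(compartment=comp, group="Ep")
        if len(reb_cols) < 2 or len(ep_cols) < 2:
            raise ValidationError(f"need >= 2 Reb and >= 2 Ep samples in {comp}")
        reb = exp_norm.expression[reb_cols].to_numpy(dtype=float)
        ep = exp_norm.expression[ep_cols].to_numpy(dtype=float)
        keep = ~(np.isnan(reb).any(axis=1) | np.isnan(ep).any(axis=1))

        reb_k, ep_k = reb[keep], ep[keep]
        fc = reb_k.mean(axis=1) / ep_k.mean(axis=1)
        log_reb = np.log2(reb_k + eps)
        log_ep = np.log2(ep_k + eps)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_res = stats.ttest_ind(log_reb, log_ep, axis=1, equal_var=False)
        p = np.asarray(t_res.pvalue, dtype=float)
        # degenerate variance: all values identical within both groups
        zero_var = (np.ptp(log_reb, axis=1) == 0) & (np.ptp(log_ep, axis=1) == 0)
        equal_mean = log_reb[:, 0] == log_ep[:, 0]
        degenerate = zero_var & equal_mean
        if degenerate.any():
            log.info("%d genes with degenerate variance in %s (p set to 1)",
                     int(degenerate.sum()), comp)
        p[degenerate] = 1.0
        p[zero_var & ~equal_mean] = 0.0
        p[~np.isfinite(p)] = 1.0
        adj_p = multipletests(p, method="fdr_bh")[1]

        log2_fc = np.log2(fc)
        thr = np.log2(cfg.deg_abs_fc_threshold)
        is_deg = (np.abs(log2_fc) > thr) & (adj_p < cfg.deg_adj_p_threshold)
        frames.append(
            pd.DataFrame(
                {
                    "gene": exp_norm.genes[keep],
                    "compartment": comp,
                    "fc": fc,
                    "log2_fc": log2_fc,
                    "p": p,
                    "adj_p": adj_p,
                    "is_deg": is_deg,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        by=["log2_fc"], key=lambda s: s.abs(), ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return out


def top_k_degs(records: pd.DataFrame, k: int) -> dict[str, list[str]]:
    """Top-k DEGs by |log2 FC| per compartment.

    Ties broken by smaller adjusted p, then lexicographic gene symbol.
    Returns fewer than k per compartment when fewer DEGs exist (logged).
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    out: dict[str, list[str]] = {}
    for comp, sub in records.groupby("compartment"):
        degs = sub[sub["is_deg"]].copy()
        degs["abs_l2fc"] = degs["log2_fc"].abs()
        degs = degs.sort_values(
            by=["abs_l2fc", "adj_p", "gene"], ascending=[False, True, True], kind="mergesort"
        )
        if len(degs) < k:
            log.warning("only %d DEGs in %s (requested %d)", len(degs), comp, k)
        out[comp] = list(degs["gene"].head(k))
    return out
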