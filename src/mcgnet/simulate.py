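"""Synthetic data generators with known ground truth.

Two generators drive the test surface of the whole pipeline:

* :func:`simulate_mouse_experiment` emulates a paired TC/TAM RNA-seq
  experiment with Vehicle / Endpoint / Rebound arms (default group sizes
  5 / 6 / 4 animals): log-normal FPKM-like abundances, planted
  Rebound-vs-Endpoint fold changes, and planted "correlation-gained"
  gene pairs whose Rebound samples act as high-leverage points that
  raise a pair's Pearson correlation when a single resistant sample is
  added to the sensitive reference set.

* :func:`simulate_cohort` emulates a glioma patient cohort: log-normal
  expression over a gene universe containing a planted signature, event
  times from a proportional-hazards model on the planted linear
  predictor plus age/grade effects, and independent exponential
  censoring tuned to a target censoring fraction.

Identical seed + truth gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import published
from .datatypes import Cohort, CompartmentExperiment, ValidationError

# ---------------------------------------------------------------------------
# Mouse experiment
# ---------------------------------------------------------------------------


@dataclass
class GainedPair:
    """A planted correlation-gained gene pair.

    ``rho_ep`` / ``rho_reb`` are the latent within-group correlations on
    the log scale.  In Rebound samples the pair's shared latent factor is
    amplified to ``reb_scale`` log units (vs the baseline noise sigma),
    so each single Rebound sample is a high-leverage point lying on the
    pair's own diagonal — adding it to the Endpoint reference samples
    raises the pair's correlation, which is the gained-edge mechanism.
    ``reb_shift`` optionally adds a common Rebound mean shift so the pair
    genes are also differentially expressed (and hence enter the top-k
    DEG node lists in full-pipeline runs).
    """

    gene_a: str
    comp_a: str
    gene_b: str
    comp_b: str
    rho_ep: float = 0.0
    rho_reb: float = 0.998
    reb_scale: float = 5.0
    reb_shift: float = 0.0


@dataclass
class MouseTruth:
    """Ground truth for the synthetic paired-compartment experiment."""

    n_genes: int = 1000
    group_sizes: tuple[int, int, int] = (5, 6, 4)  # Veh, Ep, Reb animals
    noise_sigma: float = 0.2
    base_log_mean: float = 3.0
    base_log_sd: float = 1.0
    deg_fc: dict[str, dict[str, float]] = field(default_factory=dict)  # comp -> gene -> FC
    gained_pairs: list[GainedPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_veh, n_ep, n_reb = self.group_sizes
        if n_ep < 3:
            raise ValidationError("n_Ep < 3: correlation undefined")
        if n_veh < 1 or n_reb < 1:
            raise ValidationError("Veh and Reb groups must be nonempty")
        for p in self.gained_pairs:
            for rho in (p.rho_ep, p.rho_reb):
                if not 0 <= rho <= 1:
                    raise ValidationError("planted |rho| must lie in [0, 1]")
        used: set[tuple[str, str]] = set()
        for p in self.gained_pairs:
            for key in ((p.gene_a, p.comp_a), (p.gene_b, p.comp_b)):
                if key in used:
                    raise ValidationError(f"gene {key} appears in more than one planted pair")
                used.add(key)

    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def mouse_truth_preset(
    n_planted_degs: int = 20,
    n_gained_pairs: int = 10,
    rho_ep: float = 0.0,
    rho_reb: float = 0.998,
    reb_scale: float = 5.0,
    reb_shift: float = 1.5,
    seed: int = 0,
) -> MouseTruth:
    """Default study conditions: 5/6/4 animals, 1000 genes per compartment,
    20 planted DEGs per compartment and 10 planted gained pairs."""
    truth = MouseTruth()
    genes = truth.gene_names()
    rng = np.random.default_rng(seed)
    # planted gained pairs use dedicated genes at the front of the universe
    pairs: list[GainedPair] = []
    comps = [("TC", "TC"), ("TAM", "TAM"), ("TC", "TAM")]
    for i in range(n_gained_pairs):
        ca, cb = comps[i % len(comps)]
        pairs.append(
            GainedPair(
                gene_a=genes[2 * i], comp_a=ca,
                gene_b=genes[2 * i + 1], comp_b=cb,
                rho_ep=rho_ep, rho_reb=rho_reb,
                reb_scale=reb_scale, reb_shift=reb_shift,
            )
        )
    truth.gained_pairs = pairs
    # planted DEGs occupy the next block of genes
    offset = 2 * n_gained_pairs
    deg_fc: dict[str, dict[str, float]] = {"TC": {}, "TAM": {}}
    for comp in ("TC", "TAM"):
        for g in genes[offset: offset + n_planted_degs]:
            fc = float(np.exp(rng.uniform(np.log(1.8), np.log(4.0))))
            if rng.random() < 0.5:
                fc = 1.0 / fc
            deg_fc[comp][g] = fc
        offset += n_planted_degs
    truth.deg_fc = deg_fc
    truth.__post_init__()
    return truth


def diffnet_recovery_truth(
    n_gained_pairs: int = 10,
    n_noise_genes_per_compartment: int = 40,
    rho_ep: float = 0.0,
    rho_reb: float = 0.998,
    reb_scale: float = 5.0,
) -> tuple[MouseTruth, dict[str, list[str]]]:
    """Conditions for the differential-network recovery experiment.

    Only the gained pairs are planted (no fold-change planting), so any
    gained call outside the planted set is a false discovery.  Returns
    the truth and the network node universe: the pair genes plus noise
    genes per compartment.
    """
    truth = mouse_truth_preset(
        n_planted_degs=0, n_gained_pairs=n_gained_pairs,
        rho_ep=rho_ep, rho_reb=rho_reb, reb_scale=reb_scale, reb_shift=0.0,
    )
    genes = truth.gene_names()
    node_genes: dict[str, list[str]] = {"TC": [], "TAM": []}
    for p in truth.gained_pairs:
        node_genes[p.comp_a].append(p.gene_a)
        node_genes[p.comp_b].append(p.gene_b)
    offset = 2 * n_gained_pairs
    for comp in ("TC", "TAM"):
        node_genes[comp] += genes[offset: offset + n_noise_genes_per_compartment]
        offset += n_noise_genes_per_compartment
    return truth, node_genes


def simulate_mouse_experiment(
    truth: MouseTruth, seed: int | None
) -> tuple[CompartmentExperiment, MouseTruth]:
    """Generate the paired TC/TAM expression matrix for a given truth."""
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    n_veh, n_ep, n_reb = truth.group_sizes
    genes = truth.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}

    pair_ids = (
        [f"V{i + 1}" for i in range(n_veh)]
        + [f"E{i + 1}" for i in range(n_ep)]
        + [f"R{i + 1}" for i in range(n_reb)]
    )
    groups = ["Veh"] * n_veh + ["Ep"] * n_ep + ["Reb"] * n_reb
    n_animals = len(pair_ids)

    base_mu = rng.normal(truth.base_log_mean, truth.base_log_sd, size=truth.n_genes)
    sigma = truth.noise_sigma

    # per-compartment log-expression, genes x animals
    log_x = {
        comp: np.tile(base_mu[:, None], (1, n_animals))
        + rng.normal(0.0, sigma, size=(truth.n_genes, n_animals))
        for comp in ("TC", "TAM")
    }

    # planted fold changes: shift the Reb log-mean by log(FC) relative to Ep
    is_reb = np.array([g == "Reb" for g in groups])
    for comp, fcs in truth.deg_fc.items():
        for g, fc in fcs.items():
            log_x[comp][gene_idx[g], is_reb] += math.log(fc)

    # planted gained pairs: shared latent factor per group; the Rebound
    # factor is amplified to reb_scale log units (leverage mechanism)
    group_arr = np.array(groups)
    for pair in truth.gained_pairs:
        for grp, rho, scale in (
            ("Ep", pair.rho_ep, sigma),
            ("Reb", pair.rho_reb, pair.reb_scale),
        ):
            mask = group_arr == grp
            n = int(mask.sum())
            z = rng.normal(0.0, 1.0, size=n)
            for gene, comp in ((pair.gene_a, pair.comp_a), (pair.gene_b, pair.comp_b)):
                i = gene_idx[gene]
                eps = rng.normal(0.0, 1.0, size=n)
                log_x[comp][i, mask] = (
                    base_mu[i]
                    + scale * (math.sqrt(rho) * z + math.sqrt(1.0 - rho) * eps)
                )
        if pair.reb_shift != 0.0:
            for gene, comp in ((pair.gene_a, pair.comp_a), (pair.gene_b, pair.comp_b)):
                log_x[comp][gene_idx[gene], is_reb] += pair.reb_shift

    columns: list[str] = []
    meta_rows = []
    blocks = []
    for comp in ("TC", "TAM"):
        for j, pid in enumerate(pair_ids):
            columns.append(f"{pid}_{comp}")
            meta_rows.append({"compartment": comp, "group": groups[j], "pair_id": pid})
        blocks.append(np.exp(log_x[comp]))
    expr = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=pd.Index(genes, name="gene"), columns=columns
    )
    samples = pd.DataFrame(meta_rows, index=pd.Index(columns, name="sample_id"))
    return CompartmentExperiment(expression=expr, samples=samples), truth


# ---------------------------------------------------------------------------
# Patient cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortTruth:
    """Ground truth for the synthetic survival cohort.

    The hazard model is ``h(t) = h0 * exp(eta)`` with
    ``eta = sum_g beta_g x_g + beta_age60 1[age>=60] + beta_grade (grade - 1)``
    where ``x_g`` are the stored (raw, log-normal) expression values, so a
    Cox fit on stored expression recovers the planted coefficients.
    """

    signature: dict[str, float] = field(default_factory=dict)
    n_genes: int = 2000
    log_mu: float = 0.0
    log_sigma: float = 0.5
    baseline_hazard: float = 0.25  # events per year
    censoring_fraction: float = 0.3
    beta_age60: float = math.log(1.9)  # effect of age >= 60 (indicator)
    beta_grade: float = 0.8  # per grade step (1 -> 2)
    fraction_high_grade: float = 0.5
    fraction_targeted_therapy: float = 0.4
    annotation_association: float = 0.8
    candidate_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("baseline_hazard", "log_sigma"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.censoring_fraction < 1:
            raise ValidationError("censoring_fraction must lie in [0, 1)")

    def gene_universe(self) -> list[str]:
        """Planted signature genes, published comparison-signature genes,
        then filler genes up to ``n_genes``."""
        named = list(dict.fromkeys(
            list(self.signature)
            + published.EGFR_SIGNATURE_GENES
            + published.CHENG_SIGNATURE_GENES
            + published.IGF1_SIGNATURE_GENES
        ))
        n_fill = self.n_genes - len(named)
        if n_fill < 0:
            raise ValidationError("n_genes smaller than the named gene set")
        return named + [f"G{i + 1:05d}" for i in range(n_fill)]


def cohort_truth_preset(
    effect_size: float = 0.9,
    n_genes: int = 2000,
    n_noise_candidates: int = 17,
    null: bool = False,
) -> CohortTruth:
    """Planted 12-gene signature with the published coefficient signs and a
    uniform magnitude calibrated to give ~0.9 validation 5-year AUC.

    ``null=True`` zeroes every effect (survival independent of expression
    and covariates).  ``candidate_genes`` lists the 12 planted genes plus
    ``n_noise_candidates`` null genes — the synthetic analog of the
    29-gene differential-network candidate list.
    """
    signs = {g: math.copysign(1.0, b) for g, b in published.MACROPHAGE_SIGNATURE_TERMS.items()}
    if null:
        signature = {g: 0.0 for g in signs}
        beta_age60, beta_grade = 0.0, 0.0
    else:
        signature = {g: s * effect_size for g, s in signs.items()}
        beta_age60, beta_grade = math.log(1.9), 0.8
    truth = CohortTruth(
        signature=signature, n_genes=n_genes,
        beta_age60=beta_age60, beta_grade=beta_grade,
    )
    import re

    universe = truth.gene_universe()
    filler = [g for g in universe if re.fullmatch(r"G\d{5}", g)]
    truth.candidate_genes = list(signature) + filler[:n_noise_candidates]
    return truth


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving mean P(C < T) = target.

    For exponential event time with rate h and censoring rate g,
    P(censored) = g / (g + h); solve mean over patients by bisection.
    """
    if target <= 0:
        return 0.0

    def frac(g: float) -> float:
        return float(np.mean(g / (g + hazards)))

    lo, hi = 1e-10, 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_cohort(
    truth: CohortTruth, n_patients: int, seed: int | None, name: str = "synthetic"
) -> tuple[Cohort, CohortTruth]:
    """Generate a patient cohort from a proportional-hazards truth."""
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    if n_patients < 20:
        raise ValidationError("n_patients must be >= 20")
    rng = np.random.default_rng(seed)

    universe = truth.gene_universe()
    missing = [g for g in truth.signature if g not in set(universe)]
    if missing:
        raise ValidationError(f"signature genes absent from universe: {missing}")
    gene_idx = {g: i for i, g in enumerate(universe)}

    log_expr = rng.normal(truth.log_mu, truth.log_sigma, size=(len(universe), n_patients))
    expr = np.exp(log_expr)

    age = np.clip(rng.normal(55.0, 12.0, size=n_patients), 20.0, 89.0)
    grade = np.where(rng.random(n_patients) < truth.fraction_high_grade, 2, 1)
    gender = np.where(rng.random(n_patients) < 0.55, "Male", "Female")

    eta = np.zeros(n_patients)
    for g, b in truth.signature.items():
        if b != 0.0:
            eta += b * expr[gene_idx[g]]
    eta = eta - eta.mean() if truth.signature else eta
    eta += truth.beta_age60 * (age >= 60.0) + truth.beta_grade * (grade - 1)

    hazards = truth.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / hazards)
    gamma = _solve_censoring_rate(hazards, truth.censoring_fraction)
    if gamma > 0:
        t_cens = rng.exponential(1.0 / gamma, size=n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)

    def tri_state(frac_yes: float, frac_unknown: float = 0.05) -> np.ndarray:
        u = rng.random(n_patients)
        out = np.where(u < frac_yes, "yes", "no").astype(object)
        out[rng.random(n_patients) < frac_unknown] = "unknown"
        return out

    def annotated(levels: list[str]) -> np.ndarray:
        latent = truth.annotation_association * (eta - eta.mean()) / (eta.std() + 1e-12)
        latent = latent + rng.normal(0.0, 1.0, size=n_patients)
        qs = np.quantile(latent, np.linspace(0, 1, len(levels) + 1)[1:-1])
        return np.array(levels)[np.searchsorted(qs, latent)]

    patient_ids = [f"P{i + 1:04d}" for i in range(n_patients)]
    clinical = pd.DataFrame(
        {
            "survival_time": time,
            "event": event,
            "age": age,
            "gender": gender,
            "grade": grade,
            "targeted_therapy": tri_state(truth.fraction_targeted_therapy),
            "pharmaceutical": tri_state(0.5),
            "radiotherapy": tri_state(0.6),
            "IDH1": annotated(["Mutant", "Wildtype"]),
            "CIMP": annotated(["CIMP+", "CIMP-"]),
            "EGFR": annotated(["Mutant", "Wildtype"]),
            "PTEN": annotated(["Mutant", "Wildtype"]),
            "subtype": annotated(["Proneural", "Neural", "Classical", "Mesenchymal"]),
        },
        index=pd.Index(patient_ids, name="patient_id"),
    )
    expr_df = pd.DataFrame(
        expr, index=pd.Index(universe, name="gene"), columns=patient_ids
    )
    return Cohort(expression=expr_df, clinical=clinical, name=name), truth
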