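"""Core domain types for the multicellular network pipeline.

The pipeline operates on two kinds of datasets:

* a paired-compartment animal experiment (:class:`CompartmentExperiment`)
  in which each animal contributes a tumor-cell (TC) and a
  tumor-associated-macrophage (TAM) expression profile, grouped into
  Vehicle / Endpoint (drug-sensitive) / Rebound (drug-resistant) arms, and
* patient cohorts (:class:`Cohort`) carrying expression, survival and
  clinicopathologic covariates, used to learn and validate risk signatures.

All expression matrices are pandas DataFrames with gene symbols as the row
index and sample/patient identifiers as columns.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("TC", "TAM")
GROUPS = ("Veh", "Ep", "Reb")


class ValidationError(ValueError):
    """Raised when a typed object violates its invariants."""


@dataclass
class CompartmentExperiment:
    """Paired TC/TAM expression with Veh/Ep/Reb group labels.

    Parameters
    ----------
    expression : DataFrame
        Nonnegative FPKM-like abundances; rows are gene symbols, columns
        are sample IDs (one column per gene x compartment profile).
    samples : DataFrame
        Per-column metadata indexed by sample ID with columns
        ``compartment`` ({TC, TAM}), ``group`` ({Veh, Ep, Reb}) and
        ``pair_id`` linking each TC column to its TAM counterpart.
    normalized : bool
        True after vehicle normalization; relaxes the nonnegativity check
        to allow NaN markers for genes dropped in one compartment.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.expression.columns.duplicated().any():
            dups = self.expression.columns[self.expression.columns.duplicated()]
            raise ValidationError(f"duplicate sample IDs: {sorted(set(dups))}")
        if not self.expression.columns.equals(self.samples.index):
            missing = set(self.expression.columns) ^ set(self.samples.index)
            raise ValidationError(
                f"expression columns and sample metadata disagree: {sorted(missing)[:5]}"
            )
        for col in ("compartment", "group", "pair_id"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample table lacks required column {col!r}")
        bad_comp = set(self.samples["compartment"]) - set(COMPARTMENTS)
        if bad_comp:
            raise ValidationError(f"unknown compartments: {sorted(bad_comp)}")
        bad_grp = set(self.samples["group"]) - set(GROUPS)
        if bad_grp:
            raise ValidationError(f"unknown groups: {sorted(bad_grp)}")
        values = self.expression.to_numpy(dtype=float)
        if self.normalized:
            if np.isinf(values).any():
                raise ValidationError("expression contains infinite values")
        else:
            if not np.isfinite(values).all():
                raise ValidationError("expression contains non-finite values")
            if (values < 0).any():
                raise ValidationError("expression contains negative values")
        # each pairing ID maps to exactly one TC and one TAM column
        for pair_id, sub in self.samples.groupby("pair_id"):
            comps = sorted(sub["compartment"])
            if comps != ["TAM", "TC"]:
                raise ValidationError(
                    f"pair_id {pair_id!r} does not link exactly one TC and one TAM column"
                )

    # -- convenience accessors -------------------------------------------------

    def sample_ids(self, compartment: str | None = None, group: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if compartment is not None:
            mask &= self.samples["compartment"] == compartment
        if group is not None:
            mask &= self.samples["group"] == group
        return list(self.samples.index[mask])

    def pair_ids(self, group: str | None = None) -> list[str]:
        """Pairing IDs (animals), optionally restricted to one group."""
        sub = self.samples if group is None else self.samples[self.samples["group"] == group]
        seen: dict[str, None] = {}
        for pid in sub["pair_id"]:
            seen.setdefault(pid, None)
        return list(seen)

    def column_for(self, pair_id: str, compartment: str) -> str:
        sub = self.samples[
            (self.samples["pair_id"] == pair_id)
            & (self.samples["compartment"] == compartment)
        ]
        if len(sub) != 1:
            raise KeyError(f"no unique column for pair {pair_id!r} / {compartment}")
        return sub.index[0]

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.pair_ids(group=g)) for g in GROUPS}


@dataclass
class Cohort:
    """Patient cohort: expression plus survival and clinical covariates.

    ``clinical`` is indexed by patient ID and must contain
    ``survival_time`` (> 0, units given by ``time_units``) and ``event``
    (1 = death, 0 = censored).  Optional columns: ``age``, ``gender``
    ({Male, Female}), ``grade`` (1 = lower grade, 2 = high grade),
    tri-state therapy flags (``targeted_therapy``, ``pharmaceutical``,
    ``radiotherapy`` in {yes, no, unknown}) and annotation columns
    (``IDH1``, ``CIMP``, ``EGFR``, ``PTEN``, ``subtype``).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    name: str = "cohort"
    time_units: str = "years"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.expression.columns.duplicated().any():
            dups = self.expression.columns[self.expression.columns.duplicated()]
            raise ValidationError(f"duplicate patient IDs: {sorted(set(dups))}")
        if not self.expression.columns.equals(self.clinical.index):
            missing = set(self.expression.columns) ^ set(self.clinical.index)
            raise ValidationError(
                f"expression columns and clinical index disagree: {sorted(missing)[:5]}"
            )
        for col in ("survival_time", "event"):
            if col not in self.clinical.columns:
                raise ValidationError(f"clinical table lacks required column {col!r}")
        t = self.clinical["survival_time"].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t <= 0).any():
            raise ValidationError("survival_time must be finite and > 0")
        ev = set(self.clinical["event"].astype(int))
        if not ev <= {0, 1}:
            raise ValidationError(f"event must be 0/1, found {sorted(ev - {0, 1})}")
        idx = self.expression.index
        if not idx.equals(idx.str.upper().str.strip()):
            raise ValidationError("gene symbols must be uppercase-normalized")

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.clinical["survival_time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.clinical["event"].to_numpy(dtype=int)

    def horizon_in_time_units(self, years: float) -> float:
        """Convert a horizon expressed in years into the cohort's time units."""
        factor = {"years": 1.0, "months": 12.0, "days": 365.25}
        if self.time_units not in factor:
            raise ValidationError(f"unknown time_units {self.time_units!r}")
        return years * factor[self.time_units]

    def subset(self, patient_ids: Sequence[str], name: str | None = None) -> "Cohort":
        ids = list(patient_ids)
        return Cohort(
            expression=self.expression[ids],
            clinical=self.clinical.loc[ids],
            name=name or self.name,
            time_units=self.time_units,
        )


@dataclass
class AnalysisConfig:
    """All numeric cutoffs used by the pipeline, with their published defaults.

    Attributes
    ----------
    deg_abs_fc_threshold : float
        DEG call requires |FC| > this ratio (strict), symmetric on the
        log scale (FC > 1.5 or FC < 1/1.5).
    edge_abs_pcc_threshold, edge_p_threshold : float
        An edge requires |PCC| > 0.95 and p < 0.05 (both strict).
    delta_pcc_threshold : float
        Differential-edge call requires |dPCC| > 0.05 per perturbation.
    min_perturbations : int
        Robust edges must exceed the dPCC threshold, with consistent sign,
        in at least this many perturbation networks.
    """

    deg_abs_fc_threshold: float = 1.5
    deg_adj_p_threshold: float = 0.05
    top_k_per_compartment: int = 50
    edge_abs_pcc_threshold: float = 0.95
    edge_p_threshold: float = 0.05
    delta_pcc_threshold: float = 0.05
    min_perturbations: int = 3
    cv_folds: int = 10
    lambda_rule: str = "min"  # "min" (minimum CV deviance) or "1se"
    n_random_signatures: int = 1000
    random_signature_size: int = 12
    robustness_fraction: float = 0.5
    robustness_reps: int = 100
    roc_horizons: tuple[float, ...] = (3.0, 5.0)  # years
    overall_horizon_quantile: float = 0.75
    log2_epsilon: float = 0.01
    use_normalized_for_pcc: bool = True
    log_transform_expression: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        positive = (
            "deg_abs_fc_threshold",
            "deg_adj_p_threshold",
            "top_k_per_compartment",
            "edge_abs_pcc_threshold",
            "edge_p_threshold",
            "delta_pcc_threshold",
            "min_perturbations",
            "cv_folds",
            "n_random_signatures",
            "random_signature_size",
            "robustness_reps",
            "log2_epsilon",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.robustness_fraction <= 1:
            raise ValidationError("robustness_fraction must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(d)
        if "roc_horizons" in cfg:
            cfg["roc_horizons"] = tuple(float(h) for h in cfg["roc_horizons"])
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roc_horizons"] = list(self.roc_horizons)
        return d


@dataclass
class GeneSignature:
    """A gene -> coefficient mapping defining a linear risk score.

    The risk score of a patient is the linear predictor
    ``RS = sum_g beta_g * x_g`` over the signature genes present in the
    expression matrix.  ``lambda_`` records the penalty at which a
    penalized fit selected the terms (None for unpenalized refits or
    published fixed signatures).
    """

    name: str
    terms: dict[str, float]
    lambda_: float | None = None
    learning_set: str | None = None
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # an empty term set is legal in memory (a fully-penalized fit);
        # serialization requires >= 1 term
        genes = list(self.terms)
        if len(set(genes)) != len(genes):
            raise ValidationError("signature contains duplicate genes")
        for g, b in self.terms.items():
            if not math.isfinite(b):
                raise ValidationError(f"non-finite coefficient for {g}")
        if self.lambda_ is not None and self.lambda_ <= 0:
            raise ValidationError("lambda must be > 0 when present")

    @property
    def genes(self) -> list[str]:
        return list(self.terms)

    @property
    def log_lambda(self) -> float | None:
        return None if self.lambda_ is None else math.log(self.lambda_)

    def __len__(self) -> int:
        return len(self.terms)
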