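"""Published fixed signatures and the combined-signature coefficients.

The macrophage-related 12-gene signature ships with its published Cox
coefficients and per-gene compartment tags (MPHI = macrophage, TC = tumor
cell).  The three comparison signatures are published gene *lists* whose
coefficients were never printed; they are refit by unpenalized
multivariate Cox on a learning cohort (see
:func:`mcgnet.signature.cox_refit_signature`).
"""

from __future__ import annotations

from .datatypes import GeneSignature

# Signature 1: macrophage-related 12-gene signature (published coefficients).
MACROPHAGE_SIGNATURE_TERMS: dict[str, float] = {
    "ANPEP": 0.001695826,
    "DPP4": 0.001351164,
    "PRRG1": 0.828492221,
    "GPNMB": 0.002693736,
    "TMEM26": 0.572250065,
    "PXDN": 0.011112329,
    "CDH6": 0.000861924,
    "SCN3A": -0.877296902,
    "SEMA6B": -0.042307865,
    "CCDC37": 0.019673956,
    "FANCA": 1.184362541,
    "NETO2": 0.101032334,
}

MACROPHAGE_SIGNATURE_COMPARTMENTS: dict[str, str] = {
    "ANPEP": "MPHI",
    "DPP4": "MPHI",
    "PRRG1": "MPHI",
    "GPNMB": "MPHI",
    "TMEM26": "MPHI",
    "PXDN": "TC",
    "CDH6": "TC",
    "SCN3A": "TC",
    "SEMA6B": "TC",
    "CCDC37": "TC",
    "FANCA": "TC",
    "NETO2": "TC",
}

# Optimal LASSO penalty reported for the 12-gene fit.
PUBLISHED_LAMBDA = 0.06226413
PUBLISHED_LOG_LAMBDA = -2.77637

# Signature 2: conventional EGFR signature (single-gene list; score by Cox refit).
EGFR_SIGNATURE_GENES: list[str] = ["EGFR"]

# Signature 3: Cheng et al. immune-related signature (gene list).
CHENG_SIGNATURE_GENES: list[str] = [
    "FOXO3", "IL6", "IL10", "ZBTB16", "CCL18", "AIMP1", "FCGR2B", "MMP9",
]

# Signature 4: IGF1/IGF1R-mediated macrophage-glioma pathway gene families.
IGF1_SIGNATURE_GENES: list[str] = [
    "PIK3R1", "PIK3R2", "PIK3R3", "PIK3R4", "PIK3R5", "PIK3R6", "PIK3AP1",
    "AKT1", "AKT2", "AKT3", "IGF1", "IGF1R", "IL4", "IL4R",
    "NFATC1", "NFATC2", "NFATC3", "NFATC4", "NFAT5", "STAT6", "CSF1", "CSF1R",
]

# Combined signature: CS = a*Age + b*Grade + c*Signature1 + d*Signature3,
# Grade coded 1 (lower grade) / 2 (high grade).
COMBINED_SIGNATURE_COEFFICIENTS: dict[str, float] = {
    "age": 0.008974621,
    "grade": 1.617859481,
    "signature_1": 0.940077644,
    "signature_3": 0.006408624,
}


def macrophage_signature() -> GeneSignature:
    """The published 12-gene macrophage-related signature as a GeneSignature."""
    return GeneSignature(
        name="macrophage_12gene",
        terms=dict(MACROPHAGE_SIGNATURE_TERMS),
        lambda_=PUBLISHED_LAMBDA,
        learning_set="published",
        compartments=dict(MACROPHAGE_SIGNATURE_COMPARTMENTS),
    )
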