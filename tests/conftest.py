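import numpy as np
import pandas as pd
import pytest

from mcgnet import simulate
from mcgnet.datatypes import AnalysisConfig, Cohort, CompartmentExperiment


def make_experiment(values: dict[str, dict[str, list[float]]], groups: list[str]):
    """Build a small paired experiment from per-compartment gene rows.

    ``values[comp][gene]`` is one value per animal; ``groups`` assigns
    each animal to Veh/Ep/Reb.
    """
    n = len(groups)
    pair_ids = [f"A{i + 1}" for i in range(n)]
    columns, meta, rows = [], [], {}
    genes = sorted({g for comp in values.values() for g in comp})
    for comp in ("TC", "TAM"):
        for i, pid in enumerate(pair_ids):
            col = f"{pid}_{comp}"
            columns.append(col)
            meta.append({"compartment": comp, "group": groups[i], "pair_id": pid})
    data = np.zeros((len(genes), len(columns)))
    for j, col in enumerate(columns):
        comp = col.split("_")[1]
        i_animal = int(col.split("_")[0][1:]) - 1
        for gi, g in enumerate(genes):
            data[gi, j] = values.get(comp, {}).get(g, [1.0] * n)[i_animal]
    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=columns)
    samples = pd.DataFrame(meta, index=pd.Index(columns, name="sample_id"))
    return CompartmentExperiment(expression=expr, samples=samples)


@pytest.fixture(scope="session")
def mouse_default():
    truth = simulate.mouse_truth_preset(seed=0)
    exp, truth = simulate.simulate_mouse_experiment(truth, seed=7)
    return exp, truth


@pytest.fixture(scope="session")
def planted_cohorts():
    """Learning (n=310) and validation (n=690) cohorts with the planted
    12-gene signature, plus the truth."""
    truth = simulate.cohort_truth_preset()
    learn, _ = simulate.simulate_cohort(truth, 310, seed=11, name="learning")
    valid, _ = simulate.simulate_cohort(truth, 690, seed=12, name="validation")
    return learn, valid, truth


@pytest.fixture()
def cfg():
    return AnalysisConfig(rng_seed=0)


def truth_signature(truth):
    """GeneSignature carrying the generator's planted coefficients."""
    from mcgnet.datatypes import GeneSignature

    return GeneSignature(name="planted", terms=dict(truth.signature))


def toy_cohort(n=40, seed=0, censor=0.0):
    """Tiny cohort with independent expression and exponential survival."""
    rng = np.random.default_rng(seed)
    genes = [f"T{i}" for i in range(5)]
    expr = pd.DataFrame(
        rng.lognormal(0.0, 0.5, size=(5, n)),
        index=pd.Index(genes, name="gene"),
        columns=[f"P{i}" for i in range(n)],
    )
    t = rng.exponential(2.0, size=n)
    event = (rng.random(n) >= censor).astype(int)
    clinical = pd.DataFrame(
        {
            "survival_time": t,
            "event": event,
            "age": rng.normal(55, 10, size=n),
            "gender": np.where(rng.random(n) < 0.5, "Male", "Female"),
            "grade": rng.integers(1, 3, size=n),
        },
        index=expr.columns,
    )
    return Cohort(expression=expr, clinical=clinical, name="toy")
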