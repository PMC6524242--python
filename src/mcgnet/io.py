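"""Readers and writers for expression tables, signatures and networks.

Expression tables are delimited text (TSV by default, CSV detected from
the extension) with a header row of sample/patient IDs and gene symbols
in the first column.  Compartment experiments take a sample sidecar
(``sample_id, compartment, group, pair_id``); cohorts take a clinical
sidecar keyed by patient ID.  Signatures round-trip through JSON;
networks export as edge-list TSV or GraphML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import Cohort, CompartmentExperiment, GeneSignature, ValidationError

log = logging.getLogger(__name__)


def _read_delimited(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # pandas silently mangles duplicated header IDs, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    ids = header[1:] if index_col == 0 else header
    seen: set[str] = set()
    dups = {h for h in ids if h in seen or seen.add(h)}
    if dups:
        raise ValidationError(f"duplicated column ID(s) in {path.name}: {sorted(dups)}")
    return pd.read_csv(path, sep=sep, index_col=index_col)


def _normalize_gene_index(expr: pd.DataFrame) -> pd.DataFrame:
    """Uppercase/strip gene symbols; collapse duplicates by mean (logged)."""
    expr = expr.copy()
    expr.index = expr.index.astype(str).str.strip().str.upper()
    if expr.index.duplicated().any():
        n_dup = int(expr.index.duplicated().sum())
        log.info("collapsing %d duplicate gene symbols by mean", n_dup)
        expr = expr.groupby(level=0, sort=False).mean()
    return expr


def read_compartment_experiment(
    expr_path: str | Path, samples_path: str | Path
) -> CompartmentExperiment:
    """Read a paired TC/TAM experiment from an expression table + sample sidecar."""
    expr = _read_delimited(expr_path)
    if expr.columns.duplicated().any():
        dup = sorted(set(expr.columns[expr.columns.duplicated()]))
        raise ValidationError(f"duplicated sample column ID(s): {dup}")
    bad = expr.columns[~expr.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValidationError(f"non-numeric expression cells in column(s): {list(bad)}")
    expr = _normalize_gene_index(expr.astype(float))

    samples = _read_delimited(samples_path)
    samples.index = samples.index.astype(str)
    missing = set(expr.columns) ^ set(samples.index)
    if missing:
        raise ValidationError(
            f"sample sidecar does not match expression columns: {sorted(missing)}"
        )
    samples = samples.loc[expr.columns]
    return CompartmentExperiment(expression=expr, samples=samples)


def read_cohort(
    expr_path: str | Path,
    clinical_path: str | Path,
    name: str = "cohort",
    time_units: str = "years",
) -> Cohort:
    """Read a patient cohort, keeping the patient-ID intersection.

    Patients present in only one of the two tables are dropped (counts
    logged); patients missing survival_time or event are dropped as well.
    """
    expr = _read_delimited(expr_path)
    if expr.columns.duplicated().any():
        dup = sorted(set(expr.columns[expr.columns.duplicated()]))
        raise ValidationError(f"duplicated patient column ID(s): {dup}")
    expr = _normalize_gene_index(expr.astype(float))

    clin = _read_delimited(clinical_path)
    clin.index = clin.index.astype(str)
    if clin.index.duplicated().any():
        dup = sorted(set(clin.index[clin.index.duplicated()]))
        raise ValidationError(f"duplicated clinical patient ID(s): {dup}")

    shared = [p for p in expr.columns if p in set(clin.index)]
    n_expr_only = expr.shape[1] - len(shared)
    n_clin_only = clin.shape[0] - len(shared)
    if n_expr_only or n_clin_only:
        log.info(
            "patient-ID intersection: kept %d, dropped %d expression-only and %d clinical-only",
            len(shared), n_expr_only, n_clin_only,
        )
    if not shared:
        raise ValidationError("no patient IDs shared between expression and clinical tables")
    clin = clin.loc[shared]

    usable = clin["survival_time"].notna() & clin["event"].notna()
    if (~usable).any():
        log.info("dropping %d patients missing survival_time/event", int((~usable).sum()))
    kept = list(clin.index[usable])
    return Cohort(
        expression=expr[kept], clinical=clin.loc[kept], name=name, time_units=time_units
    )


def read_expression_table(
    expr_path: str | Path,
    sidecar_path: str | Path,
    schema: str = "compartment-experiment",
    **kwargs,
) -> CompartmentExperiment | Cohort:
    """Schema-dispatching reader: a paired compartment experiment (with a
    sample sidecar) or a patient cohort (with a clinical sidecar)."""
    if schema == "compartment-experiment":
        return read_compartment_experiment(expr_path, sidecar_path)
    if schema == "cohort":
        return read_cohort(expr_path, sidecar_path, **kwargs)
    raise ValidationError(f"unknown schema {schema!r}")


def write_expression_table(expr: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    expr.to_csv(path, sep=sep, index_label="gene")


# -- signatures ----------------------------------------------------------------


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    if len(sig.terms) == 0:
        raise ValidationError("cannot serialize a signature with no terms")
    payload = {
        "name": sig.name,
        "terms": sig.terms,
        "lambda": sig.lambda_,
        "log_lambda": sig.log_lambda,
        "learning_set": sig.learning_set,
        "compartments": sig.compartments,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _reject_duplicate_keys(pairs):
    keys = [k for k, _ in pairs]
    dups = {k for k in keys if keys.count(k) > 1}
    if dups:
        raise ValidationError(f"duplicate gene(s) in signature: {sorted(dups)}")
    return dict(pairs)


def read_signature(path: str | Path) -> GeneSignature:
    try:
        payload = json.loads(
            Path(path).read_text(), object_pairs_hook=_reject_duplicate_keys
        )
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed signature file {path}: {exc}") from exc
    terms = payload.get("terms", {})
    if not terms:
        raise ValidationError("signature file has no terms")
    return GeneSignature(
        name=payload.get("name", Path(path).stem),
        terms={str(g): float(b) for g, b in terms.items()},
        lambda_=payload.get("lambda"),
        learning_set=payload.get("learning_set"),
        compartments=payload.get("compartments") or {},
    )


# -- networks ------------------------------------------------------------------

_EDGE_COLUMNS = ["node_a", "comp_a", "node_b", "comp_b", "pcc", "p", "edge_kind"]


def export_network_tsv(net, path: str | Path) -> None:
    """Write a network as an edge-list TSV (header-only if edgeless)."""
    rows = []
    for e in net.edges:
        rows.append(
            {
                "node_a": e.node_a.gene, "comp_a": e.node_a.compartment,
                "node_b": e.node_b.gene, "comp_b": e.node_b.compartment,
                "pcc": e.pcc, "p": e.p, "edge_kind": e.kind,
            }
        )
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_network_edges(path: str | Path) -> pd.DataFrame:
    """Read back an edge-list TSV (edge set round-trip; returns a DataFrame)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"edge list {path} lacks columns {sorted(missing)}")
    return df


def export_network_graphml(net, path: str | Path) -> None:
    g = nx.Graph(label=net.label)
    for node in net.nodes:
        g.add_node(f"{node.gene}|{node.compartment}", gene=node.gene,
                   compartment=node.compartment)
    for e in net.edges:
        g.add_edge(
            f"{e.node_a.gene}|{e.node_a.compartment}",
            f"{e.node_b.gene}|{e.node_b.compartment}",
            pcc=float(e.pcc), p=float(e.p), edge_kind=e.kind,
        )
    nx.write_graphml(g, path)


def export_network(net, path: str | Path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        export_network_tsv(net, path)
    elif fmt == "graphml":
        export_network_graphml(net, path)
    else:
        raise ValidationError(f"unknown network format {fmt!r}")
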