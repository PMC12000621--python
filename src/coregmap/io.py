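"""Readers and writers for the pipeline's tabular formats.

TSV is the canonical format everywhere; CSV is accepted on read.
Gene and sample identifiers are opaque strings (no symbol mapping).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cooperativity import CoopEdge, CoRegNetwork
from .grn import GRN, EvidenceSet, RegulatoryProgram
from .influence import InfluenceMatrix

logger = logging.getLogger("coregmap")

__all__ = [
    "read_expression",
    "read_regulators",
    "read_evidence",
    "write_grn",
    "read_grn",
    "write_network",
    "read_network",
    "write_influence",
    "read_influence",
    "read_labels",
]


def _sep_for(path) -> str | None:
    suffix = Path(path).suffix.lower()
    return {"csv": ","}.get(suffix.lstrip("."), "\t")


def read_expression(path, orientation: str = "genes-rows") -> pd.DataFrame:
    """Read a gene × sample expression table.

    Duplicate gene rows are collapsed by mean (logged); duplicate
    sample identifiers are an error. Non-numeric cells other than
    empty/NA raise with their coordinates. ``orientation`` may be
    ``genes-rows`` (default) or ``samples-rows`` (transposed input).
    """
    if orientation not in ("genes-rows", "samples-rows"):
        raise ValueError("orientation must be 'genes-rows' or 'samples-rows'")
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    # undo pandas' silent renaming of duplicate header fields so that
    # duplicate samples are caught and duplicate genes can be collapsed
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    if len(header) - 1 == df.shape[1]:
        df.columns = header[1:]
    if orientation == "samples-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
    bad = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        mask = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip().str.upper() != "NA")
        bad.extend((g, col) for g in df.index[mask])
        df[col] = coerced
    if bad:
        raise ValueError(f"non-numeric cells at (gene, sample): {bad[:5]}")
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        logger.warning("collapsed %d duplicate gene rows by mean", n)
        df = df.groupby(level=0, sort=False).mean()
    return df.astype(float)


def read_regulators(path) -> list:
    """One regulator symbol per line; blanks ignored."""
    lines = Path(path).read_text().splitlines()
    return [s.strip() for s in lines if s.strip()]


def read_evidence(regulation_path=None, cooperation_path=None) -> EvidenceSet:
    """Two-column tables: (regulator, target) and (regulator, regulator)."""

    def pairs(path):
        if path is None:
            return []
        df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns")
        return list(df.iloc[:, :2].itertuples(index=False, name=None))

    return EvidenceSet.from_pairs(pairs(regulation_path), pairs(cooperation_path))


# -- GRN ---------------------------------------------------------------------


def write_grn(grn, path, json_path=None) -> None:
    rows = [
        {
            "target": p.target,
            "activators": ";".join(sorted(p.activators)),
            "inhibitors": ";".join(sorted(p.inhibitors)),
            "rule_score": p.rule_score,
            "r2": p.r2,
            "merged_score": p.merged_score,
        }
        for p in grn
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=1))


def read_grn(path) -> GRN:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"target": str}, keep_default_na=False)
    programs = []
    for i, row in df.iterrows():
        try:
            programs.append(
                RegulatoryProgram(
                    target=row["target"],
                    activators=frozenset(x for x in str(row["activators"]).split(";") if x),
                    inhibitors=frozenset(x for x in str(row["inhibitors"]).split(";") if x),
                    rule_score=float(row["rule_score"]),
                    r2=float(row["r2"]),
                    merged_score=float(row["merged_score"]),
                )
            )
        except (KeyError, ValueError) as err:
            raise ValueError(f"{path}: malformed program at line {i + 2}: {err}") from err
    return GRN(programs=programs)


# -- cooperativity network ---------------------------------------------------


def write_network(net: CoRegNetwork, tsv_path=None, graphml_path=None) -> None:
    if tsv_path is not None:
        rows = [
            {
                "tf_i": e.tf_i,
                "tf_j": e.tf_j,
                "shared_targets": e.shared_targets,
                "jaccard": e.jaccard,
                "p_value": e.p_value,
                "evidence_tag": e.evidence_tag,
            }
            for e in net.edges
        ]
        pd.DataFrame(rows, columns=["tf_i", "tf_j", "shared_targets", "jaccard", "p_value", "evidence_tag"]).to_csv(
            tsv_path, sep="\t", index=False
        )
    if graphml_path is not None:
        g = nx.Graph()
        for node, size in net.nodes.items():
            g.add_node(node, regulon_size=int(size))
        for e in net.edges:
            g.add_edge(
                e.tf_i,
                e.tf_j,
                shared_targets=int(e.shared_targets),
                jaccard=float(e.jaccard),
                p_value=float(e.p_value),
                evidence_tag=e.evidence_tag,
            )
        nx.write_graphml(g, graphml_path)


def read_network(graphml_path) -> CoRegNetwork:
    g = nx.read_graphml(graphml_path)
    nodes = {str(n): int(d.get("regulon_size", 1)) for n, d in g.nodes(data=True)}
    edges = [
        CoopEdge(
            tf_i=str(u),
            tf_j=str(v),
            shared_targets=int(d["shared_targets"]),
            jaccard=float(d["jaccard"]),
            p_value=float(d["p_value"]),
            evidence_tag=str(d.get("evidence_tag", "inferred-only")),
        )
        for u, v, d in g.edges(data=True)
    ]
    return CoRegNetwork(nodes=nodes, edges=edges)


# -- influence ---------------------------------------------------------------


def write_influence(infl: InfluenceMatrix, path, flags_path=None) -> None:
    infl.values.to_csv(path, sep="\t")
    if flags_path is not None:
        infl.provenance.to_csv(flags_path, sep="\t")


def read_influence(path, flags_path=None) -> InfluenceMatrix:
    values = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if flags_path is not None:
        prov = pd.read_csv(flags_path, sep=_sep_for(flags_path), index_col=0)
    else:
        prov = pd.DataFrame("computed", index=values.index, columns=values.columns)
    return InfluenceMatrix(values=values, provenance=prov)


def read_labels(path, column: str | None = None) -> pd.Series:
    """Sample → class table (first column sample id)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    col = column or df.columns[0]
    return df[col]
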