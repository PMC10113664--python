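"""Readers and writers for the pipeline's tab-separated interchange formats.

All files are UTF-8 TSV with a header row, except GMT which follows the
standard gene-set format (set name, description, member genes).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .network import PrescriptionRecord, SymptomRecord

__all__ = [
    "read_prescriptions", "write_prescriptions",
    "read_symptoms", "write_symptoms",
    "read_gmt", "write_gmt",
    "read_interactome_edges", "write_edge_list",
    "read_compound_targets", "write_compound_targets",
    "write_partition",
]


def read_prescriptions(path) -> list:
    """prescriptions.tsv: patient_id, is_target_disease (0/1), drug —
    one row per patient-drug pair."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for (pid, flag), grp in df.groupby(["patient_id", "is_target_disease"],
                                       sort=True):
        records.append(
            PrescriptionRecord(pid, frozenset(grp["drug"]), flag in ("1", "True"))
        )
    return records


def write_prescriptions(records: Iterable[PrescriptionRecord], path) -> None:
    rows = [
        (r.patient_id, int(r.is_target_disease), d)
        for r in records
        for d in sorted(r.drugs)
    ]
    pd.DataFrame(rows, columns=["patient_id", "is_target_disease", "drug"]).to_csv(
        path, sep="\t", index=False
    )


def read_symptoms(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SymptomRecord(pid, frozenset(grp["symptom"]))
        for pid, grp in df.groupby("patient_id", sort=True)
    ]


def write_symptoms(records: Iterable[SymptomRecord], path) -> None:
    rows = [(r.patient_id, s) for r in records for s in sorted(r.symptoms)]
    pd.DataFrame(rows, columns=["patient_id", "symptom"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable], path,
              descriptions: Mapping | None = None) -> None:
    lines = []
    for name in sorted(gene_sets, key=str):
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *sorted(gene_sets[name])]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_interactome_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"protein_a", "protein_b", "combined_score"}
    if not expected <= set(df.columns):
        raise ValueError(f"interactome table needs columns {sorted(expected)}")
    return df


def write_edge_list(net: nx.Graph, path, weight_attr: str = "weight") -> None:
    rows = [
        (u, v, d.get(weight_attr, 1))
        for u, v, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", weight_attr]).to_csv(
        path, sep="\t", index=False
    )


def read_compound_targets(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {cid: set(grp["gene"]) for cid, grp in df.groupby("compound_id", sort=True)}


def write_compound_targets(compound_targets: Mapping[str, Iterable], path) -> None:
    rows = [
        (cid, g)
        for cid in sorted(compound_targets, key=str)
        for g in sorted(compound_targets[cid])
    ]
    pd.DataFrame(rows, columns=["compound_id", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def write_partition(assignment: Mapping, path) -> None:
    rows = sorted(assignment.items(), key=lambda kv: str(kv[0]))
    pd.DataFrame(rows, columns=["node", "community"]).to_csv(
        path, sep="\t", index=False
    )
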