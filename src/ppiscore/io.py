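"""Readers and writers for the tool's text formats.

Formats: SIF / 2-column TSV edge lists for pathways, GCT 1.2 for knockdown
screens (Name = hairpin or gene, Description = gene symbol), GMT for gene
sets, and plain TSVs for contexts, score matrices, drug screens and patient
tables. All outputs are UTF-8, tab-delimited, LF-terminated; missing matrix
values are serialized as the literal ``NaN``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .engine import DualGraph, ScoreVector
from .metrics import ppi_key, split_ppi_key
from .pathway_network import CellLineContext


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# pathway edge lists


def read_sif(path: str | Path) -> list[tuple[str, str]]:
    """SIF (nodeA relation nodeB; relation ignored) or 2-column edge list."""
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 3:
            a, _, b = parts
        elif len(parts) == 2:
            a, b = parts
        else:
            raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
        if not a or not b:
            raise FormatError(f"{path}:{lineno}: empty symbol")
        edges.append((a, b))
    return edges


def write_sif(path: str | Path, edges: Iterable[tuple[str, str]], relation: str = "pp") -> None:
    lines = [f"{a}\t{relation}\t{b}" for a, b in sorted(tuple(sorted(e)) for e in edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name, description, then member symbols."""
    sets = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, members")
        sets[parts[0]] = set(parts[2:])
    return sets


# --------------------------------------------------------------------------
# GCT 1.2


def read_gct(path: str | Path) -> pd.DataFrame:
    """GCT 1.2 matrix: returns DataFrame indexed by Name with a ``gene``
    column (the Description field) and one float column per sample.

    Rows sharing a gene label are kept separate here; group on ``gene`` for
    the second-most-lethal collapse.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        got = lines[0].strip() if lines else "<empty file>"
        raise FormatError(f"{path}: expected GCT version '#1.2', got {got!r}")
    try:
        n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}:2: malformed dimensions line") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise FormatError(f"{path}:3: header must start with Name\\tDescription")
    samples = header[2:]
    if len(samples) != n_cols:
        raise FormatError(
            f"{path}: dimensions line declares {n_cols} samples, header has {len(samples)}"
        )
    body = [ln for ln in lines[3:] if ln.strip()]
    if len(body) != n_rows:
        raise FormatError(
            f"{path}: dimensions line declares {n_rows} rows, body has {len(body)}"
        )
    names, genes, data = [], [], []
    for off, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != 2 + n_cols:
            raise FormatError(f"{path}:{off + 4}: expected {2 + n_cols} fields")
        names.append(parts[0])
        genes.append(parts[1])
        try:
            data.append([float(x) for x in parts[2:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{off + 4}: non-numeric cell") from exc
    df = pd.DataFrame(data, index=names, columns=samples)
    df.insert(0, "gene", genes)
    return df


def write_gct(path: str | Path, df: pd.DataFrame) -> None:
    """Write a DataFrame with a ``gene`` column (rest numeric) as GCT 1.2."""
    samples = [c for c in df.columns if c != "gene"]
    out = ["#1.2", f"{len(df)}\t{len(samples)}", "\t".join(["Name", "Description", *samples])]
    for name, row in df.iterrows():
        vals = "\t".join(repr(float(row[c])) for c in samples)
        out.append(f"{name}\t{row['gene']}\t{vals}")
    Path(path).write_text("\n".join(out) + "\n")


def gct_to_shrna_scores(df: pd.DataFrame, sample: str) -> dict[str, list[float]]:
    """Per-gene hairpin score lists for one sample column of a GCT frame."""
    return {g: sub[sample].tolist() for g, sub in df.groupby("gene", sort=True)}


# --------------------------------------------------------------------------
# contexts


def read_context_tsv(path: str | Path) -> dict[str, CellLineContext]:
    """TSV with columns cell_line, gene, event; one context per cell line.

    Genes listed with any of the three loss events form ``lost_genes``;
    measured genes are supplied separately (from the screen file).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_line", "gene", "event"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: context TSV needs columns {sorted(required)}")
    bad = set(df["event"]) - {"mutation", "homozygous_deletion", "not_expressed"}
    if bad:
        raise FormatError(f"{path}: unknown event label(s) {sorted(bad)}")
    out = {}
    for cl, sub in df.groupby("cell_line", sort=True):
        out[cl] = CellLineContext(
            cell_line=cl, lost_genes=set(sub["gene"]), measured_genes=set()
        )
    return out


def write_context_tsv(path: str | Path, contexts: Iterable[CellLineContext]) -> None:
    rows = []
    for ctx in contexts:
        events: Mapping[str, str] = getattr(ctx, "loss_events", {})
        for g in sorted(ctx.lost_genes):
            rows.append((ctx.cell_line, g, events.get(g, "mutation")))
    df = pd.DataFrame(rows, columns=["cell_line", "gene", "event"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# essentiality matrix / scores / dual graph


def write_matrix_tsv(path: str | Path, matrix: pd.DataFrame) -> None:
    """PPIs x cell lines matrix; row key SYMBOL1_SYMBOL2; missing = NaN."""
    matrix.to_csv(path, sep="\t", index_label="ppi", na_rep="NaN", lineterminator="\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="ppi", na_values=["NaN"])
    for key in df.index:
        split_ppi_key(key)  # validates the row-key convention
    return df.astype(float)


def write_scores_tsv(path: str | Path, sv: ScoreVector) -> None:
    rows = [
        (a, b, s, sv.cell_line or "")
        for (a, b), s in sorted(sv.scores.items())
    ]
    df = pd.DataFrame(rows, columns=["protein_1", "protein_2", "score", "cell_line"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_dual_graph_tsv(path: str | Path, dg: DualGraph) -> None:
    rows = [
        (ppi_key(*dg.dual_nodes[i]), ppi_key(*dg.dual_nodes[j]), shared, w)
        for i, j, shared, w in dg.dual_edges
    ]
    df = pd.DataFrame(rows, columns=["ppi_a", "ppi_b", "shared_protein", "weight"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# --------------------------------------------------------------------------
# drug screen and patients


def write_drug_tsvs(dirpath: str | Path, auc: pd.DataFrame, targets: Mapping[str, set[str]]) -> None:
    d = Path(dirpath)
    long = auc.stack().rename_axis(["compound", "cell_line"]).rename("auc").reset_index()
    long.to_csv(d / "drug_auc.tsv", sep="\t", index=False, lineterminator="\n")
    rows = [(c, g) for c in sorted(targets) for g in sorted(targets[c])]
    pd.DataFrame(rows, columns=["compound", "target_gene"]).to_csv(
        d / "drug_targets.tsv", sep="\t", index=False, lineterminator="\n"
    )


def read_drug_tsvs(dirpath: str | Path) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    d = Path(dirpath)
    long = pd.read_csv(d / "drug_auc.tsv", sep="\t")
    auc = long.pivot(index="compound", columns="cell_line", values="auc")
    tdf = pd.read_csv(d / "drug_targets.tsv", sep="\t", dtype=str)
    targets: dict[str, set[str]] = {}
    for _, row in tdf.iterrows():
        targets.setdefault(row["compound"], set()).add(row["target_gene"])
    return auc, targets


def write_patient_tsvs(dirpath: str | Path, mutations: pd.DataFrame, clinical: pd.DataFrame) -> None:
    d = Path(dirpath)
    mutations.to_csv(d / "patient_mutations.tsv", sep="\t", index=False, lineterminator="\n")
    clinical.to_csv(d / "clinical.tsv", sep="\t", index=False, lineterminator="\n")


def read_patient_tsvs(dirpath: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    d = Path(dirpath)
    mutations = pd.read_csv(d / "patient_mutations.tsv", sep="\t", dtype=str)
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t")
    return mutations, clinical


# --------------------------------------------------------------------------
# run configuration


def write_run_config(path: str | Path, config: Mapping) -> None:
    """Resolved run parameters, written next to every output for reproducibility."""
    Path(path).write_text(
        json.dumps({k: _jsonable(v) for k, v in config.items()}, indent=2, sort_keys=True)
        + "\n"
    )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (set, frozenset)):
        return sorted(v)
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, Path):
        return str(v)
    return v
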