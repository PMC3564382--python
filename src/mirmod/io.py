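"""Readers and writers for the tabular formats.

All files are UTF-8, tab-delimited, decimal point.  Expression matrices have
features as rows and a header row of sample IDs; groups and feature classes
are two-column tables; target tables are three-column tables.  Module reports
consist of a per-module summary table, one edge list per module, and a JSON
dump with every field.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .datamodel import (
    DataError,
    ExpressionDataset,
    Interaction,
    Module,
    TargetTable,
    VALID_CLASSES,
)


def _read_matrix(path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    return mat


def _read_two_column(path, key: str, value: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns)[:2] != [key, value]:
        if df.shape[1] < 2:
            raise DataError(f"{path}: expected columns ({key}, {value})")
        df.columns = [key, value] + list(df.columns[2:])
    return pd.Series(df[value].values, index=df[key].values, name=value)


def read_expression(path_mrna, path_mirna, path_groups, path_classes) -> ExpressionDataset:
    """Load a matched expression dataset, aligning samples by ID.

    Samples are matched on the intersection of the mRNA-matrix, miRNA-matrix
    and group-file sample IDs; samples present in only some of the inputs are
    dropped with a warning (the matched subset drives everything downstream).
    """
    mrna = _read_matrix(path_mrna)
    mirna = _read_matrix(path_mirna)
    groups = _read_two_column(path_groups, "sample_id", "group")
    classes = _read_two_column(path_classes, "feature_id", "class")

    shared = [s for s in mrna.columns if s in set(mirna.columns) & set(groups.index)]
    if not shared:
        raise DataError(
            "no sample overlap between mRNA, miRNA and group files; "
            f"mRNA samples: {list(mrna.columns)[:5]}..., "
            f"miRNA samples: {list(mirna.columns)[:5]}..."
        )
    dropped = (set(mrna.columns) | set(mirna.columns) | set(groups.index)) - set(shared)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) without full overlap: "
            f"{sorted(dropped)[:10]}",
            stacklevel=2,
        )
    missing_class = [f for f in mrna.index if f not in classes.index]
    if missing_class:
        raise DataError(
            f"mRNA features without TF/nTF class entry: {missing_class[:5]}"
        )
    bad = set(classes.unique()) - set(VALID_CLASSES)
    if bad:
        raise DataError(f"invalid feature class values: {sorted(bad)}")
    return ExpressionDataset(
        mrna=mrna[shared].astype(float),
        mirna=mirna[shared].astype(float),
        groups=groups.loc[shared],
        feature_class=classes.loc[mrna.index],
    )


def read_targets(path, regulator_kind: str) -> TargetTable:
    """Load a regulator->gene target-prediction table (scores in (0,1])."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns)[:3] != ["regulator_id", "gene_id", "score"]:
        if df.shape[1] < 3:
            raise DataError(f"{path}: expected columns regulator_id, gene_id, score")
        df.columns = ["regulator_id", "gene_id", "score"] + list(df.columns[3:])
    df["regulator_id"] = df["regulator_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    df["score"] = df["score"].astype(float)
    return TargetTable(df[["regulator_id", "gene_id", "score"]], regulator_kind)


def read_pvalues(path) -> pd.Series:
    """Load a precomputed per-feature p-value table (feature_id, pvalue).

    Lets users bypass the built-in two-sample test with e.g. limma output.
    """
    s = _read_two_column(path, "feature_id", "pvalue").astype(float)
    if ((s < 0) | (s > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    return s


# ---------------------------------------------------------------------------
# module reports
# ---------------------------------------------------------------------------

def _module_record(i: int, m: Module) -> dict:
    counts = m.category_counts()
    return {
        "module": i,
        "n_mirnas": len(m.mirnas),
        "n_tf_genes": len(m.tf_genes),
        "n_ntf_genes": len(m.ntf_genes),
        "n_interactions": len(m.interactions),
        "n_both": counts["both"],
        "n_pcc_only": counts["pcc_only"],
        "n_binding_only": counts["binding_only"],
        "fitness": m.fitness,
        "final_score": m.final_score,
        "p_value": m.p_value,
    }


def write_module_report(modules: list[Module], outdir) -> Path:
    """Write summary TSV + per-module edge lists + a JSON dump.

    Re-running on identical input produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(modules, start=1):
        if m.final_score is None:
            raise DataError(f"module {i} has not been evaluated (no final_score)")
    summary = pd.DataFrame(
        [_module_record(i, m) for i, m in enumerate(modules, start=1)],
        columns=[
            "module", "n_mirnas", "n_tf_genes", "n_ntf_genes",
            "n_interactions", "n_both", "n_pcc_only", "n_binding_only",
            "fitness", "final_score", "p_value",
        ],
    )
    summary.to_csv(outdir / "modules_summary.tsv", sep="\t", index=False,
                   float_format="%.10g")
    dump = []
    for i, m in enumerate(modules, start=1):
        edges = pd.DataFrame(
            [
                {
                    "source": it.source,
                    "target": it.target,
                    "kind": it.kind,
                    "category": it.category,
                    "pcc": it.pcc,
                    "binding_score": it.binding,
                }
                for it in sorted(
                    m.interactions, key=lambda e: (e.kind, e.source, e.target)
                )
            ],
            columns=["source", "target", "kind", "category", "pcc", "binding_score"],
        )
        edges.to_csv(outdir / f"module_{i:02d}_edges.tsv", sep="\t", index=False,
                     float_format="%.10g")
        rec = _module_record(i, m)
        rec.update(
            mirnas=sorted(m.mirnas),
            tf_genes=sorted(m.tf_genes),
            ntf_genes=sorted(m.ntf_genes),
            genes=sorted(m.genes),
            interactions=edges.to_dict(orient="records"),
        )
        dump.append(rec)
    with open(outdir / "modules.json", "w", encoding="utf-8") as fh:
        json.dump(dump, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return outdir


def read_module_report(outdir) -> list[Module]:
    """Reload modules from a JSON dump written by :func:`write_module_report`."""
    with open(Path(outdir) / "modules.json", encoding="utf-8") as fh:
        dump = json.load(fh)
    modules = []
    for rec in dump:
        modules.append(
            Module(
                mirnas=frozenset(rec["mirnas"]),
                tf_genes=frozenset(rec["tf_genes"]),
                ntf_genes=frozenset(rec["ntf_genes"]),
                genes=frozenset(rec["genes"]),
                fitness=rec["fitness"],
                final_score=rec["final_score"],
                p_value=rec["p_value"],
                interactions=[
                    Interaction(
                        source=e["source"], target=e["target"], kind=e["kind"],
                        category=e["category"], pcc=e["pcc"],
                        binding=e["binding_score"],
                    )
                    for e in rec["interactions"]
                ],
            )
        )
    return modules


def write_expression(dataset: ExpressionDataset, outdir) -> Path:
    """Write a dataset back out in the four-file input layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.mrna.rename_axis("feature_id").to_csv(
        outdir / "mrna.tsv", sep="\t", float_format="%.10g")
    dataset.mirna.rename_axis("feature_id").to_csv(
        outdir / "mirna.tsv", sep="\t", float_format="%.10g")
    dataset.groups.rename_axis("sample_id").rename("group").to_csv(
        outdir / "groups.tsv", sep="\t")
    dataset.feature_class.rename_axis("feature_id").rename("class").to_csv(
        outdir / "classes.tsv", sep="\t")
    return outdir


def write_targets(table: TargetTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path
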