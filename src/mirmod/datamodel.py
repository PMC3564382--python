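"""Core domain types.

The method operates on a *matched* expression dataset: an mRNA matrix and a
miRNA matrix measured on the same samples, a two-level sample grouping (e.g.
tumor vs. normal), and a classification of every mRNA feature as a
transcription-factor gene (``TF``) or a non-TF gene (``nTF``).  Sequence-based
target predictions enter as regulator -> gene edge tables with confidence
scores in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

TF_CLASS = "TF"
NTF_CLASS = "nTF"
VALID_CLASSES = (TF_CLASS, NTF_CLASS)

#: interaction support categories (mirrors the three evidence classes used in
#: module summaries: predicted binding + significant correlation, correlation
#: only, binding only)
CATEGORY_BOTH = "both"
CATEGORY_PCC = "pcc_only"
CATEGORY_BINDING = "binding_only"
CATEGORIES = (CATEGORY_BOTH, CATEGORY_PCC, CATEGORY_BINDING)


class DataError(ValueError):
    """Raised when an input violates a dataset contract."""


@dataclass
class ExpressionDataset:
    """Matched mRNA / miRNA expression with sample groups and feature classes.

    Parameters
    ----------
    mrna, mirna
        Feature x sample matrices (rows: features, columns: sample IDs).
        Expression values are assumed normalized and log-scale.
    groups
        Per-sample label (index: sample IDs) from a two-level factor.
    feature_class
        Per-mRNA-feature label, ``"TF"`` or ``"nTF"`` (index: mRNA feature IDs).
    """

    mrna: pd.DataFrame
    mirna: pd.DataFrame
    groups: pd.Series
    feature_class: pd.Series

    def __post_init__(self) -> None:
        for name, mat in (("mrna", self.mrna), ("mirna", self.mirna)):
            if mat.index.has_duplicates:
                dupes = mat.index[mat.index.duplicated()].unique().tolist()
                raise DataError(f"duplicate {name} feature IDs: {dupes[:5]}")
            if mat.isna().any().any():
                r, c = np.argwhere(mat.isna().values)[0]
                raise DataError(
                    f"NaN in {name} matrix at feature {mat.index[r]!r}, "
                    f"sample {mat.columns[c]!r}"
                )
        if list(self.mrna.columns) != list(self.mirna.columns):
            raise DataError("mrna and mirna matrices must share sample order")
        self.groups = self.groups.reindex(self.mrna.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise DataError(f"samples without group label: {missing[:5]}")
        levels = sorted(self.groups.unique())
        if len(levels) != 2:
            raise DataError(
                f"exactly two groups required, got {len(levels)}: {levels}"
            )
        counts = self.groups.value_counts()
        if (counts < 2).any():
            raise DataError("each group needs at least 2 samples")
        self.feature_class = self.feature_class.reindex(self.mrna.index)
        if self.feature_class.isna().any():
            missing = self.feature_class.index[self.feature_class.isna()].tolist()
            raise DataError(f"mRNA features without TF/nTF class: {missing[:5]}")
        bad = set(self.feature_class.unique()) - set(VALID_CLASSES)
        if bad:
            raise DataError(f"invalid feature classes: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.mrna.columns)

    @property
    def group_levels(self) -> list[str]:
        return sorted(self.groups.unique())

    @property
    def tf_genes(self) -> list[str]:
        return list(self.feature_class.index[self.feature_class == TF_CLASS])

    @property
    def ntf_genes(self) -> list[str]:
        return list(self.feature_class.index[self.feature_class == NTF_CLASS])


@dataclass
class TargetTable:
    """Directed regulator -> gene predicted-binding edges with scores.

    ``regulator_kind`` is ``"miRNA"`` (scores are the scaled alignment scores
    of miRNA target predictions, MS) or ``"TF"`` (TF-binding-site similarity
    scores, TS).  Scores must lie in (0, 1].
    """

    edges: pd.DataFrame
    regulator_kind: str

    def __post_init__(self) -> None:
        if self.regulator_kind not in ("miRNA", "TF"):
            raise DataError(f"unknown regulator kind {self.regulator_kind!r}")
        required = ["regulator_id", "gene_id", "score"]
        if list(self.edges.columns)[:3] != required:
            missing = [c for c in required if c not in self.edges.columns]
            if missing:
                raise DataError(f"target table missing columns: {missing}")
            self.edges = self.edges[required]
        edges = self.edges.reset_index(drop=True)
        scores = edges["score"].astype(float)
        bad = (scores <= 0) | (scores > 1)
        if bad.any():
            row = edges[bad].iloc[0]
            raise DataError(
                f"binding score out of (0,1]: {row.regulator_id}->{row.gene_id} "
                f"= {row.score} (pre-scale scores to (0,1])"
            )
        key = ["regulator_id", "gene_id"]
        dup = edges.duplicated(subset=key, keep=False)
        if dup.any():
            grouped = edges[dup].groupby(key)["score"].nunique()
            conflict = grouped[grouped > 1]
            if len(conflict):
                pair = conflict.index[0]
                raise DataError(
                    f"duplicate pair with conflicting scores: {pair[0]}->{pair[1]}"
                )
            edges = edges.drop_duplicates(subset=key)
        self.edges = edges.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    def score_map(self) -> dict[tuple[str, str], float]:
        """(regulator, gene) -> score lookup."""
        return {
            (r, g): s
            for r, g, s in zip(
                self.edges["regulator_id"], self.edges["gene_id"],
                self.edges["score"],
            )
        }

    def restrict(self, regulators: Iterable[str], genes: Iterable[str]) -> "TargetTable":
        """Edges whose endpoints both lie in the given universes."""
        regs, gens = set(regulators), set(genes)
        mask = self.edges["regulator_id"].isin(regs) & self.edges["gene_id"].isin(gens)
        return TargetTable(self.edges[mask].reset_index(drop=True), self.regulator_kind)


@dataclass
class Interaction:
    """One supported regulator-gene or expression-expression interaction."""

    source: str
    target: str
    kind: str  # "miRNA-gene", "TF-gene", "miRNA-miRNA", "nTF-nTF"
    category: str  # both | pcc_only | binding_only
    pcc: float  # signed Pearson correlation (0 if non-significant)
    binding: float  # raw binding score (0 if unpredicted)


@dataclass
class Module:
    """A regulatory module: miRNAs M', TF regulators T', nTF genes R'.

    ``genes`` is the fixed coexpressed gene set found by the GA (the union of
    its TF-class and nTF-class members); the local search only edits the
    regulator sets M' and T'.  A TF regulator added by the local search from
    outside the coexpressed set acts on the genes without itself being a
    module gene.
    """

    mirnas: frozenset[str]
    tf_genes: frozenset[str]
    ntf_genes: frozenset[str]
    genes: frozenset[str]
    fitness: float = 0.0
    final_score: Optional[float] = None
    p_value: Optional[float] = None
    interactions: list[Interaction] = field(default_factory=list)
    control_scores: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mirnas = frozenset(self.mirnas)
        self.tf_genes = frozenset(self.tf_genes)
        self.ntf_genes = frozenset(self.ntf_genes)
        self.genes = frozenset(self.genes)
        if self.mirnas & (self.tf_genes | self.ntf_genes):
            raise DataError("miRNA set overlaps gene sets")
        if self.tf_genes & self.ntf_genes:
            raise DataError("TF and nTF member sets overlap")

    @property
    def members(self) -> frozenset[str]:
        return self.mirnas | self.tf_genes | self.genes

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for it in self.interactions:
            counts[it.category] += 1
        return counts
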