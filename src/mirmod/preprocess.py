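"""Feature selection entering module discovery.

Three steps define the feature universe: (1) a coefficient-of-variation
filter discarding the least-variable fraction of probes, (2) a two-group
differential-expression test per feature, and (3) Benjamini-Hochberg
adjustment with class-specific thresholds.  TF genes are exempt from the
differential-expression threshold (functional TFs need not be differentially
expressed) but still pass through the variation filter; nTF genes use a
stringent adjusted-p cutoff (default 0.001) and miRNAs a looser one
(default 0.05), reflecting that small miRNA expression changes can have
large downstream effects.

The built-in test is Welch's two-sample t-test.  Users with moderated-t
output (e.g. from limma) can supply precomputed per-feature p-values
instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import DataError, ExpressionDataset, NTF_CLASS, TF_CLASS

_MEAN_EPS = 1e-12


def cv_filter(matrix: pd.DataFrame, drop_fraction: float = 0.25) -> pd.DataFrame:
    """Drop the ``drop_fraction`` of rows with the lowest coefficient of variation.

    CV = sd / |mean| per row (sample sd, ddof=1).  ``ceil((1-f)*n)`` rows are
    kept; boundary ties are broken deterministically in favor of the
    lexicographically smaller feature ID.  Rows are returned in their input
    order.
    """
    if not 0 <= drop_fraction < 1:
        raise DataError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    means = matrix.mean(axis=1)
    near_zero = means.abs() < _MEAN_EPS
    if near_zero.any():
        bad = means.index[near_zero].tolist()
        raise DataError(
            f"CV undefined for zero-mean feature(s) {bad[:5]}; "
            "shift the data to a positive baseline or remove them"
        )
    cv = matrix.std(axis=1, ddof=1) / means.abs()
    n_keep = math.ceil((1 - drop_fraction) * len(matrix))
    # ascending CV with id-descending tie-break (stable sort), so that among
    # boundary ties the lexicographically smaller ID survives
    drop_order = sorted(matrix.index, reverse=True)
    drop_order = sorted(drop_order, key=lambda f: cv[f])
    dropped = set(drop_order[: len(matrix) - n_keep])
    survivors = [f for f in matrix.index if f not in dropped]
    return matrix.loc[survivors]


def two_group_de(matrix: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Welch two-sample t-test per feature; returns two-sided p-values.

    A feature with zero variance in both groups gets p = 1 when the group
    means coincide and p = 0 otherwise (complete separation).
    """
    groups = groups.reindex(matrix.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise DataError(f"exactly two groups required, got {levels}")
    a = matrix.loc[:, groups == levels[0]].values
    b = matrix.loc[:, groups == levels[1]].values
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise DataError("each group needs at least 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return pd.Series(p, index=matrix.index, name="pvalue")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR adjustment; input order preserved, values capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class FeatureSelection:
    """The selected universe: TF genes, differentially expressed nTF genes
    and miRNAs, with per-feature raw/adjusted p-values."""

    kept_tf: list[str]
    kept_ntf: list[str]
    kept_mirna: list[str]
    mrna_pvalues: pd.DataFrame  # columns: pvalue, adjusted (index: post-CV features)
    mirna_pvalues: pd.DataFrame

    @property
    def kept_genes(self) -> list[str]:
        return self.kept_tf + self.kept_ntf


def select_features(
    dataset: ExpressionDataset,
    alpha_ntf: float = 0.001,
    alpha_mirna: float = 0.05,
    drop_fraction: float = 0.25,
    mrna_pvalues: pd.Series | None = None,
    mirna_pvalues: pd.Series | None = None,
) -> FeatureSelection:
    """CV filter -> differential expression -> BH -> class-specific thresholds.

    The CV filter is label-blind (all samples pooled).  BH adjustment runs
    across all CV-surviving features of each matrix; the adjusted-p threshold
    is then applied to nTF genes (``alpha_ntf``) and miRNAs (``alpha_mirna``)
    only — every CV-surviving TF gene is kept regardless of its p-value.
    Precomputed p-value series (e.g. limma output) replace the built-in test
    when given; they must cover every CV-surviving feature.
    """
    mrna = cv_filter(dataset.mrna, drop_fraction)
    mirna = cv_filter(dataset.mirna, drop_fraction)

    def _pvals(mat, precomputed, label):
        if precomputed is None:
            return two_group_de(mat, dataset.groups)
        missing = [f for f in mat.index if f not in precomputed.index]
        if missing:
            raise DataError(
                f"precomputed {label} p-values missing features: {missing[:5]}"
            )
        return precomputed.reindex(mat.index).astype(float)

    p_mrna = _pvals(mrna, mrna_pvalues, "mRNA")
    p_mirna = _pvals(mirna, mirna_pvalues, "miRNA")
    adj_mrna = pd.Series(benjamini_hochberg(p_mrna.values), index=p_mrna.index)
    adj_mirna = pd.Series(benjamini_hochberg(p_mirna.values), index=p_mirna.index)

    classes = dataset.feature_class.reindex(mrna.index)
    kept_tf = sorted(classes.index[classes == TF_CLASS])
    ntf = classes.index[classes == NTF_CLASS]
    kept_ntf = sorted(f for f in ntf if adj_mrna[f] < alpha_ntf)
    kept_mirna = sorted(f for f in mirna.index if adj_mirna[f] < alpha_mirna)

    if not kept_ntf:
        raise DataError("no features survive selection: kept_ntf is empty")
    if not kept_mirna:
        raise DataError("no features survive selection: kept_mirna is empty")

    return FeatureSelection(
        kept_tf=kept_tf,
        kept_ntf=kept_ntf,
        kept_mirna=kept_mirna,
        mrna_pvalues=pd.DataFrame({"pvalue": p_mrna, "adjusted": adj_mrna}),
        mirna_pvalues=pd.DataFrame({"pvalue": p_mirna, "adjusted": adj_mirna}),
    )
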