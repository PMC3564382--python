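"""Pearson correlations, permutation significance, and (0.5, 1) scaling.

Three pair classes are handled: mRNA-mRNA, miRNA-miRNA and miRNA-mRNA.
Significance comes from a label-shuffling permutation test: per permutation
one shared sample shuffle is applied to the mRNA-side member of every pair
(the miRNA profile stays fixed for miRNA-mRNA pairs; for within-matrix pairs
one member's labels are shuffled) and the PCC is recomputed.  The p-value is
the fraction of shuffles whose correlation is at least as extreme as the
observed one — two-sided via |PCC| by default, so strongly negative
miRNA-mRNA correlations are significant; a signed one-sided mode is
available.

Absolute correlations and binding scores that enter module scoring are
min-max scaled into [0.5, 1] so that every supported interaction contributes
at least half a unit while preserving order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import DataError, ExpressionDataset
from .preprocess import FeatureSelection


def pearson(x, y) -> float:
    """Standard product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson expects two equal-length 1-D vectors")
    if x.size < 3:
        raise DataError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])


def scale_half_unit(values) -> np.ndarray:
    """Linear min-max map onto [0.5, 1]: min -> 0.5, max -> 1.

    A degenerate collection (max == min) maps to the midpoint 0.75.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("cannot scale an empty collection")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.full_like(v, 0.75)
    return 0.5 + 0.5 * (v - lo) / (hi - lo)


class HalfUnitScaler:
    """The [0.5, 1] map with a frozen (min, max), applied pointwise later.

    Values are clipped into the fitted range first, so a value outside the
    fitting collection still maps inside [0.5, 1].
    """

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            # nothing to calibrate against: degenerate midpoint convention
            self.lo, self.hi = 0.0, 0.0
        else:
            self.lo, self.hi = float(v.min()), float(v.max())

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.hi == self.lo:
            return np.where(np.isnan(x), np.nan, 0.75)
        return 0.5 + 0.5 * (np.clip(x, self.lo, self.hi) - self.lo) / (self.hi - self.lo)


def _standardize(X: np.ndarray) -> np.ndarray:
    """Row-standardize so that Zx @ Zy.T / n is the correlation matrix."""
    Z = X - X.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DataError("zero-variance feature in correlation input")
    return Z / sd


def permutation_pvalues(
    X: np.ndarray,
    Y: np.ndarray | None,
    n_perm: int,
    rng: np.random.Generator,
    two_sided: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed correlations and permutation p-values for corr(Y, X).

    ``X`` is the matrix whose sample labels are shuffled (features x samples);
    ``Y`` keeps its labels (``Y=None`` means the within-``X`` pair class, where
    one member of each pair is shuffled).  One shared shuffle per permutation
    is applied across all pairs.  Returns ``(cor, pval)`` with shape
    (rows(Y), rows(X)); for ``Y=None`` both are symmetric with unit diagonal
    (p=0 on the diagonal by convention, never used).
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    Zx = _standardize(np.asarray(X, dtype=float))
    n = Zx.shape[1]
    within = Y is None
    Zy = Zx if within else _standardize(np.asarray(Y, dtype=float))
    obs = Zy @ Zx.T / n
    ref = np.abs(obs) if two_sided else obs
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        C = Zy @ Zx[:, perm].T / n
        stat = np.abs(C) if two_sided else C
        exceed += stat >= ref - 1e-15
    pval = exceed / n_perm
    if within:
        obs = (obs + obs.T) / 2
        # one member shuffled => matrix asymmetric; take the upper-triangle
        # statistic for each unordered pair and mirror
        upper = np.triu(pval, 1)
        pval = upper + upper.T
        np.fill_diagonal(pval, 0.0)
        np.fill_diagonal(obs, 1.0)
    return obs, pval


@dataclass
class CorrelationStore:
    """Signed PCCs, permutation p-values and masks for the three pair classes.

    ``gg_*`` are gene x gene (mRNA-mRNA), ``mm_*`` miRNA x miRNA and ``mg_*``
    miRNA x gene.  ``sig`` masks flag pairs with p < alpha; ``gg_removed``
    flags mRNA-mRNA pairs retired by the module-extraction pipeline — removed
    pairs never re-enter any fitness term.
    """

    genes: list[str]
    mirnas: list[str]
    gg_cor: np.ndarray
    mm_cor: np.ndarray
    mg_cor: np.ndarray
    gg_pval: np.ndarray
    mm_pval: np.ndarray
    mg_pval: np.ndarray
    alpha: float = 1e-4
    gg_removed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        G, R = len(self.genes), len(self.mirnas)
        assert self.gg_cor.shape == (G, G) and self.mm_cor.shape == (R, R)
        assert self.mg_cor.shape == (R, G)
        if self.gg_removed is None:
            self.gg_removed = np.zeros((G, G), dtype=bool)
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.mirna_index = {m: i for i, m in enumerate(self.mirnas)}

    # -- significance masks (diagonals excluded) ---------------------------
    @property
    def gg_sig(self) -> np.ndarray:
        mask = self.gg_pval < self.alpha
        np.fill_diagonal(mask, False)
        return mask

    @property
    def mm_sig(self) -> np.ndarray:
        mask = self.mm_pval < self.alpha
        np.fill_diagonal(mask, False)
        return mask

    @property
    def mg_sig(self) -> np.ndarray:
        return self.mg_pval < self.alpha

    def usable_gg_abs(self) -> np.ndarray:
        """|PCC| of significant, not-removed mRNA pairs; 0 elsewhere."""
        return np.abs(self.gg_cor) * (self.gg_sig & ~self.gg_removed)

    def remove_genes(self, gene_ids) -> None:
        """Retire every mRNA-mRNA pair involving the given genes."""
        idx = [self.gene_index[g] for g in gene_ids if g in self.gene_index]
        self.gg_removed[idx, :] = True
        self.gg_removed[:, idx] = True

    def copy_masks(self) -> np.ndarray:
        return self.gg_removed.copy()


@dataclass
class CorrelationConfig:
    n_perm: int = 10_000
    alpha: float = 1e-4
    two_sided: bool = True
    seed: int | None = None


def build_store(
    dataset: ExpressionDataset,
    selection: FeatureSelection,
    config: CorrelationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CorrelationStore:
    """Correlations + permutation p-values over the selected feature universe.

    The gene universe is ``kept_tf + kept_ntf`` (TF genes first) and the miRNA
    universe ``kept_mirna``.  All three pair classes share the same shuffle
    sequence within a permutation round.
    """
    config = config or CorrelationConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(selection.kept_tf) + list(selection.kept_ntf)
    mirnas = list(selection.kept_mirna)
    X = dataset.mrna.loc[genes].values
    Y = dataset.mirna.loc[mirnas].values
    # shared shuffles per class-pass; each pass uses its own draw from rng,
    # deterministic under the store seed
    gg_cor, gg_p = permutation_pvalues(X, None, config.n_perm, rng, config.two_sided)
    mm_cor, mm_p = permutation_pvalues(Y, None, config.n_perm, rng, config.two_sided)
    mg_cor, mg_p = permutation_pvalues(X, Y, config.n_perm, rng, config.two_sided)
    return CorrelationStore(
        genes=genes, mirnas=mirnas,
        gg_cor=gg_cor, mm_cor=mm_cor, mg_cor=mg_cor,
        gg_pval=gg_p, mm_pval=mm_p, mg_pval=mg_p,
        alpha=config.alpha,
    )
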