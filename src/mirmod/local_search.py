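"""Local search over candidate regulators for a fixed coexpressed gene set.

Given the gene set G' from the GA, the search space is the pool of candidate
regulators: every miRNA or TF that is either predicted to target a gene in
G' or has a significant correlation with one.  The module fitness combines,
per supported interaction, a scaled binding score and a scaled absolute
correlation:

    MGI    = sum over miRNA i in M', gene j in G' of (k1*MS_ij + k2*|Cor_ij|)
    TGI    = sum over TF i in T', gene j in G', j != i of (k1*TS_ij + k2*|Cor_ij|)
    Cor_M' = sum over unordered miRNA pairs in M' of |Cor_ij|
    F      = (MGI + TGI + Cor_M') / N

with N the number of interactions, i.e. pairs with at least one nonzero
component.  Binding scores (MS/TS) and significant |Cor| values are min-max
scaled into [0.5, 1] once per discovery run; absent components stay exactly
0 so the support category of each interaction remains detectable.

The search is a hill climb: each iteration proposes one local change to M'
or T' (add / remove below the size cap, swap at the cap) and accepts it only
if the fitness strictly increases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .correlation import CorrelationStore, HalfUnitScaler
from .datamodel import (
    CATEGORY_BINDING,
    CATEGORY_BOTH,
    CATEGORY_PCC,
    DataError,
    Interaction,
    Module,
    TargetTable,
)


@dataclass
class LSConfig:
    k1: float = 1.0
    k2: float = 1.0
    mirna_cap_fraction: float = 0.01
    tf_cap_fraction: float = 0.04
    max_iterations: int = 1000
    stagnation_limit: int = 100
    negative_only_mirna: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise DataError("k1 and k2 must be positive")
        for name in ("mirna_cap_fraction", "tf_cap_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DataError(f"{name} must be in (0, 1], got {v}")
        if self.max_iterations < 1 or self.stagnation_limit < 1:
            raise DataError("iteration limits must be >= 1")


class InteractionLedger:
    """Scaled interaction components for every candidate pair.

    Dense matrices over the correlation-store universes:

    - ``mg_scaled`` / ``mm_scaled`` / ``gg_scaled``: scaled |Cor| where the
      pair is significant (and, for gene-gene pairs, not removed), else 0.
    - ``ms_scaled`` (miRNA x gene) and ``ts_scaled`` (gene x gene, rows are
      TF regulators): scaled binding scores, 0 where unpredicted.
    - raw signed correlations and raw binding scores are kept for reports.

    With ``negative_only_mirna`` the miRNA-gene |Cor| component counts only
    when the signed correlation is negative.
    """

    def __init__(
        self,
        store: CorrelationStore,
        mirna_targets: TargetTable,
        tf_targets: TargetTable,
        cor_scaler: HalfUnitScaler,
        ms_scaler: HalfUnitScaler,
        ts_scaler: HalfUnitScaler,
        negative_only_mirna: bool = False,
    ):
        self.store = store
        self.genes = store.genes
        self.mirnas = store.mirnas
        self.gene_index = store.gene_index
        self.mirna_index = store.mirna_index
        self.negative_only_mirna = negative_only_mirna

        gg_mask = store.gg_sig & ~store.gg_removed
        self.gg_scaled = np.where(gg_mask, cor_scaler(np.abs(store.gg_cor)), 0.0)
        self.mm_scaled = np.where(store.mm_sig, cor_scaler(np.abs(store.mm_cor)), 0.0)
        mg_mask = store.mg_sig
        if negative_only_mirna:
            mg_mask = mg_mask & (store.mg_cor < 0)
        self.mg_scaled = np.where(mg_mask, cor_scaler(np.abs(store.mg_cor)), 0.0)

        R, G = len(self.mirnas), len(self.genes)
        self.ms_raw = np.zeros((R, G))
        for r, g, s in mirna_targets.edges.itertuples(index=False):
            ri, gi = self.mirna_index.get(r), self.gene_index.get(g)
            if ri is not None and gi is not None:
                self.ms_raw[ri, gi] = s
        self.ts_raw = np.zeros((G, G))
        for r, g, s in tf_targets.edges.itertuples(index=False):
            ri, gi = self.gene_index.get(r), self.gene_index.get(g)
            if ri is not None and gi is not None and ri != gi:
                self.ts_raw[ri, gi] = s
        self.ms_scaled = np.where(self.ms_raw > 0, ms_scaler(self.ms_raw), 0.0)
        self.ts_scaled = np.where(self.ts_raw > 0, ts_scaler(self.ts_raw), 0.0)

    def gidx(self, ids) -> list[int]:
        try:
            return [self.gene_index[g] for g in ids]
        except KeyError as e:
            raise DataError(f"module member {e.args[0]!r} absent from ledger") from e

    def midx(self, ids) -> list[int]:
        try:
            return [self.mirna_index[m] for m in ids]
        except KeyError as e:
            raise DataError(f"module member {e.args[0]!r} absent from ledger") from e


def build_ledger(
    store: CorrelationStore,
    mirna_targets: TargetTable,
    tf_targets: TargetTable,
    config: LSConfig | None = None,
    scalers: tuple[HalfUnitScaler, HalfUnitScaler, HalfUnitScaler] | None = None,
) -> InteractionLedger:
    """Assemble the ledger, fitting the three scalers if not supplied.

    The |Cor| scaler is fitted over every significant absolute correlation
    across the three pair classes; the MS/TS scalers over the binding scores
    of edges that map into the store universes.  Pass precomputed ``scalers``
    to keep the maps fixed across extraction rounds.
    """
    config = config or LSConfig()
    if scalers is None:
        scalers = fit_scalers(store, mirna_targets, tf_targets)
    cor_scaler, ms_scaler, ts_scaler = scalers
    return InteractionLedger(
        store, mirna_targets, tf_targets,
        cor_scaler, ms_scaler, ts_scaler,
        negative_only_mirna=config.negative_only_mirna,
    )


def fit_scalers(
    store: CorrelationStore,
    mirna_targets: TargetTable,
    tf_targets: TargetTable,
) -> tuple[HalfUnitScaler, HalfUnitScaler, HalfUnitScaler]:
    """Fit the three [0.5, 1] scaling maps over the candidate universe."""
    gg = np.abs(store.gg_cor)[np.triu(store.gg_sig, 1)]
    mm = np.abs(store.mm_cor)[np.triu(store.mm_sig, 1)]
    mg = np.abs(store.mg_cor)[store.mg_sig]
    cor_scaler = HalfUnitScaler(np.concatenate([gg, mm, mg]))
    genes, mirnas = set(store.genes), set(store.mirnas)
    ms = mirna_targets.restrict(mirnas, genes).edges["score"].values
    ts = tf_targets.restrict(genes, genes).edges["score"].values
    return cor_scaler, HalfUnitScaler(ms), HalfUnitScaler(ts)


def build_candidate_pool(
    gene_set,
    mirna_targets: TargetTable,
    tf_targets: TargetTable,
    store: CorrelationStore,
    tf_universe,
) -> tuple[list[str], list[str]]:
    """Candidate regulators: predicted to target the gene set or
    significantly correlated with one of its members.

    TF candidates are drawn from ``tf_universe`` (the TF-class genes of the
    correlation store) and always include the TF genes inside the set.
    Returns sorted (mirna_candidates, tf_candidates).
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise DataError("empty gene set")
    gidx = [store.gene_index[g] for g in gene_set if g in store.gene_index]

    mirna_pool: set[str] = set()
    edges = mirna_targets.edges
    mirna_pool |= set(edges.loc[edges["gene_id"].isin(gene_set), "regulator_id"])
    mg_sig = store.mg_sig[:, gidx].any(axis=1)
    mirna_pool |= {m for m, s in zip(store.mirnas, mg_sig) if s}
    mirna_pool &= set(store.mirnas)

    tf_universe = set(tf_universe)
    tf_pool: set[str] = tf_universe & gene_set
    edges = tf_targets.edges
    tf_pool |= set(edges.loc[edges["gene_id"].isin(gene_set), "regulator_id"]) & tf_universe
    gg_sig = (store.gg_sig & ~store.gg_removed)[:, gidx].any(axis=1)
    tf_pool |= {g for g, s in zip(store.genes, gg_sig) if s} & tf_universe

    if not mirna_pool and not tf_pool:
        raise DataError("no candidate regulators for this gene set")
    return sorted(mirna_pool), sorted(tf_pool)


def _cap(fraction: float, pool_size: int) -> int:
    return max(1, math.ceil(fraction * pool_size)) if pool_size else 0


def init_solution(
    gene_set,
    pools: tuple[list[str], list[str]],
    tf_classes,
    config: LSConfig,
    rng: np.random.Generator,
) -> Module:
    """Initial module: the gene set's TF genes as regulators plus a random
    cap-sized draw of miRNAs from the candidate pool."""
    gene_set = set(gene_set)
    mirna_pool, _ = pools
    tf_in_set = gene_set & set(tf_classes)
    ntf_in_set = gene_set - tf_in_set
    n_init = min(_cap(config.mirna_cap_fraction, len(mirna_pool)), len(mirna_pool))
    if not mirna_pool:
        warnings.warn("empty miRNA candidate pool; starting with no miRNAs",
                      stacklevel=2)
        mirnas: list[str] = []
    else:
        mirnas = list(rng.choice(sorted(mirna_pool), size=n_init, replace=False))
    return Module(
        mirnas=frozenset(mirnas),
        tf_genes=frozenset(tf_in_set),
        ntf_genes=frozenset(ntf_in_set),
        genes=frozenset(gene_set),
    )


def module_fitness(
    module: Module,
    ledger: InteractionLedger,
    config: LSConfig | None = None,
) -> tuple[float, float, float, float, int]:
    """Module fitness components: returns (F, MGI, TGI, Cor_M', N).

    N counts supported pairs only (at least one nonzero component): ordered
    regulator->gene pairs for MGI/TGI, unordered pairs for Cor_M'.  F = 0
    when N = 0.
    """
    config = config or LSConfig()
    k1, k2 = config.k1, config.k2
    mi = ledger.midx(sorted(module.mirnas))
    ti = ledger.gidx(sorted(module.tf_genes))
    gi = ledger.gidx(sorted(module.genes))

    MGI = 0.0
    TGI = 0.0
    corM = 0.0
    N = 0
    if mi and gi:
        ms = ledger.ms_scaled[np.ix_(mi, gi)]
        mc = ledger.mg_scaled[np.ix_(mi, gi)]
        MGI = float((k1 * ms + k2 * mc).sum())
        N += int(((ms > 0) | (mc > 0)).sum())
    if ti and gi:
        ts = ledger.ts_scaled[np.ix_(ti, gi)]
        tc = ledger.gg_scaled[np.ix_(ti, gi)]
        # exclude self-pairs (a TF "regulating" itself)
        self_mask = np.equal.outer(np.asarray(ti), np.asarray(gi))
        ts = np.where(self_mask, 0.0, ts)
        tc = np.where(self_mask, 0.0, tc)
        TGI = float((k1 * ts + k2 * tc).sum())
        N += int(((ts > 0) | (tc > 0)).sum())
    if len(mi) >= 2:
        mm = ledger.mm_scaled[np.ix_(mi, mi)]
        iu = np.triu_indices(len(mi), 1)
        corM = float(mm[iu].sum())
        N += int((mm[iu] > 0).sum())
    F = (MGI + TGI + corM) / N if N else 0.0
    return F, MGI, TGI, corM, N


def propose_move(
    module: Module,
    pools: tuple[list[str], list[str]],
    config: LSConfig,
    rng: np.random.Generator,
) -> Module:
    """One local change to M' or T' (class chosen with probability 1/2).

    Below the class cap, a uniformly chosen pool candidate is added — or
    removed, if it is already in the module.  At (or above) the cap, an
    inside member is swapped with an outside candidate.  The gene set G'
    never changes.  If neither class admits a move the module is returned
    unchanged.
    """
    mirna_pool, tf_pool = pools
    caps = {
        "mirna": _cap(config.mirna_cap_fraction, len(mirna_pool)),
        "tf": _cap(config.tf_cap_fraction, len(tf_pool)),
    }
    first = "mirna" if rng.random() < 0.5 else "tf"
    for cls in (first, "tf" if first == "mirna" else "mirna"):
        pool = mirna_pool if cls == "mirna" else tf_pool
        inside = set(module.mirnas if cls == "mirna" else module.tf_genes)
        if not pool:
            continue
        if len(inside) < caps[cls]:
            pick = pool[int(rng.integers(len(pool)))]
            new = (inside - {pick}) if pick in inside else (inside | {pick})
        else:
            outside = sorted(set(pool) - inside)
            if not outside or not inside:
                continue
            drop = sorted(inside)[int(rng.integers(len(inside)))]
            add = outside[int(rng.integers(len(outside)))]
            new = (inside - {drop}) | {add}
        if cls == "mirna":
            return replace(module, mirnas=frozenset(new))
        return replace(module, tf_genes=frozenset(new))
    return module


def module_interactions(module: Module, ledger: InteractionLedger,
                        include_ntf_pairs: bool = False) -> list[Interaction]:
    """Enumerate the module's supported interactions with their categories.

    ``include_ntf_pairs`` additionally lists the significant nTF-nTF
    correlation pairs that enter the final score.
    """
    out: list[Interaction] = []
    mi = ledger.midx(sorted(module.mirnas))
    ti = ledger.gidx(sorted(module.tf_genes))
    gi = ledger.gidx(sorted(module.genes))
    mirnas = sorted(module.mirnas)
    tfs = sorted(module.tf_genes)
    genes = sorted(module.genes)

    def _cat(binding: float, cor: float) -> str:
        if binding > 0 and cor > 0:
            return CATEGORY_BOTH
        return CATEGORY_PCC if cor > 0 else CATEGORY_BINDING

    for a, ia in zip(mirnas, mi):
        for b, jb in zip(genes, gi):
            ms, mc = ledger.ms_scaled[ia, jb], ledger.mg_scaled[ia, jb]
            if ms > 0 or mc > 0:
                out.append(Interaction(
                    a, b, "miRNA-gene", _cat(ms, mc),
                    pcc=float(ledger.store.mg_cor[ia, jb]) if mc > 0 else 0.0,
                    binding=float(ledger.ms_raw[ia, jb]),
                ))
    for a, ia in zip(tfs, ti):
        for b, jb in zip(genes, gi):
            if ia == jb:
                continue
            ts, tc = ledger.ts_scaled[ia, jb], ledger.gg_scaled[ia, jb]
            if ts > 0 or tc > 0:
                out.append(Interaction(
                    a, b, "TF-gene", _cat(ts, tc),
                    pcc=float(ledger.store.gg_cor[ia, jb]) if tc > 0 else 0.0,
                    binding=float(ledger.ts_raw[ia, jb]),
                ))
    for x in range(len(mi)):
        for y in range(x + 1, len(mi)):
            mm = ledger.mm_scaled[mi[x], mi[y]]
            if mm > 0:
                out.append(Interaction(
                    mirnas[x], mirnas[y], "miRNA-miRNA", CATEGORY_PCC,
                    pcc=float(ledger.store.mm_cor[mi[x], mi[y]]), binding=0.0,
                ))
    if include_ntf_pairs:
        ntfs = sorted(module.ntf_genes)
        ri = ledger.gidx(ntfs)
        for x in range(len(ri)):
            for y in range(x + 1, len(ri)):
                gg = ledger.gg_scaled[ri[x], ri[y]]
                if gg > 0:
                    out.append(Interaction(
                        ntfs[x], ntfs[y], "nTF-nTF", CATEGORY_PCC,
                        pcc=float(ledger.store.gg_cor[ri[x], ri[y]]), binding=0.0,
                    ))
    return out


@dataclass
class LSResult:
    module: Module
    trace: pd.DataFrame  # iteration, fitness, n_mirnas, n_tfs
    iterations: int


def run_local_search(
    gene_set,
    ledger: InteractionLedger,
    pools: tuple[list[str], list[str]],
    tf_classes,
    config: LSConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LSResult:
    """Hill climb from the initial solution; accept only strict improvements.

    Terminates after ``max_iterations`` proposals or once the fitness has not
    changed for ``stagnation_limit`` consecutive proposals.
    """
    config = config or LSConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    module = init_solution(gene_set, pools, tf_classes, config, rng)
    best, *_ = module_fitness(module, ledger, config)
    trace = [(0, best, len(module.mirnas), len(module.tf_genes))]
    stagnation = 0
    it = 0
    for it in range(1, config.max_iterations + 1):
        cand = propose_move(module, pools, config, rng)
        f, *_ = module_fitness(cand, ledger, config)
        if f > best + 1e-12:
            module, best = cand, f
            stagnation = 0
        else:
            stagnation += 1
        trace.append((it, best, len(module.mirnas), len(module.tf_genes)))
        if stagnation >= config.stagnation_limit:
            break
    module = replace(module, fitness=best,
                     interactions=module_interactions(module, ledger))
    return LSResult(
        module=module,
        trace=pd.DataFrame(trace, columns=["iteration", "fitness", "n_mirnas", "n_tfs"]),
        iterations=it,
    )
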