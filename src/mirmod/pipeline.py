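"""Iterative module extraction and module-level evaluation.

Modules are extracted one per round: the GA proposes a coexpressed gene set,
the local search attaches regulators, and the mRNA-mRNA correlation pairs
involving the module's genes are then retired from the store so no two
modules share internal gene-gene interactions.  Each module is scored with
the final score

    F_final = (MGI + TGI + Cor_M' + Cor_R') / N

where Cor_R' adds the correlations among the module's nTF genes and N is
recounted to include the supported nTF-nTF pairs.  Significance comes from
two sources: same-shape random control modules (score separation) and a
permutation test that substitutes a uniformly drawn number of members by
random same-class candidates, with p the fraction of permuted modules
scoring above the observed one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .correlation import (
    CorrelationConfig,
    CorrelationStore,
    build_store,
)
from .datamodel import DataError, ExpressionDataset, Module, TargetTable
from .ga import GAConfig, run_ga
from .local_search import (
    InteractionLedger,
    LSConfig,
    build_candidate_pool,
    build_ledger,
    fit_scalers,
    module_fitness,
    module_interactions,
    run_local_search,
)
from .preprocess import FeatureSelection, select_features

logger = logging.getLogger("mirmod")


@dataclass
class PipelineConfig:
    n_modules: int = 10
    n_random_controls: int = 1000
    n_module_perms: int = 1000
    alpha_module: float = 0.005
    seed: int | None = None
    ga: GAConfig = field(default_factory=GAConfig)
    ls: LSConfig = field(default_factory=LSConfig)
    corr: CorrelationConfig = field(default_factory=CorrelationConfig)

    def __post_init__(self) -> None:
        if min(self.n_modules, self.n_random_controls, self.n_module_perms) < 1:
            raise DataError("pipeline counts must be >= 1")


@dataclass
class Universes:
    """Candidate member universes used for controls and permutations."""

    mirnas: list[str]
    tf_genes: list[str]
    ntf_genes: list[str]

    @classmethod
    def from_selection(cls, selection: FeatureSelection) -> "Universes":
        return cls(
            mirnas=sorted(selection.kept_mirna),
            tf_genes=sorted(selection.kept_tf),
            ntf_genes=sorted(selection.kept_ntf),
        )


def final_score(module: Module, ledger: InteractionLedger,
                config: LSConfig | None = None) -> tuple[float, int]:
    """Final module score (fitness terms plus Cor_R'), with the recounted N."""
    config = config or LSConfig()
    F, MGI, TGI, corM, N = module_fitness(module, ledger, config)
    ri = ledger.gidx(sorted(module.ntf_genes))
    corR = 0.0
    if len(ri) >= 2:
        sub = ledger.gg_scaled[np.ix_(ri, ri)]
        iu = np.triu_indices(len(ri), 1)
        corR = float(sub[iu].sum())
        N += int((sub[iu] > 0).sum())
    score = (MGI + TGI + corM + corR) / N if N else 0.0
    return score, N


def interaction_summary(module: Module, ledger: InteractionLedger) -> dict[str, int]:
    """Support-category counts (both / pcc_only / binding_only) over the
    module's interactions including the nTF-nTF pairs; counts sum to the N
    of the final score."""
    interactions = module_interactions(module, ledger, include_ntf_pairs=True)
    counts = {"both": 0, "pcc_only": 0, "binding_only": 0}
    for it in interactions:
        counts[it.category] += 1
    return counts


def _random_module_like(module: Module, universes: Universes,
                        rng: np.random.Generator) -> Module:
    """A uniformly resampled module with the same class shape."""
    def draw(pool: list[str], k: int) -> frozenset[str]:
        if k > len(pool):
            raise DataError(
                f"universe of size {len(pool)} cannot supply {k} members"
            )
        if k == 0:
            return frozenset()
        return frozenset(rng.choice(pool, size=k, replace=False))

    tfs = draw(universes.tf_genes, len(module.tf_genes))
    ntfs = draw(universes.ntf_genes, len(module.ntf_genes))
    return Module(
        mirnas=draw(universes.mirnas, len(module.mirnas)),
        tf_genes=tfs,
        ntf_genes=ntfs,
        genes=tfs | ntfs,
    )


def random_control_scores(
    module: Module,
    universes: Universes,
    ledger: InteractionLedger,
    n: int,
    rng: np.random.Generator,
    config: LSConfig | None = None,
) -> np.ndarray:
    """Final scores of ``n`` random same-shape control modules."""
    return np.array([
        final_score(_random_module_like(module, universes, rng), ledger, config)[0]
        for _ in range(n)
    ])


def _substitute_members(module: Module, universes: Universes,
                        rng: np.random.Generator) -> Module:
    """One permutation round: replace s ~ U{0..|G'|} members (class-
    preserving) by uniformly chosen outside candidates."""
    members = (
        [("mirna", m) for m in sorted(module.mirnas)]
        + [("tf", t) for t in sorted(module.tf_genes)]
        + [("ntf", r) for r in sorted(module.ntf_genes)]
    )
    s = int(rng.integers(0, len(module.genes) + 1))
    s = min(s, len(members))
    if s == 0:
        return module
    chosen = rng.choice(len(members), size=s, replace=False)
    mirnas, tfs, ntfs = set(module.mirnas), set(module.tf_genes), set(module.ntf_genes)
    genes = set(module.genes)
    pools = {"mirna": universes.mirnas, "tf": universes.tf_genes,
             "ntf": universes.ntf_genes}
    current = {"mirna": mirnas, "tf": tfs, "ntf": ntfs}
    for ci in chosen:
        cls, old = members[ci]
        outside = sorted(set(pools[cls]) - current[cls])
        if not outside:
            continue  # no replacement pool for this class
        new = outside[int(rng.integers(len(outside)))]
        current[cls].discard(old)
        current[cls].add(new)
        if cls in ("tf", "ntf") and old in genes:
            genes.discard(old)
            genes.add(new)
    return Module(mirnas=frozenset(mirnas), tf_genes=frozenset(tfs),
                  ntf_genes=frozenset(ntfs), genes=frozenset(genes))


def module_permutation_pvalue(
    module: Module,
    universes: Universes,
    ledger: InteractionLedger,
    n_perm: int,
    rng: np.random.Generator,
    config: LSConfig | None = None,
) -> float:
    """Fraction of member-substituted modules scoring above the observed one."""
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    observed, _ = final_score(module, ledger, config)
    better = 0
    for _ in range(n_perm):
        perm = _substitute_members(module, universes, rng)
        score, _ = final_score(perm, ledger, config)
        if score > observed:
            better += 1
    return better / n_perm


@dataclass
class ExtractedModule:
    module: Module
    ledger: InteractionLedger = field(repr=False)
    ga_trace: object = field(repr=False, default=None)
    ls_trace: object = field(repr=False, default=None)


def extract_modules(
    store: CorrelationStore,
    selection: FeatureSelection,
    mirna_targets: TargetTable,
    tf_targets: TargetTable,
    config: PipelineConfig | None = None,
) -> list[ExtractedModule]:
    """Run ``n_modules`` GA + local-search rounds with store updates.

    After each round every mRNA-mRNA pair involving the module's genes is
    retired from the correlation store, so later rounds cannot rediscover
    the same coexpression structure.  Scaling maps are fitted once, before
    any removal, and stay fixed across rounds.
    """
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    scalers = fit_scalers(store, mirna_targets, tf_targets)
    tf_set = set(selection.kept_tf)
    out: list[ExtractedModule] = []
    for round_no in range(config.n_modules):
        ga_rng, ls_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        if not store.usable_gg_abs().any():
            warnings.warn(f"round {round_no + 1}: no usable gene pairs left",
                          stacklevel=2)
            break
        ga_res = run_ga(store, tf_set, config.ga, rng=ga_rng)
        if len(ga_res.genes) < 2 or ga_res.fitness <= 0:
            warnings.warn(f"round {round_no + 1}: GA returned no coexpressed "
                          "gene set; skipping round", stacklevel=2)
            continue
        ledger = build_ledger(store, mirna_targets, tf_targets, config.ls,
                              scalers=scalers)
        try:
            pools = build_candidate_pool(
                ga_res.genes, mirna_targets, tf_targets, store, tf_set)
        except DataError as err:
            warnings.warn(f"round {round_no + 1}: {err}; skipping round",
                          stacklevel=2)
            continue
        ls_res = run_local_search(
            ga_res.genes, ledger, pools, tf_set, config.ls, rng=ls_rng)
        module = ls_res.module
        score, _ = final_score(module, ledger, config.ls)
        module = replace(module, final_score=score,
                         interactions=module_interactions(
                             module, ledger, include_ntf_pairs=True))
        logger.info("round %d: %d genes, %d miRNAs, %d TFs, F=%.4f, final=%.4f",
                    round_no + 1, len(module.genes), len(module.mirnas),
                    len(module.tf_genes), module.fitness, score)
        out.append(ExtractedModule(module=module, ledger=ledger,
                                   ga_trace=ga_res.trace, ls_trace=ls_res.trace))
        store.remove_genes(module.genes)
    if not out:
        raise DataError("all extraction rounds failed")
    return out


def evaluate_modules(
    extracted: list[ExtractedModule],
    universes: Universes,
    config: PipelineConfig,
) -> list[Module]:
    """Attach control scores and permutation p-values to extracted modules."""
    ss = np.random.SeedSequence(
        config.seed if config.seed is None else config.seed + 0x5EED)
    out = []
    for em in extracted:
        ctrl_rng, perm_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        controls = random_control_scores(
            em.module, universes, em.ledger, config.n_random_controls,
            ctrl_rng, config.ls)
        pval = module_permutation_pvalue(
            em.module, universes, em.ledger, config.n_module_perms,
            perm_rng, config.ls)
        out.append(replace(em.module, p_value=pval, control_scores=controls))
    return out


@dataclass
class DiscoveryResult:
    modules: list[Module]
    extracted: list[ExtractedModule]
    selection: FeatureSelection
    store: CorrelationStore
    universes: Universes


def run_discovery(
    dataset: ExpressionDataset,
    mirna_targets: TargetTable,
    tf_targets: TargetTable,
    config: PipelineConfig | None = None,
    selection: FeatureSelection | None = None,
    alpha_ntf: float = 0.001,
    alpha_mirna: float = 0.05,
    drop_fraction: float = 0.25,
) -> DiscoveryResult:
    """End-to-end: feature selection -> correlation store -> extraction ->
    evaluation, all seeded from ``config.seed``."""
    config = config or PipelineConfig()
    if selection is None:
        selection = select_features(dataset, alpha_ntf=alpha_ntf,
                                    alpha_mirna=alpha_mirna,
                                    drop_fraction=drop_fraction)
    corr_cfg = config.corr
    corr_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0]
        if config.seed is not None else None)
    store = build_store(dataset, selection, corr_cfg, rng=corr_rng)
    universes = Universes.from_selection(selection)
    extracted = extract_modules(store, selection, mirna_targets, tf_targets,
                                config)
    modules = evaluate_modules(extracted, universes, config)
    return DiscoveryResult(modules=modules, extracted=extracted,
                           selection=selection, store=store,
                           universes=universes)
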