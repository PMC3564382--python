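"""Shared fixtures: deterministic random correlation stores, target tables,
and one cached planted-module discovery study reused by several tests."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import mirmod as mm
from mirmod.correlation import CorrelationStore
from mirmod.datamodel import Module, TargetTable


def make_store(rng, n_genes=8, n_mirnas=4, sig_frac=0.6, alpha=0.5):
    """Random store: uniform correlations, each pair significant with
    probability ``sig_frac`` (p-value 0 or 1)."""
    genes = [f"g{i}" for i in range(n_genes)]
    mirnas = [f"m{i}" for i in range(n_mirnas)]

    def sym(n):
        C = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        C[iu] = rng.uniform(-1, 1, len(iu[0]))
        C = C + C.T
        np.fill_diagonal(C, 1.0)
        return C

    def pmask(shape, symmetric=False):
        P = (rng.random(shape) > sig_frac).astype(float)
        if symmetric:
            P = np.triu(P, 1) + np.triu(P, 1).T
        return P

    return CorrelationStore(
        genes=genes, mirnas=mirnas,
        gg_cor=sym(n_genes), mm_cor=sym(n_mirnas),
        mg_cor=rng.uniform(-1, 1, (n_mirnas, n_genes)),
        gg_pval=pmask((n_genes, n_genes), True),
        mm_pval=pmask((n_mirnas, n_mirnas), True),
        mg_pval=pmask((n_mirnas, n_genes)),
        alpha=alpha,
    )


def make_targets(rng, regulators, genes, kind, rate=0.5):
    rows = [
        (r, g, float(rng.uniform(0.1, 1.0)))
        for r in regulators for g in genes
        if r != g and rng.random() < rate
    ]
    if not rows:
        rows = [(regulators[0], genes[0], 0.5)]
    return TargetTable(
        pd.DataFrame(rows, columns=["regulator_id", "gene_id", "score"]), kind)


def brute_force_module_score(module, store, mirna_targets, tf_targets,
                             cfg, scalers, include_ntf=False):
    """Independent double-loop recomputation of the module score from the raw
    correlation store and target tables (oracle for the ledger-based path)."""
    cor_s, ms_s, ts_s = scalers
    ms_map = mirna_targets.score_map()
    ts_map = tf_targets.score_map()

    def cor(kind, a, b):
        if kind == "mg":
            i, j = store.mirna_index[a], store.gene_index[b]
            sig = store.mg_pval[i, j] < store.alpha
            return float(cor_s(abs(store.mg_cor[i, j]))) if sig else 0.0
        if kind == "mm":
            i, j = store.mirna_index[a], store.mirna_index[b]
            sig = store.mm_pval[i, j] < store.alpha
            return float(cor_s(abs(store.mm_cor[i, j]))) if sig else 0.0
        i, j = store.gene_index[a], store.gene_index[b]
        sig = store.gg_pval[i, j] < store.alpha and not store.gg_removed[i, j]
        return float(cor_s(abs(store.gg_cor[i, j]))) if sig else 0.0

    total = 0.0
    n = 0
    for m in sorted(module.mirnas):
        for g in sorted(module.genes):
            ms = float(ms_s(ms_map[(m, g)])) if (m, g) in ms_map else 0.0
            c = cor("mg", m, g)
            total += cfg.k1 * ms + cfg.k2 * c
            n += (ms > 0) or (c > 0)
    for t in sorted(module.tf_genes):
        for g in sorted(module.genes):
            if t == g:
                continue
            ts = float(ts_s(ts_map[(t, g)])) if (t, g) in ts_map else 0.0
            c = cor("gg", t, g)
            total += cfg.k1 * ts + cfg.k2 * c
            n += (ts > 0) or (c > 0)
    for a, b in itertools.combinations(sorted(module.mirnas), 2):
        c = cor("mm", a, b)
        total += c
        n += c > 0
    if include_ntf:
        for a, b in itertools.combinations(sorted(module.ntf_genes), 2):
            c = cor("gg", a, b)
            total += c
            n += c > 0
    return (total / n if n else 0.0), n


def random_module(rng, store, tf_genes, max_mirnas=3, max_tfs=2):
    """A random module whose gene set mixes TF and nTF genes of the store."""
    ntf_pool = [g for g in store.genes if g not in tf_genes]
    mirnas = rng.choice(store.mirnas, rng.integers(0, max_mirnas + 1),
                        replace=False)
    tfs = rng.choice(sorted(tf_genes), rng.integers(0, max_tfs + 1),
                     replace=False)
    ntfs = rng.choice(ntf_pool, rng.integers(1, min(5, len(ntf_pool)) + 1),
                      replace=False)
    return Module(
        mirnas=frozenset(mirnas), tf_genes=frozenset(tfs),
        ntf_genes=frozenset(ntfs),
        genes=frozenset(ntfs) | frozenset(tfs),
    )


@pytest.fixture(scope="session")
def planted_study():
    """Ten seeded end-to-end discovery runs on planted two-module datasets.

    Cached once per session; used for recovery, invariants and score
    separation checks.  Each entry carries the ground truth, the discovery
    result and per-planted-module recovery metrics.
    """
    from mirmod.presets import desk_scale_pipeline, desk_scale_sim, recovery_metrics

    runs = []
    for seed in range(10):
        ds, targets, truth = mm.generate_dataset(desk_scale_sim(100 + seed))
        cfg = desk_scale_pipeline(seed=seed)
        result = mm.run_discovery(ds, targets["miRNA"], targets["TF"], cfg)
        runs.append({
            "seed": seed,
            "truth": truth,
            "result": result,
            "recovery": recovery_metrics(result.modules, truth),
        })
    return runs
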