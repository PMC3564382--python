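"""Candidate pools, module fitness (composite interaction score), moves."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirmod.correlation import CorrelationStore, HalfUnitScaler
from mirmod.datamodel import DataError, Module, TargetTable
from mirmod.local_search import (
    LSConfig,
    _cap,
    build_candidate_pool,
    build_ledger,
    fit_scalers,
    init_solution,
    module_fitness,
    propose_move,
    run_local_search,
)

from conftest import brute_force_module_score, make_store, make_targets, random_module


def _identity_scalers():
    # scalers fitted on {0, 1} leave 1 -> 1.0 and map x in [0,1] to 0.5+x/2
    s = HalfUnitScaler([0.0, 1.0])
    return s, s, s


def _single_pair_setup(ms_scaled_to=0.8, cor_scaled_to=0.6):
    """One miRNA targeting one gene with chosen scaled components."""
    store = CorrelationStore(
        genes=["g1"], mirnas=["m1"],
        gg_cor=np.ones((1, 1)), mm_cor=np.ones((1, 1)),
        mg_cor=np.array([[2 * cor_scaled_to - 1]]),  # scales to cor_scaled_to
        gg_pval=np.ones((1, 1)), mm_pval=np.ones((1, 1)),
        mg_pval=np.zeros((1, 1)), alpha=0.5)
    raw_ms = 2 * ms_scaled_to - 1
    targets = TargetTable(pd.DataFrame(
        [("m1", "g1", raw_ms)], columns=["regulator_id", "gene_id", "score"]),
        "miRNA")
    tf_targets = TargetTable(pd.DataFrame(
        [("g1", "g1", 0.5)], columns=["regulator_id", "gene_id", "score"]), "TF")
    ledger = build_ledger(store, targets, tf_targets, LSConfig(),
                          scalers=_identity_scalers())
    module = Module(mirnas={"m1"}, tf_genes=set(), ntf_genes={"g1"},
                    genes={"g1"})
    return module, ledger


def test_module_fitness_single_interaction():
    module, ledger = _single_pair_setup()
    F, MGI, TGI, corM, N = module_fitness(module, ledger, LSConfig(k1=1, k2=1))
    assert (MGI, TGI, corM, N) == (pytest.approx(1.4), 0.0, 0.0, 1)
    assert F == pytest.approx(1.4)
    # linear in k1: doubling the binding weight adds one scaled MS
    F2, *_ = module_fitness(module, ledger, LSConfig(k1=2, k2=1))
    assert F2 == pytest.approx(2.2)
    F3, *_ = module_fitness(module, ledger, LSConfig(k1=1, k2=3))
    assert F3 == pytest.approx(0.8 + 3 * 0.6)


def test_module_fitness_matches_brute_force_oracle():
    rng = np.random.default_rng(21)
    for _ in range(40):
        store = make_store(rng, n_genes=9, n_mirnas=4, sig_frac=0.5)
        tf_genes = {"g0", "g1", "g2"}
        mt = make_targets(rng, store.mirnas, store.genes, "miRNA")
        tt = make_targets(rng, sorted(tf_genes), store.genes, "TF")
        cfg = LSConfig(k1=float(rng.uniform(0.5, 3)), k2=float(rng.uniform(0.5, 3)))
        scalers = fit_scalers(store, mt, tt)
        ledger = build_ledger(store, mt, tt, cfg, scalers=scalers)
        module = random_module(rng, store, tf_genes)
        F, MGI, TGI, corM, N = module_fitness(module, ledger, cfg)
        expected, n_expected = brute_force_module_score(
            module, store, mt, tt, cfg, scalers)
        assert N == n_expected
        assert F == pytest.approx(expected, rel=1e-10, abs=1e-12)


def test_module_fitness_member_order_invariance():
    rng = np.random.default_rng(22)
    store = make_store(rng, n_genes=8, n_mirnas=4)
    mt = make_targets(rng, store.mirnas, store.genes, "miRNA")
    tt = make_targets(rng, ["g0", "g1"], store.genes, "TF")
    ledger = build_ledger(store, mt, tt, LSConfig())
    module = random_module(rng, store, {"g0", "g1"})
    results = {module_fitness(module, ledger, LSConfig())[0] for _ in range(5)}
    assert len(results) == 1


def test_build_candidate_pool_either_or_semantics():
    # m0 targets g3 (edge only); m1 has a significant PCC only; m2 neither
    store = CorrelationStore(
        genes=["g0", "g3"], mirnas=["m0", "m1", "m2"],
        gg_cor=np.eye(2), mm_cor=np.eye(3),
        mg_cor=np.array([[0.0, 0.0], [0.9, 0.0], [0.0, 0.0]]),
        gg_pval=np.ones((2, 2)), mm_pval=np.ones((3, 3)),
        mg_pval=np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 1.0]]),
        alpha=0.5)
    mt = TargetTable(pd.DataFrame(
        [("m0", "g3", 0.7)], columns=["regulator_id", "gene_id", "score"]),
        "miRNA")
    tt = TargetTable(pd.DataFrame(
        [("g0", "g3", 0.9)], columns=["regulator_id", "gene_id", "score"]), "TF")
    mirnas, tfs = build_candidate_pool(["g0", "g3"], mt, tt, store, {"g0"})
    assert mirnas == ["m0", "m1"]
    assert tfs == ["g0"]  # TF gene inside the set is always a candidate
    with pytest.raises(DataError, match="no candidate regulators"):
        empty_mt = TargetTable(pd.DataFrame(
            [("mX", "gX", 0.5)], columns=["regulator_id", "gene_id", "score"]),
            "miRNA")
        store2 = CorrelationStore(
            genes=["g0", "g3"], mirnas=[],
            gg_cor=np.eye(2), mm_cor=np.zeros((0, 0)),
            mg_cor=np.zeros((0, 2)), gg_pval=np.ones((2, 2)),
            mm_pval=np.zeros((0, 0)), mg_pval=np.zeros((0, 2)), alpha=0.5)
        build_candidate_pool(["g0", "g3"], empty_mt, empty_mt, store2, set())


def test_init_solution_sizes_and_determinism():
    rng = np.random.default_rng(23)
    pool = [f"m{i}" for i in range(200)]
    cfg = LSConfig(mirna_cap_fraction=0.01)
    m1 = init_solution(["t1", "r1", "r2"], (pool, ["t1"]), {"t1"}, cfg,
                       np.random.default_rng(1))
    assert len(m1.mirnas) == 2  # ceil(0.01 * 200)
    assert m1.tf_genes == {"t1"} and m1.ntf_genes == {"r1", "r2"}
    m2 = init_solution(["t1", "r1", "r2"], (pool, ["t1"]), {"t1"}, cfg,
                       np.random.default_rng(1))
    assert m1.mirnas == m2.mirnas
    with pytest.warns(UserWarning, match="empty miRNA"):
        m3 = init_solution(["r1"], ([], []), set(), cfg, rng)
    assert m3.mirnas == frozenset() and m3.tf_genes == frozenset()


def test_propose_move_cap_semantics():
    rng = np.random.default_rng(24)
    module = Module(mirnas={"m0", "m1"}, tf_genes=set(), ntf_genes={"r1"},
                    genes={"r1"})
    pool = ["m0", "m1", "m2", "m3"]
    cfg = LSConfig(mirna_cap_fraction=0.5)  # cap = 2: at cap -> swap only
    for _ in range(20):
        out = propose_move(module, (pool, []), cfg, rng)
        assert len(out.mirnas) == 2
        assert out.mirnas != module.mirnas
        assert out.genes == module.genes
    # below cap: adds or removals only
    cfg_loose = LSConfig(mirna_cap_fraction=1.0)
    sizes = {len(propose_move(module, (pool, []), cfg_loose, rng).mirnas)
             for _ in range(30)}
    assert sizes <= {1, 3}
    # pool exhausted entirely inside the module at cap: no-op
    stuck = Module(mirnas={"m0"}, tf_genes=set(), ntf_genes={"r1"},
                   genes={"r1"})
    cfg_tight = LSConfig(mirna_cap_fraction=0.001)
    out = propose_move(stuck, (["m0"], []), cfg_tight, rng)
    assert out.mirnas == {"m0"}


def test_run_local_search_monotone_trace_and_caps():
    rng = np.random.default_rng(25)
    store = make_store(rng, n_genes=10, n_mirnas=6, sig_frac=0.5)
    tf_genes = {"g0", "g1"}
    mt = make_targets(rng, store.mirnas, store.genes, "miRNA", rate=0.6)
    tt = make_targets(rng, sorted(tf_genes), store.genes, "TF", rate=0.6)
    cfg = LSConfig(mirna_cap_fraction=0.4, tf_cap_fraction=0.5,
                   max_iterations=300, stagnation_limit=80)
    ledger = build_ledger(store, mt, tt, cfg)
    gene_set = ["g0", "g2", "g3", "g4", "g5"]
    pools = build_candidate_pool(gene_set, mt, tt, store, tf_genes)
    res = run_local_search(gene_set, ledger, pools, tf_genes, cfg,
                           rng=np.random.default_rng(1))
    assert (np.diff(res.trace["fitness"]) >= -1e-15).all()
    assert len(res.module.mirnas) <= _cap(0.4, len(pools[0]))
    assert res.module.genes == frozenset(gene_set)


def test_run_local_search_reaches_enumerated_optimum():
    """On tiny pools the hill climb matches exhaustive enumeration over all
    regulator configurations reachable from the initial solution."""
    hits = 0
    for s in range(30):
        rng = np.random.default_rng(500 + s)
        store = make_store(rng, n_genes=6, n_mirnas=3, sig_frac=0.4)
        tf_genes = {"g0", "g1"}
        mt = make_targets(rng, store.mirnas, store.genes, "miRNA", rate=0.6)
        tt = make_targets(rng, sorted(tf_genes), store.genes, "TF", rate=0.6)
        cfg = LSConfig(mirna_cap_fraction=0.34, tf_cap_fraction=0.5,
                       max_iterations=400, stagnation_limit=120)
        gene_set = ["g0", "g2", "g3", "g4"]
        scalers = fit_scalers(store, mt, tt)
        ledger = build_ledger(store, mt, tt, cfg, scalers=scalers)
        pools = build_candidate_pool(gene_set, mt, tt, store, tf_genes)
        mp, tp = pools
        cap_m, cap_t = _cap(0.34, len(mp)), _cap(0.5, len(tp))
        m_sizes = (range(len(mp) + 1) if cap_m >= len(mp)
                   else [min(cap_m, len(mp))])
        t_init = len([g for g in gene_set if g in tf_genes])
        t_sizes = (range(cap_t + 1) if t_init < cap_t
                   else [max(t_init, cap_t)])
        ntf = frozenset(g for g in gene_set if g not in tf_genes)
        best = -1.0
        for km in m_sizes:
            for mset in itertools.combinations(mp, km):
                for kt in t_sizes:
                    for tset in itertools.combinations(tp, kt):
                        mod = Module(mirnas=frozenset(mset),
                                     tf_genes=frozenset(tset),
                                     ntf_genes=ntf, genes=frozenset(gene_set))
                        best = max(best, module_fitness(mod, ledger, cfg)[0])
        res = run_local_search(gene_set, ledger, pools, tf_genes, cfg,
                               rng=np.random.default_rng(s))
        hits += abs(res.module.fitness - best) < 1e-12
    assert hits >= 27


def test_negative_only_mirna_restricts_correlation_support():
    rng = np.random.default_rng(26)
    store = make_store(rng, n_genes=8, n_mirnas=5, sig_frac=0.8)
    mt = make_targets(rng, store.mirnas, store.genes, "miRNA", rate=0.3)
    tt = make_targets(rng, ["g0"], store.genes, "TF", rate=0.3)
    neg_ledger = build_ledger(store, mt, tt,
                              LSConfig(negative_only_mirna=True))
    # every nonzero miRNA-gene correlation component must stem from a
    # negative signed PCC
    nz = neg_ledger.mg_scaled > 0
    assert (store.mg_cor[nz] < 0).all()
    assert nz.any()
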