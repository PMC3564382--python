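"""Synthetic matched expression datasets with planted regulatory modules.

Each planted module is built from a shared latent factor: member expression
is ``loading * factor + Gaussian noise``, with the loading chosen so that
the expected pairwise |PCC| among members equals ``rho``
(rho = lambda^2 / (lambda^2 + sigma^2)).  miRNA members take negative
loadings when configured, giving the anti-correlation expected of
repressors.  Condition specificity comes through the factor itself: the
factor mean shifts by ``de_effect`` between the two sample groups
(alternating sign across modules so modules stay distinguishable), so every
member inherits a differential-expression signal proportional to its
loading.  A fraction of background features receives an independent group
shift — differentially expressed decoys that survive feature selection
without belonging to any module.  All features sit on a positive baseline
drawn per feature, giving the positive means that a coefficient-of-
variation filter presumes on log-scale expression data.

Planted regulator->member edges are emitted with high binding scores; decoy
edges connect random regulator-gene pairs at ``background_edge_rate`` with
lower scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    DataError,
    ExpressionDataset,
    NTF_CLASS,
    TF_CLASS,
    TargetTable,
)


@dataclass
class ModuleShape:
    n_mirnas: int = 3
    n_tf_genes: int = 2
    n_ntf_genes: int = 10


@dataclass
class SimConfig:
    n_samples_per_group: int = 50
    n_mirnas: int = 30
    n_tf_genes: int = 40
    n_ntf_genes: int = 460
    n_planted_modules: int = 2
    shapes: list[ModuleShape] | None = None  # default: one default shape per module
    rho: float = 0.9
    negative_mirna: bool = True
    de_effect: float = 2.0
    background_de_fraction: float = 0.3
    background_edge_rate: float = 0.002
    true_score_range: tuple[float, float] = (0.7, 0.95)
    decoy_score_range: tuple[float, float] = (0.1, 0.5)
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (5.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise DataError(f"rho must be in (0, 1), got {self.rho}")
        if self.shapes is None:
            self.shapes = [ModuleShape() for _ in range(self.n_planted_modules)]
        if len(self.shapes) != self.n_planted_modules:
            raise DataError("one shape per planted module required")
        need_m = sum(s.n_mirnas for s in self.shapes)
        need_t = sum(s.n_tf_genes for s in self.shapes)
        need_g = sum(s.n_ntf_genes for s in self.shapes)
        if need_m > self.n_mirnas or need_t > self.n_tf_genes \
                or need_g > self.n_ntf_genes:
            raise DataError("planted module shapes do not fit inside universes")


@dataclass
class GroundTruth:
    """Planted membership, true edges and per-feature DE status."""

    modules: list[dict] = field(default_factory=list)
    de_features: list[str] = field(default_factory=list)

    def module_gene_sets(self) -> list[set[str]]:
        return [set(m["tf_genes"]) | set(m["ntf_genes"]) for m in self.modules]

    def module_regulators(self) -> list[set[str]]:
        return [set(m["mirnas"]) | set(m["tf_genes"]) for m in self.modules]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"modules": self.modules, "de_features": self.de_features},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(modules=d["modules"], de_features=d["de_features"])


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_dataset(
    config: SimConfig | None = None,
) -> tuple[ExpressionDataset, dict[str, TargetTable], GroundTruth]:
    """Emit (ExpressionDataset, {"miRNA": ..., "TF": ...}, GroundTruth)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_samples_per_group
    samples = [f"S{i:03d}" for i in range(1, n + 1)]
    group = np.array(["g1"] * cfg.n_samples_per_group
                     + ["g2"] * cfg.n_samples_per_group)
    group_shift = (group == "g2").astype(float)

    mirna_ids = _ids("miR-", cfg.n_mirnas)
    tf_ids = _ids("TF-", cfg.n_tf_genes)
    ntf_ids = _ids("G-", cfg.n_ntf_genes)
    gene_ids = tf_ids + ntf_ids

    sd = cfg.noise_sd
    lam = np.sqrt(cfg.rho / (1 - cfg.rho)) * sd

    expr_genes = rng.normal(0.0, sd, size=(len(gene_ids), n))
    expr_mirna = rng.normal(0.0, sd, size=(len(mirna_ids), n))
    gi = {g: i for i, g in enumerate(gene_ids)}
    mi = {m: i for i, m in enumerate(mirna_ids)}

    # planted modules: disjoint member draws
    free_m, free_t, free_g = list(mirna_ids), list(tf_ids), list(ntf_ids)
    truth = GroundTruth()
    de_features: set[str] = set()
    for k, shape in enumerate(cfg.shapes):
        members_m = sorted(rng.choice(free_m, shape.n_mirnas, replace=False))
        members_t = sorted(rng.choice(free_t, shape.n_tf_genes, replace=False))
        members_g = sorted(rng.choice(free_g, shape.n_ntf_genes, replace=False))
        free_m = [x for x in free_m if x not in members_m]
        free_t = [x for x in free_t if x not in members_t]
        free_g = [x for x in free_g if x not in members_g]

        direction = 1.0 if k % 2 == 0 else -1.0
        factor = rng.normal(0.0, 1.0, size=n) + direction * cfg.de_effect * group_shift
        for g in members_t + members_g:
            expr_genes[gi[g]] = lam * factor + rng.normal(0.0, sd, size=n)
        mir_sign = -1.0 if cfg.negative_mirna else 1.0
        for m in members_m:
            expr_mirna[mi[m]] = mir_sign * lam * factor + rng.normal(0.0, sd, size=n)

        edges = []
        for m in members_m:
            for g in members_t + members_g:
                edges.append([m, g])
        for t in members_t:
            for g in members_t + members_g:
                if g != t:
                    edges.append([t, g])
        truth.modules.append({
            "mirnas": members_m, "tf_genes": members_t, "ntf_genes": members_g,
            "edges": edges,
        })
        de_features |= set(members_m) | set(members_t) | set(members_g)

    # differentially expressed decoys among the remaining background features
    n_decoy_g = int(round(cfg.background_de_fraction * len(free_g)))
    n_decoy_m = int(round(cfg.background_de_fraction * len(free_m)))
    decoy_g = sorted(rng.choice(free_g, n_decoy_g, replace=False)) if n_decoy_g else []
    decoy_m = sorted(rng.choice(free_m, n_decoy_m, replace=False)) if n_decoy_m else []
    for g in decoy_g:
        expr_genes[gi[g]] += cfg.de_effect * sd * group_shift
    for m in decoy_m:
        expr_mirna[mi[m]] += cfg.de_effect * sd * group_shift
    de_features |= set(decoy_g) | set(decoy_m)

    # positive per-feature baselines (log-scale intensities)
    lo, hi = cfg.baseline_range
    expr_genes += rng.uniform(lo, hi, size=(len(gene_ids), 1))
    expr_mirna += rng.uniform(lo, hi, size=(len(mirna_ids), 1))

    dataset = ExpressionDataset(
        mrna=pd.DataFrame(expr_genes, index=gene_ids, columns=samples),
        mirna=pd.DataFrame(expr_mirna, index=mirna_ids, columns=samples),
        groups=pd.Series(group, index=samples, name="group"),
        feature_class=pd.Series(
            [TF_CLASS] * len(tf_ids) + [NTF_CLASS] * len(ntf_ids),
            index=gene_ids, name="class"),
    )

    # target tables: true edges high-scored, decoy edges low-scored
    true_pairs_m = {(m, g) for mod in truth.modules for m, g in mod["edges"]
                    if m in mi}
    true_pairs_t = {(t, g) for mod in truth.modules for t, g in mod["edges"]
                    if t in gi}
    t_lo, t_hi = cfg.true_score_range
    d_lo, d_hi = cfg.decoy_score_range
    rows_m = [(m, g, rng.uniform(t_lo, t_hi)) for m, g in sorted(true_pairs_m)]
    rows_t = [(t, g, rng.uniform(t_lo, t_hi)) for t, g in sorted(true_pairs_t)]
    for m in mirna_ids:
        hits = rng.random(len(gene_ids)) < cfg.background_edge_rate
        for g in np.asarray(gene_ids)[hits]:
            if (m, g) not in true_pairs_m:
                rows_m.append((m, g, rng.uniform(d_lo, d_hi)))
    for t in tf_ids:
        hits = rng.random(len(gene_ids)) < cfg.background_edge_rate
        for g in np.asarray(gene_ids)[hits]:
            if g != t and (t, g) not in true_pairs_t:
                rows_t.append((t, g, rng.uniform(d_lo, d_hi)))

    def _table(rows, kind):
        df = pd.DataFrame(rows, columns=["regulator_id", "gene_id", "score"])
        return TargetTable(df, kind)

    truth.de_features = sorted(de_features)
    return dataset, {"miRNA": _table(rows_m, "miRNA"),
                     "TF": _table(rows_t, "TF")}, truth


def write_simulation(config: SimConfig, outdir) -> Path:
    """Generate and write the full input layout plus ground-truth JSON."""
    from .io import write_expression, write_targets

    outdir = Path(outdir)
    dataset, targets, truth = generate_dataset(config)
    write_expression(dataset, outdir)
    write_targets(targets["miRNA"], outdir / "mirna_targets.tsv")
    write_targets(targets["TF"], outdir / "tf_targets.tsv")
    truth.to_json(outdir / "ground_truth.json")
    return outdir
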