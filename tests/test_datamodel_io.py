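"""Domain-type contracts and tabular round trips."""

import numpy as np
import pandas as pd
import pytest

import mirmod as mm
from mirmod.datamodel import DataError, Interaction, Module, TargetTable
from mirmod import io as mio


def _write_dataset(tmp_path, mrna_cols=None):
    samples = ["s1", "s2", "s3", "s4"]
    mrna = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["gA", "gB", "gC"], columns=samples)
    mirna = pd.DataFrame(
        np.arange(8, dtype=float).reshape(2, 4) + 0.5,
        index=["m1", "m2"], columns=samples)
    if mrna_cols:
        mrna = mrna[mrna_cols]
    mrna.rename_axis("feature_id").to_csv(tmp_path / "mrna.tsv", sep="\t")
    mirna.rename_axis("feature_id").to_csv(tmp_path / "mirna.tsv", sep="\t")
    (tmp_path / "groups.tsv").write_text(
        "sample_id\tgroup\ns1\tA\ns2\tA\ns3\tB\ns4\tB\n")
    (tmp_path / "classes.tsv").write_text(
        "feature_id\tclass\ngA\tTF\ngB\tnTF\ngC\tnTF\n")
    return tmp_path


def test_read_expression_round_trip_and_order_invariance(tmp_path):
    (tmp_path / "a").mkdir()
    d1 = _write_dataset(tmp_path / "a")
    ds = mio.read_expression(d1 / "mrna.tsv", d1 / "mirna.tsv",
                             d1 / "groups.tsv", d1 / "classes.tsv")
    assert ds.samples == ["s1", "s2", "s3", "s4"]
    assert ds.tf_genes == ["gA"] and ds.ntf_genes == ["gB", "gC"]
    # same data with shuffled mRNA column order loads to the same dataset
    d2 = (tmp_path / "b")
    d2.mkdir()
    _write_dataset(d2, mrna_cols=["s3", "s1", "s4", "s2"])
    ds2 = mio.read_expression(d2 / "mrna.tsv", d2 / "mirna.tsv",
                              d2 / "groups.tsv", d2 / "classes.tsv")
    pd.testing.assert_frame_equal(ds.mrna[sorted(ds.mrna.columns)],
                                  ds2.mrna[sorted(ds2.mrna.columns)])
    pd.testing.assert_frame_equal(ds.mirna[ds.mirna.columns],
                                  ds2.mirna[ds.mirna.columns])


def test_read_expression_rejects_three_groups(tmp_path):
    d = _write_dataset(tmp_path)
    (tmp_path / "groups.tsv").write_text(
        "sample_id\tgroup\ns1\tA\ns2\tB\ns3\tC\ns4\tB\n")
    with pytest.raises(DataError, match="exactly two groups"):
        mio.read_expression(d / "mrna.tsv", d / "mirna.tsv",
                            d / "groups.tsv", d / "classes.tsv")


def test_read_expression_rejects_nan_with_coordinates(tmp_path):
    d = _write_dataset(tmp_path)
    text = (tmp_path / "mrna.tsv").read_text().replace("6.0", "")
    (tmp_path / "mrna.tsv").write_text(text)
    with pytest.raises(DataError, match="NaN"):
        mio.read_expression(d / "mrna.tsv", d / "mirna.tsv",
                            d / "groups.tsv", d / "classes.tsv")


def test_read_expression_warns_and_drops_unmatched_samples(tmp_path):
    d = _write_dataset(tmp_path)
    (tmp_path / "groups.tsv").write_text(
        "sample_id\tgroup\ns1\tA\ns2\tA\ns3\tB\ns4\tB\ns5\tB\n")
    with pytest.warns(UserWarning, match="s5"):
        ds = mio.read_expression(d / "mrna.tsv", d / "mirna.tsv",
                                 d / "groups.tsv", d / "classes.tsv")
    assert ds.samples == ["s1", "s2", "s3", "s4"]


@pytest.mark.parametrize(
    "rows, n_expected",
    [([("m1", "g1", 0.7), ("m1", "g2", 0.9)], 2),
     ([("m1", "g1", 0.7), ("m1", "g1", 0.7)], 1)],
)
def test_read_targets_dedup(tmp_path, rows, n_expected):
    path = tmp_path / "targets.tsv"
    body = "\n".join(f"{r}\t{g}\t{s}" for r, g, s in rows)
    path.write_text(f"regulator_id\tgene_id\tscore\n{body}\n")
    table = mio.read_targets(path, "miRNA")
    assert len(table) == n_expected


def test_read_targets_rejects_out_of_range_score(tmp_path):
    path = tmp_path / "targets.tsv"
    path.write_text("regulator_id\tgene_id\tscore\nm1\tg1\t1.3\n")
    with pytest.raises(DataError, match=r"out of \(0,1\]"):
        mio.read_targets(path, "miRNA")


def test_target_table_rejects_conflicting_duplicates():
    df = pd.DataFrame(
        [("m1", "g1", 0.7), ("m1", "g1", 0.8)],
        columns=["regulator_id", "gene_id", "score"])
    with pytest.raises(DataError, match="conflicting"):
        TargetTable(df, "miRNA")


def test_module_member_sets_must_be_disjoint():
    with pytest.raises(DataError):
        Module(mirnas={"x"}, tf_genes={"x"}, ntf_genes=set(), genes={"x"})


def _toy_modules():
    interactions = [
        Interaction("m1", "g1", "miRNA-gene", "both", -0.8, 0.7),
        Interaction("m1", "g2", "miRNA-gene", "both", -0.6, 0.9),
        Interaction("t1", "g1", "TF-gene", "pcc_only", 0.9, 0.0),
        Interaction("t1", "g2", "TF-gene", "pcc_only", 0.7, 0.0),
        Interaction("t1", "g3", "TF-gene", "pcc_only", 0.6, 0.0),
        Interaction("m1", "g3", "miRNA-gene", "binding_only", 0.0, 0.5),
    ]
    return [Module(
        mirnas={"m1"}, tf_genes={"t1"}, ntf_genes={"g1", "g2", "g3"},
        genes={"t1", "g1", "g2", "g3"}, fitness=1.1, final_score=1.2,
        p_value=0.001, interactions=interactions)]


def test_module_report_counts_sum_and_round_trip(tmp_path):
    modules = _toy_modules()
    out = mio.write_module_report(modules, tmp_path / "report")
    summary = pd.read_csv(out / "modules_summary.tsv", sep="\t")
    row = summary.iloc[0]
    assert row.n_both + row.n_pcc_only + row.n_binding_only == row.n_interactions == 6
    back = mio.read_module_report(out)
    assert back[0].mirnas == modules[0].mirnas
    assert back[0].final_score == modules[0].final_score
    assert sorted((i.source, i.target) for i in back[0].interactions) == \
        sorted((i.source, i.target) for i in modules[0].interactions)


def test_module_report_writer_is_deterministic(tmp_path):
    modules = _toy_modules()
    out1 = mio.write_module_report(modules, tmp_path / "r1")
    out2 = mio.write_module_report(modules, tmp_path / "r2")
    for name in ("modules_summary.tsv", "module_01_edges.tsv", "modules.json"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_module_report_requires_evaluated_modules(tmp_path):
    module = Module(mirnas={"m1"}, tf_genes=set(), ntf_genes={"g1"},
                    genes={"g1"})
    with pytest.raises(DataError, match="not been evaluated"):
        mio.write_module_report([module], tmp_path / "report")


def test_empty_module_list_writes_header_only_summary(tmp_path):
    out = mio.write_module_report([], tmp_path / "report")
    summary = pd.read_csv(out / "modules_summary.tsv", sep="\t")
    assert len(summary) == 0 and "final_score" in summary.columns
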