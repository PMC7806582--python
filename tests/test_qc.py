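import numpy as np
import pandas as pd
import pytest

import isobiome as ib


def _meta(samples, controls=()):
    rows = []
    for s in samples:
        rows.append(
            {
                "bird_id": s if s not in controls else "",
                "sex": "female" if s not in controls else "unknown",
                "stage": "incubating" if s not in controls else "",
                "sampling_point": 1 if s not in controls else 0,
                "is_negative_control": s in controls,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample_id"))


@pytest.fixture
def contaminated_table():
    """6 samples (2 controls) x 5 ASVs with hand-enumerable prevalences.

    ctl prevalence: f1 2/2, f2 1/2, f3 2/2, f4 0/2, f5 2/2 (but absent in feces).
    Expected contaminants at 0.5: f1 (prev 1.0, in feces), f3 (prev 1.0, in
    feces); f2 prev 0.5 and in feces -> contaminant too; f5 prev 1.0 but not
    in any fecal sample -> retained (column empty after control drop).
    """
    counts = pd.DataFrame(
        {
            "f1": [3, 4, 10, 0, 5, 0],
            "f2": [2, 0, 0, 7, 0, 3],
            "f3": [1, 1, 0, 2, 2, 0],
            "f4": [0, 0, 5, 5, 5, 5],
            "f5": [6, 6, 0, 0, 0, 0],
        },
        index=["c1", "c2", "x1", "x2", "x3", "x4"],
    )
    return ib.FeatureTable(counts), _meta(list(counts.index), controls=("c1", "c2"))


def test_contaminant_removal_hand_enumerated(contaminated_table):
    table, meta = contaminated_table
    out, report = ib.remove_control_contaminants(table, meta)
    assert sorted(report.removed_feature_ids) == ["f1", "f2", "f3"]
    assert sorted(report.removed_sample_ids) == ["c1", "c2"]
    assert out.sample_ids == ["x1", "x2", "x3", "x4"]
    assert sorted(out.feature_ids) == ["f4", "f5"]


def test_contaminant_below_threshold_retained():
    counts = pd.DataFrame(
        {"f1": [1, 0, 0, 4]}, index=["c1", "c2", "c3", "x1"]
    )
    table = ib.FeatureTable(counts)
    meta = _meta(["c1", "c2", "c3", "x1"], controls=("c1", "c2", "c3"))
    out, report = ib.remove_control_contaminants(table, meta)
    assert report.removed_feature_ids == []  # prevalence 1/3 < 0.5
    assert out.feature_ids == ["f1"]


def test_contaminant_no_controls_warns_noop(toy_table, caplog):
    meta = _meta(toy_table.sample_ids)
    with caplog.at_level("WARNING", logger="isobiome"):
        out, report = ib.remove_control_contaminants(toy_table, meta)
    assert "skipped" in caplog.text
    assert out.counts.equals(toy_table.counts)


@pytest.mark.parametrize("depths,expected_removed", [((999,), 1), ((1000,), 0)])
def test_low_depth_boundary_strict(depths, expected_removed):
    rows = {f"s{i}": [d] for i, d in enumerate(depths)}
    rows["deep"] = [76942]
    table = ib.FeatureTable(pd.DataFrame.from_dict(rows, orient="index", columns=["f1"]))
    out, report = ib.remove_low_depth_samples(table)
    assert report.samples_removed == expected_removed


def test_low_depth_fixture_counts():
    table = ib.FeatureTable(
        pd.DataFrame({"f1": [500, 1000, 76942]}, index=["a", "b", "c"])
    )
    out, report = ib.remove_low_depth_samples(table)
    assert report.removed_sample_ids == ["a"]
    assert out.sample_ids == ["b", "c"]


def test_low_depth_all_removed_errors():
    table = ib.FeatureTable(pd.DataFrame({"f1": [5, 6]}, index=["a", "b"]))
    with pytest.raises(ValueError, match="all"):
        ib.remove_low_depth_samples(table)


def test_singletons_definition_is_table_wide():
    counts = pd.DataFrame(
        {"single": [1, 0], "split": [1, 1], "empty": [0, 0], "big": [5, 5]},
        index=["s1", "s2"],
    )
    out, reports = ib.remove_singletons(ib.FeatureTable(counts))
    by_stage = {r.stage: r for r in reports}
    assert by_stage["singletons"].removed_feature_ids == ["single"]
    assert by_stage["empty_features"].removed_feature_ids == ["empty"]
    assert sorted(out.feature_ids) == ["big", "split"]


def test_taxonomy_filter(tmp_path):
    tax_path = tmp_path / "tax.tsv"
    tax_path.write_text(
        "feature_id\tlineage\n"
        "keep\tBacteria;Firmicutes;Bacilli;Lactobacillales;Enterococcaceae;Catellicoccus\n"
        "mito\tBacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria\n"
        "chloro\tBacteria;Cyanobacteria;Oxyphotobacteria;Chloroplast\n"
        "nodomain\t;\n"
    )
    taxonomy = ib.read_taxonomy(tax_path)
    counts = pd.DataFrame(
        {f: [2, 3] for f in ["keep", "mito", "chloro", "nodomain", "missing"]},
        index=["s1", "s2"],
    )
    out, report = ib.remove_unassigned_and_organelles(ib.FeatureTable(counts), taxonomy)
    assert sorted(report.removed_feature_ids) == ["chloro", "missing", "mito", "nodomain"]
    assert out.feature_ids == ["keep"]


def _engineered_cascade_inputs(tmp_path):
    """Each stage removes a known count: 1 contaminant, 1 shallow sample,
    1 singleton, 1 organelle."""
    counts = pd.DataFrame(
        {
            "contam": [8, 8, 3, 0, 0],
            "good1": [0, 0, 1500, 1200, 400],
            "good2": [0, 0, 600, 900, 500],
            "single": [0, 0, 1, 0, 0],
            "mito": [0, 0, 30, 40, 50],
        },
        index=["c1", "c2", "x1", "x2", "shallow"],
    )
    table = ib.FeatureTable(counts)
    meta = _meta(list(counts.index), controls=("c1", "c2"))
    tax_path = tmp_path / "tax.tsv"
    tax_path.write_text(
        "feature_id\tlineage\n"
        "contam\tBacteria;Proteobacteria\n"
        "good1\tBacteria;Firmicutes\n"
        "good2\tBacteria;Fusobacteria\n"
        "single\tBacteria;Firmicutes\n"
        "mito\tBacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria\n"
    )
    return table, meta, ib.read_taxonomy(tax_path)


def test_cascade_engineered_counts(tmp_path):
    table, meta, taxonomy = _engineered_cascade_inputs(tmp_path)
    out, reports = ib.run_qc_cascade(table, meta, taxonomy)
    by_stage = {r.stage: r for r in reports}
    assert by_stage["control_contaminants"].removed_feature_ids == ["contam"]
    assert by_stage["low_depth_samples"].removed_sample_ids == ["shallow"]
    assert by_stage["singletons"].removed_feature_ids == ["single"]
    assert by_stage["unassigned_and_organelles"].removed_feature_ids == ["mito"]
    assert out.sample_ids == ["x1", "x2"]
    assert sorted(out.feature_ids) == ["good1", "good2"]
    # report removal counts account exactly for the feature delta
    assert sum(r.features_removed for r in reports) == len(table.feature_ids) - len(out.feature_ids)


def test_cascade_idempotent(tmp_path):
    table, meta, taxonomy = _engineered_cascade_inputs(tmp_path)
    once, _ = ib.run_qc_cascade(table, meta, taxonomy)
    twice, reports = ib.run_qc_cascade(once, meta, taxonomy)
    assert twice.counts.equals(once.counts)
    assert all(r.features_removed == 0 and r.samples_removed == 0 for r in reports)


def test_cascade_clean_table_unchanged(tmp_path):
    counts = pd.DataFrame(
        {"good1": [1500, 1200], "good2": [600, 900]}, index=["x1", "x2"]
    )
    table = ib.FeatureTable(counts)
    meta = _meta(["x1", "x2"])
    tax_path = tmp_path / "tax.tsv"
    tax_path.write_text(
        "feature_id\tlineage\ngood1\tBacteria;Firmicutes\ngood2\tBacteria;Fusobacteria\n"
    )
    out, reports = ib.run_qc_cascade(table, meta, ib.read_taxonomy(tax_path))
    assert out.counts.equals(table.counts)
    assert sum(r.features_removed + r.samples_removed for r in reports) == 0


def test_cascade_only_drops_never_modifies(tmp_path):
    table, meta, taxonomy = _engineered_cascade_inputs(tmp_path)
    out, _ = ib.run_qc_cascade(table, meta, taxonomy)
    sub = table.counts.loc[out.sample_ids, out.feature_ids]
    assert out.counts.equals(sub)
    assert out.counts.to_numpy().sum() <= table.counts.to_numpy().sum()
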