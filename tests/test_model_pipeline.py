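import json

import numpy as np
import pytest
from click.testing import CliRunner

from dcanet import CVConfig, DCAModel
from dcanet.cli import main
from dcanet.pipeline import PipelineConfig, run_pipeline
from dcanet.synthetic import SyntheticSpec


@pytest.fixture(scope="module")
def small_spec():
    """Reduced-scale preset so pipeline tests stay fast."""
    return SyntheticSpec(
        n_drugs=24,
        n_complexes=30,
        n_proteins=20,
        n_families=4,
        n_motifs=30,
        motifs_per_family=8,
        seed=17,
    )


def test_model_fit_summary_and_predictions(small_spec):
    res = DCAModel.from_synthetic(small_spec).fit()
    assert res.clustering.k == 24  # k = auto = number of drugs
    text = res.summary()
    assert "clusters" in text and "edges" in text
    pred = res.predict("CN")
    assert pred["counts"]["n_scored"] == res.network.n_drugs * res.network.n_clusters
    assert pred["counts"]["n_important"] <= pred["counts"]["n_significant"]
    sig_pairs = {(d, c) for d, c, _ in pred["significant"]}
    imp_pairs = {(d, c) for d, c, _ in pred["important"]}
    assert imp_pairs <= sig_pairs
    # every expansion row references a significant pair's drug
    assert {r["drug_id"] for r in pred["drug_trimer"]} <= {d for d, _ in sig_pairs}


def test_model_multiplicity_and_degrees(small_spec):
    res = DCAModel.from_synthetic(small_spec).fit()
    mult = res.multiplicity()
    assert abs(sum(mult.values()) - 1.0) < 1e-12
    deg = res.degrees(drug_band=(1, 1000))
    assert deg["drug_degree_band_fraction"] == 1.0


def test_model_evaluate_deterministic(small_spec):
    res = DCAModel.from_synthetic(small_spec).fit()
    cfg = CVConfig(n_folds=5, seed=3)
    r1 = res.evaluate("CN", cfg)
    r2 = res.evaluate("CN", cfg)
    assert r1.to_dict() == r2.to_dict()


def test_pipeline_writes_all_artifacts_and_is_deterministic(tmp_path, small_spec):
    model = DCAModel.from_synthetic(small_spec)
    cfg = PipelineConfig(
        out_dir=str(tmp_path / "run1"),
        n_folds=5,
        benchmark_repetitions=5,
        seed=11,
    )
    out = run_pipeline(cfg, model=model)
    expected = [
        "embedding.json", "trimers.tsv", "clusters.tsv", "centroids.tsv",
        "network_edges.tsv", "adjacency.tsv", "evidence.tsv",
        "scores_CN.tsv", "significant.tsv", "important.tsv",
        "drug_trimer_predictions.tsv", "drug_protein_predictions.tsv",
        "report.json", "manifest.json",
    ]
    for name in expected:
        assert (out / name).exists(), name
    manifest = json.loads((out / "manifest.json").read_text())
    assert set(manifest["stages"]) == {
        "io", "embedding", "trimers", "clustering", "network",
        "link_prediction", "evaluation",
    }

    cfg2 = PipelineConfig(
        out_dir=str(tmp_path / "run2"), n_folds=5, benchmark_repetitions=5, seed=11
    )
    out2 = run_pipeline(cfg2, model=DCAModel.from_synthetic(small_spec))
    manifest2 = json.loads((out2 / "manifest.json").read_text())
    assert manifest["stages"] == manifest2["stages"]


def test_pipeline_error_is_recorded(tmp_path):
    cfg = PipelineConfig(out_dir=str(tmp_path / "bad"))  # no input paths
    with pytest.raises(ValueError):
        run_pipeline(cfg)
    manifest = json.loads((tmp_path / "bad" / "manifest.json").read_text())
    assert "error" in manifest


def test_config_file_round_trip(tmp_path):
    p = tmp_path / "dca.conf"
    p.write_text("k = 12\nmethod = PA\nseed = 9\nnegatives_per_positive = 2.0\n")
    cfg = PipelineConfig.from_file(p)
    assert cfg.k == 12 and cfg.method == "PA" and cfg.seed == 9
    assert cfg.negatives_per_positive == 2.0
    bad = tmp_path / "bad.conf"
    bad.write_text("nonsense = 1\n")
    with pytest.raises(ValueError, match="nonsense"):
        PipelineConfig.from_file(bad)


def test_cli_simulate_then_run(tmp_path):
    runner = CliRunner()
    sim_dir = tmp_path / "sim"
    r = runner.invoke(main, ["simulate", "--seed", "5", "--out", str(sim_dir)])
    assert r.exit_code == 0, r.output
    assert (sim_dir / "properties.tsv").exists()
    assert (sim_dir / "complexes.tsv").exists()
    truth = json.loads((sim_dir / "ground_truth.json").read_text())
    assert len(truth["drug_motifs"]) == 97

    out_dir = tmp_path / "out"
    r = runner.invoke(
        main,
        [
            "run",
            "--properties", str(sim_dir / "properties.tsv"),
            "--complexes", str(sim_dir / "complexes.tsv"),
            "--out", str(out_dir),
            "--folds", "5",
            "--benchmark-reps", "3",
            "--seed", "5",
        ],
    )
    assert r.exit_code == 0, r.output
    assert (out_dir / "manifest.json").exists()


def test_cli_stage_commands(tmp_path, small_spec):
    from dcanet.io import write_complex_table, write_property_table
    from dcanet.synthetic import generate_complexes, generate_property_table

    props = tmp_path / "props.tsv"
    cxs = tmp_path / "cxs.tsv"
    write_property_table(generate_property_table(small_spec), props)
    write_complex_table(generate_complexes(small_spec).records, cxs)
    runner = CliRunner()

    emb = tmp_path / "emb.json"
    r = runner.invoke(main, ["embed", "--properties", str(props), "--out", str(emb)])
    assert r.exit_code == 0, r.output

    tri = tmp_path / "trimers.tsv"
    r = runner.invoke(main, ["trimers", "--complexes", str(cxs), "--out", str(tri)])
    assert r.exit_code == 0, r.output

    clu = tmp_path / "clusters.tsv"
    r = runner.invoke(main, [
        "cluster", "--complexes", str(cxs), "--embedding", str(emb),
        "--k", "10", "--out", str(clu),
    ])
    assert r.exit_code == 0, r.output

    net = tmp_path / "net.tsv"
    r = runner.invoke(main, [
        "network", "--properties", str(props), "--complexes", str(cxs),
        "--out", str(net),
    ])
    assert r.exit_code == 0, r.output

    rpt = tmp_path / "report.json"
    r = runner.invoke(main, [
        "evaluate", "--properties", str(props), "--complexes", str(cxs),
        "--folds", "4", "--benchmark-reps", "2", "--out", str(rpt),
    ])
    assert r.exit_code == 0, r.output
    assert json.loads(rpt.read_text())["mean_auc"] >= 0.0


def test_cli_run_nonzero_exit_on_failure(tmp_path):
    runner = CliRunner()
    r = runner.invoke(main, ["run", "--out", str(tmp_path / "x")])
    assert r.exit_code != 0
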