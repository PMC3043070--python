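import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mirmint.io import annotations_to_frame
from mirmint.preprocess import preprocess_mirna
from mirmint.simulate import (
    CohortConfig,
    ModuleSpec,
    PlantedDE,
    TargetSpec,
    generate_cohort,
    generate_gene_sets,
    generate_target_table,
    read_truth_report,
    replicate_groups,
    truth_report,
)
from mirmint.tnom import differential_expression_table


def de_config(seed=1, effect=4.0):
    return CohortConfig(
        n_samples=60,
        n_mirna=200,
        n_mrna=100,
        replicates=2,
        subtype_proportions={"basal-like": 0.5, "luminal-A": 0.5},
        planted_de=[PlantedDE(10, effect, "up", ("subtype", "basal-like", "luminal-A"))],
        target_spec=TargetSpec(pivot=0, n_targets=20, rho=-0.5),
        modules=[ModuleSpec("mod1", 30, 0.7, pivot_couplings={1: 0.7})],
        seed=seed,
    )


class TestGenerateCohort:
    def test_shapes_and_scales(self):
        cfg = de_config()
        mirna, mrna, ann, truth = generate_cohort(cfg)
        assert mirna.values.shape == (200, 120)  # 2 replicate arrays per sample
        assert mrna.values.shape == (100, 60)
        assert mirna.scale == "linear" and (mirna.values > 0).all()
        assert mirna.detection is not None
        assert len(ann) == 60

    def test_same_seed_bit_identical(self):
        m1, r1, _, _ = generate_cohort(de_config(seed=5))
        m2, r2, _, _ = generate_cohort(de_config(seed=5))
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(m1.detection, m2.detection)
        np.testing.assert_array_equal(r1.values, r2.values)

    def test_different_seed_differs(self):
        m1, *_ = generate_cohort(de_config(seed=5))
        m2, *_ = generate_cohort(de_config(seed=6))
        assert not np.array_equal(m1.values, m2.values)

    def test_invalid_config_lists_violations(self):
        cfg = de_config()
        cfg.n_samples = 0
        cfg.subtype_proportions = {"basal-like": 0.7}
        with pytest.raises(ValueError, match="n_samples.*sum to 1"):
            generate_cohort(cfg)

    def test_planted_de_recovered_by_pipeline(self):
        cfg = de_config(seed=1, effect=4.0)
        mirna, _, ann, truth = generate_cohort(cfg)
        m = preprocess_mirna(mirna, replicate_groups(mirna))
        adf = annotations_to_frame(ann)
        a = adf.index[adf.subtype == "basal-like"].tolist()
        b = adf.index[adf.subtype == "luminal-A"].tolist()
        table = differential_expression_table(m, a, b)
        planted = {f for f, *_ in truth.de_features}
        assert planted <= set(table.head(15)["feature_id"])

    def test_detection_dropout_tracks_intensity(self):
        mirna, *_ = generate_cohort(de_config())
        intensity = np.log2(mirna.values).mean(axis=1)
        det_rate = mirna.detection.mean(axis=1)
        assert spearmanr(intensity, det_rate).statistic > 0.5

    def test_planted_target_anticorrelation_strength(self):
        cfg = de_config()
        mirna, mrna, ann, truth = generate_cohort(cfg)
        m = preprocess_mirna(mirna, replicate_groups(mirna))
        pid, gid, rho = truth.target_pairs[0]
        r = spearmanr(m.feature_vector(pid), np.log2(mrna.feature_vector(gid)))
        assert r.statistic < -0.2  # planted near -0.5, noisy at n=60


class TestGeneSets:
    def test_module_plus_decoys(self):
        *_, truth = generate_cohort(de_config())
        sets = generate_gene_sets(truth, n_decoys=50, decoy_size_range=(5, 20), seed=3)
        assert len(sets) == 51
        module_genes = set(truth.modules["mod1"])
        for name in sets.names():
            if name != "mod1":
                assert not module_genes & set(sets.members(name))

    def test_seed_stable(self):
        *_, truth = generate_cohort(de_config())
        s1 = generate_gene_sets(truth, 10, (5, 10), seed=3)
        s2 = generate_gene_sets(truth, 10, (5, 10), seed=3)
        assert {n: s1.members(n) for n in s1.names()} == {
            n: s2.members(n) for n in s2.names()
        }

    def test_oversized_decoys_rejected(self):
        *_, truth = generate_cohort(de_config())
        with pytest.raises(ValueError):
            generate_gene_sets(truth, 1, (90, 1000), seed=0)


class TestTargetTable:
    def test_counts_and_score_separation(self):
        *_, truth = generate_cohort(de_config())
        table = generate_target_table(truth, n_background_pairs=500, seed=1)
        assert len(table) == len(truth.target_pairs) + 500
        planted = {(p, g) for p, g, _ in truth.target_pairs}
        df = table.records
        is_planted = df.apply(lambda r: (r["mirna"], r["gene"]) in planted, axis=1)
        assert df.loc[is_planted, "score"].mean() < df.loc[~is_planted, "score"].mean()

    def test_planted_dominate_most_negative_scores(self):
        *_, truth = generate_cohort(de_config(seed=1))
        n_planted = len(truth.target_pairs)
        table = generate_target_table(truth, n_background_pairs=5000, seed=1)
        planted = {(p, g) for p, g, _ in truth.target_pairs}
        top = table.records.nsmallest(n_planted, "score")
        frac = np.mean([(m, g) in planted for m, g in zip(top["mirna"], top["gene"])])
        assert frac >= 0.8

    def test_requires_target_spec(self):
        cfg = de_config()
        cfg.target_spec = None
        *_, truth = generate_cohort(cfg)
        with pytest.raises(ValueError):
            generate_target_table(truth)


class TestTruthReport:
    def test_roundtrip_lists_everything(self, tmp_path):
        *_, truth = generate_cohort(de_config())
        path = tmp_path / "truth.tsv"
        truth_report(truth, path)
        df = read_truth_report(path)
        assert set(df["kind"]) == {"de", "module", "pivot", "target"}
        assert (df["kind"] == "de").sum() == len(truth.de_features)
        assert set(df.loc[df["kind"] == "module", "item"]) == set(
            truth.modules["mod1"]
        )

    def test_empty_truth_header_only(self, tmp_path):
        from mirmint.simulate import SyntheticTruth

        truth = SyntheticTruth([], [], [], {}, [], [])
        path = tmp_path / "truth.tsv"
        truth_report(truth, path)
        assert len(read_truth_report(path)) == 0


def test_emitted_files_roundtrip_to_in_memory_objects(tmp_path):
    from mirmint.io import (
        read_detection_tsv,
        read_expression_tsv,
        read_sample_annotations,
        write_detection_tsv,
        write_expression_tsv,
        write_table,
    )

    mirna, mrna, ann, _ = generate_cohort(de_config())
    write_expression_tsv(mirna, tmp_path / "mi.tsv")
    write_detection_tsv(mirna, tmp_path / "mi.det.tsv")
    back = read_expression_tsv(tmp_path / "mi.tsv")
    assert back.feature_ids == mirna.feature_ids
    assert back.sample_ids == mirna.sample_ids
    np.testing.assert_allclose(back.values, mirna.values, rtol=1e-9)
    np.testing.assert_array_equal(read_detection_tsv(tmp_path / "mi.det.tsv"),
                                  mirna.detection)
    write_table(annotations_to_frame(ann).reset_index(), tmp_path / "ann.tsv")
    back_ann = read_sample_annotations(tmp_path / "ann.tsv")
    assert back_ann == ann


def test_null_config_keeps_tnom_superuniform(null_cohort):
    cfg, (mirna, mrna, ann, truth) = null_cohort
    m = preprocess_mirna(mirna, replicate_groups(mirna))
    adf = annotations_to_frame(ann)
    a = adf.index[adf.subtype == "basal-like"].tolist()
    b = adf.index[adf.subtype == "luminal-A"].tolist()
    table = differential_expression_table(m, a, b)
    for alpha in (0.01, 0.05, 0.1):
        frac = (table["tnom_p"] <= alpha).mean()
        # superuniform: within binomial upper envelope of alpha
        assert frac <= alpha + 2.576 * np.sqrt(alpha * (1 - alpha) / len(table))


def test_effect_size_monotonicity_of_recovery():
    recovered = []
    for effect in (0.5, 1.0, 2.0, 4.0):
        counts = []
        for seed in range(3):
            cfg = de_config(seed=seed, effect=effect)
            mirna, _, ann, truth = generate_cohort(cfg)
            m = preprocess_mirna(mirna, replicate_groups(mirna))
            adf = annotations_to_frame(ann)
            a = adf.index[adf.subtype == "basal-like"].tolist()
            b = adf.index[adf.subtype == "luminal-A"].tolist()
            table = differential_expression_table(m, a, b)
            planted = {f for f, *_ in truth.de_features}
            hits = set(table.loc[table["q"] < 0.05, "feature_id"])
            counts.append(len(hits & planted))
        recovered.append(np.mean(counts))
    assert all(b >= a - 0.5 for a, b in zip(recovered, recovered[1:]))
    assert recovered[-1] >= 9
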