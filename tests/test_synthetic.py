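"""Synthetic-data generator: determinism, planted structure, round-trips."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernet.diffexpr import de_table, dysregulated_sets, select_dysregulated
from cernet.preprocess import prepare_matrix
from cernet.synthetic import (
    SimConfig,
    SimTruth,
    generate_dataset,
    null_config,
    read_fixture,
    score_recovery,
    write_fixture,
)


class TestConfigValidation:
    def test_defaults_valid(self):
        SimConfig().validate()

    @pytest.mark.parametrize("kwargs", [
        dict(n_tumor=-1),
        dict(noise_sd=0.0),
        dict(zero_rate=1.0),
        dict(n_triples=50, n_mirna=30),  # cannot host the triples
        dict(baseline_mean_range=(5.0, 3.0)),
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_dataset(SimConfig(**kwargs))


class TestDeterminismAndShape:
    def test_same_seed_bit_identical(self):
        a = generate_dataset(SimConfig(seed=7, n_lnc=10, n_mrna=12, n_mirna=8,
                                       n_triples=4, n_decoy_interactions=20))
        b = generate_dataset(SimConfig(seed=7, n_lnc=10, n_mrna=12, n_mirna=8,
                                       n_triples=4, n_decoy_interactions=20))
        pd.testing.assert_frame_equal(a.lnc.values, b.lnc.values)
        pd.testing.assert_frame_equal(a.interactions, b.interactions)
        assert a.truth.planted_triples == b.truth.planted_triples

    def test_different_seed_differs(self):
        a = generate_dataset(SimConfig(seed=1))
        b = generate_dataset(SimConfig(seed=2))
        assert not a.lnc.values.equals(b.lnc.values)

    def test_zero_triples_degenerate(self):
        ds = generate_dataset(SimConfig(n_triples=0, n_decoy_interactions=10))
        assert ds.truth.planted_triples == []
        assert set(ds.interactions["evidence"]) <= {"validated", "predicted"}

    def test_truth_labels_consistent_with_planting(self, strong_dataset):
        truth = strong_dataset.truth
        for lnc, mir, mrna in truth.planted_triples:
            assert truth.de_labels[lnc] == "up"
            assert truth.de_labels[mrna] == "up"
            assert truth.de_labels[mir] == "down"
        assert set(truth.true_interactions).isdisjoint(truth.decoy_interactions)

    def test_interaction_table_contains_planted_pairs(self, strong_dataset):
        have = set(zip(strong_dataset.interactions["mirna_id"],
                       strong_dataset.interactions["target_id"]))
        for lnc, mir, mrna in strong_dataset.truth.planted_triples:
            assert (mir, lnc) in have and (mir, mrna) in have
        n_cfg = strong_dataset.config
        assert len(have) == 2 * n_cfg.n_triples + n_cfg.n_decoy_interactions


class TestPlantedCorrelationStructure:
    def test_planted_lnc_mirna_anticorrelated_across_seeds(self):
        """Tumor-sample PCC(lnc, mirna) of planted triples is negative."""
        n_neg = n_total = 0
        for seed in range(30):
            cfg = SimConfig(seed=seed, n_lnc=8, n_mrna=8, n_mirna=8, n_triples=3,
                            n_decoy_interactions=10, zero_rate=0.0)
            ds = generate_dataset(cfg)
            lnc = prepare_matrix(ds.lnc)
            mir = prepare_matrix(ds.mirna)
            tumor = lnc.samples_in("tumor")
            for l, m, _ in ds.truth.planted_triples:
                r = np.corrcoef(lnc.values.loc[l, tumor],
                                mir.values.loc[m, tumor])[0, 1]
                n_total += 1
                n_neg += r < 0
        assert n_neg >= 0.99 * n_total

    def test_normal_samples_uncoupled(self):
        """The latent factor acts in tumor samples only."""
        cfg = SimConfig(seed=5, n_normal=150, n_tumor=20, zero_rate=0.0)
        ds = generate_dataset(cfg)
        lnc = prepare_matrix(ds.lnc)
        mrna = prepare_matrix(ds.mrna)
        normal = lnc.samples_in("normal")
        rs = [np.corrcoef(lnc.values.loc[l, normal], mrna.values.loc[g, normal])[0, 1]
              for l, _, g in ds.truth.planted_triples]
        # null correlations at n=150: individually small
        assert np.mean(np.abs(rs)) < 0.2

    def test_zero_coupling_indistinguishable_from_decoys(self):
        """With couplings at 0, planted-pair PCCs match the decoy PCCs (KS)."""
        cfg = null_config(seed=0, n_tumor=200, de_lfc_lnc=2.0, de_lfc_mrna=2.0,
                          de_lfc_mirna=-1.5, zero_rate=0.0)
        ds = generate_dataset(cfg)
        mats = {"lncRNA": prepare_matrix(ds.lnc), "mRNA": prepare_matrix(ds.mrna),
                "miRNA": prepare_matrix(ds.mirna)}
        tumor = mats["lncRNA"].samples_in("tumor")

        def pcc(cls_a, a, cls_b, b):
            return np.corrcoef(mats[cls_a].values.loc[a, tumor],
                               mats[cls_b].values.loc[b, tumor])[0, 1]

        planted = []
        for l, m, g in ds.truth.planted_triples:
            planted += [pcc("lncRNA", l, "mRNA", g), pcc("lncRNA", l, "miRNA", m),
                        pcc("mRNA", g, "miRNA", m)]
        cls_of = dict(zip(ds.interactions["target_id"],
                          ds.interactions["target_class"]))
        decoy = [pcc("miRNA", m, cls_of[t], t)
                 for m, t in ds.truth.decoy_interactions]
        assert stats.ks_2samp(planted, decoy).pvalue > 0.01

    def test_planted_lncs_pass_de_gate(self):
        """Planted up-lncRNAs clear the log2FC >= 1, FDR < 0.001 gate."""
        hits = total = 0
        for seed in range(10):
            ds = generate_dataset(SimConfig(seed=seed, n_lnc=30, n_mrna=30,
                                            n_mirna=10, n_triples=5,
                                            n_decoy_interactions=20))
            lnc = prepare_matrix(ds.lnc)
            table = select_dysregulated(de_table(lnc))
            dels = dysregulated_sets(table).get("lncRNA", set())
            for l, _, _ in ds.truth.planted_triples:
                total += 1
                hits += l in dels
        assert hits >= 0.95 * total


class TestFixtureIO:
    def test_round_trip_identity(self, tmp_path, strong_dataset):
        write_fixture(strong_dataset, tmp_path)
        back = read_fixture(tmp_path)
        for attr in ("lnc", "mrna", "mirna"):
            pd.testing.assert_frame_equal(getattr(back, attr).values,
                                          getattr(strong_dataset, attr).values)
        pd.testing.assert_frame_equal(back.interactions,
                                      strong_dataset.interactions)
        assert back.truth.planted_triples == strong_dataset.truth.planted_triples
        assert back.config == strong_dataset.config

    def test_fixture_bytes_deterministic(self, tmp_path):
        cfg = SimConfig(seed=3, n_lnc=6, n_mrna=6, n_mirna=6, n_triples=2,
                        n_decoy_interactions=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_fixture(generate_dataset(cfg), d1)
        p2 = write_fixture(generate_dataset(cfg), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_dataset_valid_headers(self, tmp_path):
        cfg = SimConfig(n_lnc=0, n_mrna=0, n_mirna=0, n_triples=0,
                        n_decoy_interactions=0, frac_de_background=0.0)
        paths = write_fixture(generate_dataset(cfg), tmp_path)
        header = paths["lnc"].read_text().splitlines()[0]
        assert header.startswith("gene_id\t")
        assert len(paths["interactions"].read_text().splitlines()) == 1


class TestScoring:
    truth = SimTruth(planted_triples=[("l1", "m1", "g1"), ("l2", "m2", "g2")],
                     de_labels={}, true_interactions=[], decoy_interactions=[])

    def test_perfect(self):
        assert score_recovery([("l1", "m1", "g1"), ("l2", "m2", "g2")],
                              self.truth) == (1.0, 1.0)

    def test_partial(self):
        p, r = score_recovery([("l1", "m1", "g1"), ("lX", "mX", "gX")], self.truth)
        assert (p, r) == (0.5, 0.5)

    def test_empty_found(self):
        assert score_recovery([], self.truth) == (0.0, 0.0)
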