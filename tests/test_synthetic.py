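import numpy as np
import pytest

from mirpair.qpcr import analyze_plate, paired_group_test
from mirpair.synthetic import (
    SimConfig,
    generate_cohort,
    generate_gene_sets,
    generate_prediction_tables,
    generate_qpcr_plate,
    generate_sequences,
    write_fasta,
    write_qpcr_table,
)
from mirpair.targets import find_seed_sites

SMALL = dict(n_mirna=20, n_mrna=60, n_de_mirna_up=4, n_de_mirna_down=4, n_true_edges=6)


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_pairs=0)

    def test_edges_need_de_mirnas(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_de_mirna_up=0, n_de_mirna_down=0, n_true_edges=5)

    def test_error_rates_bounded(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, pred_fnr=1.2)

    def test_more_edges_than_targets_infeasible(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_mrna=10, n_true_edges=11)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a_mi, a_mr, a_t = generate_cohort(SimConfig(seed=5, **SMALL))
        b_mi, b_mr, b_t = generate_cohort(SimConfig(seed=5, **SMALL))
        assert a_mi.values.equals(b_mi.values)
        assert a_mr.values.equals(b_mr.values)
        assert a_t.edges == b_t.edges and a_t.de_direction == b_t.de_direction

    def test_different_seeds_differ(self):
        a_mi, _, _ = generate_cohort(SimConfig(seed=5, **SMALL))
        b_mi, _, _ = generate_cohort(SimConfig(seed=6, **SMALL))
        assert not a_mi.values.equals(b_mi.values)

    def test_truth_invariants(self):
        _, _, truth = generate_cohort(SimConfig(seed=2, **SMALL))
        for mi, mr in truth.edges:
            assert truth.de_direction[mi] in ("up", "down")
            assert truth.de_direction[mr] != truth.de_direction[mi]
            assert truth.de_direction[mr] in ("up", "down")

    def test_planted_edges_anticorrelated_vs_random(self):
        edge_rs, null_rs = [], []
        for seed in range(10):
            mi_m, mr_m, truth = generate_cohort(SimConfig(seed=seed, **SMALL))
            rng = np.random.default_rng(seed)
            for mi, mr in truth.edges:
                x = mi_m.values.loc[mi].to_numpy()
                y = mr_m.values.loc[mr].to_numpy()
                edge_rs.append(np.corrcoef(x, y)[0, 1])
            for _ in range(len(truth.edges)):
                a = mi_m.values.iloc[rng.integers(mi_m.n_features)].to_numpy()
                b = mr_m.values.iloc[rng.integers(mr_m.n_features)].to_numpy()
                null_rs.append(np.corrcoef(a, b)[0, 1])
        assert np.median(edge_rs) < np.median(null_rs)
        assert np.mean(edge_rs) < -0.5  # coupling 0.9, noise 0.3

    def test_flags_all_detected(self):
        mi_m, mr_m, _ = generate_cohort(SimConfig(seed=1, **SMALL))
        assert (mi_m.flags == "IsGeneDetected;WellAboveNeg").all().all()
        assert (mr_m.flags == "IsFound;IsSaturated;IsWellAboveBG").all().all()


class TestGenerateSequences:
    def test_every_edge_has_8mer_site(self):
        cfg = SimConfig(seed=4, **SMALL)
        _, _, truth = generate_cohort(cfg)
        mirna_seqs, utr_seqs = generate_sequences(truth, cfg)
        for mi, mr in truth.edges:
            sites = find_seed_sites(mirna_seqs[mi], utr_seqs[mr], mi, mr)
            assert any(s.site_type == "8mer" for s in sites)

    def test_decoy_utrs_have_no_de_seed_sites(self):
        cfg = SimConfig(seed=4, **SMALL)
        _, _, truth = generate_cohort(cfg)
        mirna_seqs, utr_seqs = generate_sequences(truth, cfg)
        de_mirnas = [f for f, d in truth.de_direction.items() if f.startswith("mir-")]
        decoys = [g for g in utr_seqs if g not in truth.regulator_of]
        for g in decoys[:20]:
            for mi in de_mirnas:
                assert find_seed_sites(mirna_seqs[mi], utr_seqs[g]) == []

    def test_fasta_deterministic(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL)
        _, _, truth = generate_cohort(cfg)
        for run in ("a", "b"):
            mirna_seqs, utr_seqs = generate_sequences(truth, cfg)
            write_fasta(mirna_seqs, tmp_path / f"mi_{run}.fa")
            write_fasta(utr_seqs, tmp_path / f"utr_{run}.fa")
        assert (tmp_path / "mi_a.fa").read_bytes() == (tmp_path / "mi_b.fa").read_bytes()
        assert (tmp_path / "utr_a.fa").read_bytes() == (tmp_path / "utr_b.fa").read_bytes()

    def test_fasta_wrapped_at_60(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL, utr_len=150)
        _, _, truth = generate_cohort(cfg)
        _, utr_seqs = generate_sequences(truth, cfg)
        write_fasta(utr_seqs, tmp_path / "utr.fa")
        lines = (tmp_path / "utr.fa").read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 60


class TestPredictionTables:
    def test_perfect_sources_equal_truth(self):
        cfg = SimConfig(seed=3, pred_fnr=0.0, pred_fpr=0.0, **SMALL)
        _, _, truth = generate_cohort(cfg)
        a, b = generate_prediction_tables(truth, cfg)
        assert a.pairs == truth.edges and b.pairs == truth.edges

    def test_fnr_one_drops_every_edge(self):
        cfg = SimConfig(seed=3, pred_fnr=1.0, pred_fpr=0.0, **SMALL)
        _, _, truth = generate_cohort(cfg)
        a, b = generate_prediction_tables(truth, cfg)
        assert not (a.pairs & truth.edges) and not (b.pairs & truth.edges)

    def test_intersection_retention_matches_independence(self):
        # each source keeps an edge w.p. 1-fnr independently: E[kept] = (1-fnr)^2
        fracs = []
        for seed in range(50):
            cfg = SimConfig(seed=seed, pred_fnr=0.2, pred_fpr=0.0, **SMALL)
            _, _, truth = generate_cohort(cfg)
            a, b = generate_prediction_tables(truth, cfg)
            fracs.append(len(a.pairs & b.pairs & truth.edges) / len(truth.edges))
        assert np.mean(fracs) == pytest.approx(0.64, abs=0.06)

    def test_sources_differ(self):
        cfg = SimConfig(seed=3, **SMALL)
        _, _, truth = generate_cohort(cfg)
        a, b = generate_prediction_tables(truth, cfg)
        assert a.pairs != b.pairs


class TestQpcrPlate:
    def test_deterministic_csv(self, tmp_path):
        cfg = SimConfig(seed=6, n_qpcr_pairs=10, **SMALL)
        _, _, truth = generate_cohort(cfg)
        assays = [sorted(truth.edges)[0][0]]
        for run in ("a", "b"):
            plate = generate_qpcr_plate(truth, cfg, assays)
            write_qpcr_table(plate, tmp_path / f"{run}.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_failing_assay_is_excluded_by_qc(self):
        cfg = SimConfig(seed=6, n_qpcr_pairs=10, **SMALL)
        _, _, truth = generate_cohort(cfg)
        mi = sorted(truth.edges)[0][0]
        plate = generate_qpcr_plate(truth, cfg, [mi], failing_assays=[mi])
        res = analyze_plate(plate)
        assert res.qc[mi].excluded

    def test_reference_gene_null_p_uniform(self):
        # paired test on the reference dCT alone (ct == ref draw of another
        # stream) carries no group signal
        ps = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_qpcr_pairs=12, de_effect=0.0,
                            n_true_edges=0, coupling=0.0, **{k: v for k, v in SMALL.items() if k != "n_true_edges"})
            _, _, truth = generate_cohort(cfg)
            plate = generate_qpcr_plate(truth, cfg, ["gene-00000"])
            res = analyze_plate(plate)
            ps.append(paired_group_test(res.measurements)[1])
        assert 0.1 < np.median(ps) < 0.95

    def test_planted_edge_recovered_on_plate(self):
        sig = 0
        n_seeds = 6
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, n_qpcr_pairs=20, **SMALL)
            _, _, truth = generate_cohort(cfg)
            mi, mr = sorted(truth.edges)[0]
            plate_mi = generate_qpcr_plate(truth, cfg, [mi])
            plate_mr = generate_qpcr_plate(truth, cfg, [mr])
            from mirpair.qpcr import validate_pairs

            out = validate_pairs(analyze_plate(plate_mi), analyze_plate(plate_mr), [(mi, mr)])
            if bool(out.iloc[0]["significant"]):
                sig += 1
        assert sig > n_seeds / 2

    def test_unknown_assay_errors(self):
        cfg = SimConfig(seed=6, **SMALL)
        _, _, truth = generate_cohort(cfg)
        with pytest.raises(ValueError, match="not a simulated feature"):
            generate_qpcr_plate(truth, cfg, ["no-such-assay"])


class TestGeneSets:
    def test_planted_term_contains_targets(self):
        cfg = SimConfig(seed=2, **SMALL)
        _, _, truth = generate_cohort(cfg)
        sets = generate_gene_sets(truth, cfg, n_sets=5, set_size=10)
        planted = dict((t, g) for t, _, g in sets)["set-0000"]
        targets = set(truth.regulator_of)
        assert len(set(planted) & targets) >= min(len(targets), 10) - 1

    def test_deterministic(self):
        cfg = SimConfig(seed=2, **SMALL)
        _, _, truth = generate_cohort(cfg)
        assert generate_gene_sets(truth, cfg) == generate_gene_sets(truth, cfg)
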