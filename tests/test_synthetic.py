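"""The synthetic study-set generator and its on-disk fixture writer."""

import warnings

import numpy as np
import pytest
from scipy import stats

import succpred as sp
from succpred.synthetic import SyntheticConfig, SyntheticError, generate, write_fixture_set


class TestGenerate:
    def test_same_seed_identical_outputs(self):
        cfg = dict(n_proteins=4, length_range=(100, 150), n_pos=6, n_neg=6, seed=5)
        a = generate(SyntheticConfig(**cfg))
        b = generate(SyntheticConfig(**cfg))
        for ra, rb in zip(a.records, b.records):
            assert ra.sequence == rb.sequence and ra.sites == rb.sites
        for pid in a.pssms:
            np.testing.assert_array_equal(a.pssms[pid].values, b.pssms[pid].values)
            np.testing.assert_array_equal(a.profiles[pid].asa, b.profiles[pid].asa)
            np.testing.assert_array_equal(a.profiles[pid].angles, b.profiles[pid].angles)

    def test_probability_rows_normalized(self):
        data = generate(SyntheticConfig(n_proteins=3, length_range=(100, 120),
                                        n_pos=4, n_neg=4, seed=0))
        for pid, pssm in data.pssms.items():
            np.testing.assert_allclose(pssm.values.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(
                data.profiles[pid].ss_probs.sum(axis=1), 1.0, atol=1e-9
            )

    def test_lysine_planted_at_every_site(self):
        data = generate(SyntheticConfig(n_proteins=4, length_range=(150, 200),
                                        n_pos=8, n_neg=8, seed=3))
        for rec in data.records:
            for pos, _ in rec.sites:
                assert rec.sequence[pos - 1] == "K"

    def test_sites_window_disjoint(self):
        cfg = SyntheticConfig(n_proteins=4, length_range=(200, 300),
                              n_pos=8, n_neg=8, seed=3)
        data = generate(cfg)
        for rec in data.records:
            positions = sorted(p for p, _ in rec.sites)
            gaps = np.diff(positions)
            assert np.all(gaps >= 2 * cfg.flank + 1)

    def test_full_effect_one_hot_motif_reproduced_exactly(self):
        motif = np.zeros(20)
        motif[7] = 1.0
        cfg = SyntheticConfig(n_proteins=4, length_range=(200, 300),
                              n_pos=6, n_neg=6, effect_size=1.0,
                              motif=motif, seed=9)
        data = generate(cfg)
        for rec in data.records:
            pssm = data.pssms[rec.id].values
            for pos, label in rec.sites:
                if label != 1:
                    continue
                lo = max(0, pos - 1 - cfg.flank)
                hi = min(len(rec), pos + cfg.flank)
                block = pssm[lo:hi]
                np.testing.assert_allclose(
                    block, np.broadcast_to(motif, block.shape), atol=1e-12
                )

    def test_zero_effect_classes_indistinguishable(self):
        cfg = SyntheticConfig(n_proteins=20, length_range=(250, 400),
                              n_pos=60, n_neg=60, effect_size=0.0, seed=21)
        data = generate(cfg)
        ds = sp.build_dataset(data.records, data.pssms, data.profiles)
        pos, neg = ds.X[ds.y == 1], ds.X[ds.y == -1]
        pvals = [
            stats.ttest_ind(pos[:, j], neg[:, j]).pvalue for j in range(100)
        ]
        assert np.mean(np.asarray(pvals) > 0.01) >= 0.95

    def test_infeasible_placement_rejected(self):
        with pytest.raises(SyntheticError, match="place"):
            generate(SyntheticConfig(n_proteins=2, length_range=(40, 45),
                                     n_pos=50, n_neg=50, seed=0))

    def test_config_validation(self):
        with pytest.raises(SyntheticError):
            SyntheticConfig(effect_size=1.5)
        with pytest.raises(SyntheticError):
            SyntheticConfig(motif=np.ones(20))  # does not sum to 1
        with pytest.raises(SyntheticError):
            SyntheticConfig(length_range=(10, 5))


class TestWriteFixtureSet:
    def test_files_parse_without_warnings(self, fixture_tree, small_synthetic):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            records = sp.read_fasta(fixture_tree["fasta"])
            sites = sp.read_sites(fixture_tree["sites"])
            records = sp.attach_sites(records, sites)
        assert len(records) == len(small_synthetic.records)
        n_sites = sum(len(r.sites) for r in records)
        assert n_sites == 50

    def test_round_trip_within_quantization(self, fixture_tree, small_synthetic):
        for rec in small_synthetic.records:
            pssm = sp.read_pssm(f"{fixture_tree['pssm_dir']}/{rec.id}.pssm")
            np.testing.assert_allclose(
                pssm.values, small_synthetic.pssms[rec.id].values, atol=0.005 + 1e-9
            )
            prof = sp.read_structural_profile(
                f"{fixture_tree['spd3_dir']}/{rec.id}.spd3"
            )
            np.testing.assert_allclose(
                prof.asa, small_synthetic.profiles[rec.id].asa, atol=1e-4
            )

    def test_terminal_site_fixture_exercises_padding_end_to_end(self, tmp_path):
        # force a protein whose first residue is an annotated lysine, write
        # it to disk, and run the io -> window -> feature path on it
        rng = np.random.default_rng(0)
        L = 50
        rec = sp.ProteinRecord(id="edge", sequence="K" + "A" * (L - 1),
                               sites=[(1, 1)])
        pssm = sp.PSSMatrix(protein_id="edge",
                            values=np.round(rng.dirichlet(np.ones(20), L), 2))
        prof = sp.StructuralProfile(
            protein_id="edge",
            asa=rng.random(L) * 40,
            ss_probs=rng.dirichlet(np.ones(3), L),
            angles=rng.uniform(-180, 180, (L, 4)),
        )
        data = sp.SyntheticData(records=[rec], pssms={"edge": pssm},
                                profiles={"edge": prof}, sites={"edge": [(1, 1)]})
        paths = write_fixture_set(data, tmp_path)
        records = sp.attach_sites(sp.read_fasta(paths["fasta"]),
                                  sp.read_sites(paths["sites"]))
        ds = sp.build_dataset(
            records,
            {"edge": sp.read_pssm(tmp_path / "edge.pssm")},
            {"edge": sp.read_structural_profile(tmp_path / "edge.spd3")},
        )
        assert ds.X.shape == (1, 657)
        assert np.all(np.isfinite(ds.X))


class TestSignalRecoveryScaledDown:
    """Small-scale signal recovery; the full study runs in the acceptance suite."""

    def test_balancing_on_imbalanced_overlapping_classes(self):
        cfg = SyntheticConfig(n_proteins=20, length_range=(250, 400),
                              n_pos=15, n_neg=150, effect_size=0.0, seed=13)
        data = generate(cfg)
        ds = sp.build_dataset(data.records, data.pssms, data.profiles)
        balanced, report = sp.balance(ds)
        assert report.converged
        assert report.k_final >= 10
        assert balanced.n_negative <= 1.10 * balanced.n_positive
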