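"""Unit and property tests for the conformer-ensemble analysis module."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from screensuite import ensemble as ens
from screensuite import fixtures as fx


def _toy_ensemble(coords_list, ref=0):
    coords = np.asarray(coords_list, dtype=float)
    n_atoms = coords.shape[1]
    labels = tuple(("A", str(i // 4 + 1), ("N", "CA", "C", "O")[i % 4]) for i in range(n_atoms))
    return ens.ConformerEnsemble(
        model_ids=tuple(range(1, coords.shape[0] + 1)),
        coords=coords,
        atom_labels=labels,
        reference_index=ref,
    )


def _random_model(rng, n_atoms=10, scale=5.0):
    return rng.normal(0, scale, size=(n_atoms, 3))


# ---------------------------------------------------------------- reading


class TestReadMultimodelPDB:
    def test_reads_identical_models(self, tmp_path):
        text, _ = fx.make_two_state_ensemble(
            fx.EnsembleSpec(n_models=3, n_residues=5, noise_sigma=0.0,
                            cluster_occupancies=(1.0,), seed=1)
        )
        p = tmp_path / "tri.pdb"
        p.write_text(text)
        e = ens.read_multimodel_pdb(p)
        assert e.n_models == 3
        assert e.n_atoms == 20  # 5 residues x 4 backbone atoms
        assert np.allclose(e.coords[0], e.coords[1], atol=1e-3)
        assert np.allclose(e.coords[0], e.coords[2], atol=1e-3)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            ens.read_multimodel_pdb("no_such_file.pdb")

    def test_single_model_rejected(self, tmp_path):
        text, _ = fx.make_two_state_ensemble(
            fx.EnsembleSpec(n_models=2, n_residues=4, cluster_occupancies=(1.0,), seed=1)
        )
        # keep only the first MODEL block
        head = text.split("ENDMDL")[0] + "ENDMDL\nEND\n"
        p = tmp_path / "single.pdb"
        p.write_text(head)
        with pytest.raises(ValueError, match="2 MODEL"):
            ens.read_multimodel_pdb(p)

    def test_inconsistent_atom_lists_error(self, tmp_path):
        text, _ = fx.make_two_state_ensemble(
            fx.EnsembleSpec(n_models=3, n_residues=5, cluster_occupancies=(1.0,), seed=1)
        )
        # drop one residue (4 atoms) from model 2
        out_lines, in_model2, dropped = [], False, 0
        for ln in text.splitlines():
            if ln.startswith("MODEL"):
                in_model2 = "2" == ln.split()[1]
            if in_model2 and ln.startswith("ATOM") and dropped < 4:
                dropped += 1
                continue
            out_lines.append(ln)
        p = tmp_path / "bad.pdb"
        p.write_text("\n".join(out_lines) + "\n")
        with pytest.raises(ValueError, match="inconsistent atom lists"):
            ens.read_multimodel_pdb(p)

    def test_absent_chain(self, tmp_path):
        text, _ = fx.make_two_state_ensemble(
            fx.EnsembleSpec(n_models=2, n_residues=4, cluster_occupancies=(1.0,), seed=1)
        )
        p = tmp_path / "x.pdb"
        p.write_text(text)
        with pytest.raises(ValueError, match="chain"):
            ens.read_multimodel_pdb(p, chain="B")


# ------------------------------------------------------------ superposition


class TestSuperposition:
    def test_translation_removed(self, rng):
        a = _random_model(rng)
        e = ens.superpose_kabsch(_toy_ensemble([a, a + np.array([5.0, 5.0, 5.0])]))
        assert ens.rmsd_between(e.coords[0], e.coords[1]) < 1e-6

    def test_rotation_removed(self, rng):
        a = _random_model(rng)
        rot = Rotation.from_euler("z", 90, degrees=True)
        e = ens.superpose_kabsch(_toy_ensemble([a, rot.apply(a)]))
        assert ens.rmsd_between(e.coords[0], e.coords[1]) < 1e-6

    def test_reference_unchanged(self, rng):
        a, b = _random_model(rng), _random_model(rng)
        e = ens.superpose_kabsch(_toy_ensemble([a, b]))
        assert np.array_equal(e.coords[0], a)

    def test_optimality_against_random_rotation_oracle(self, rng):
        """The fitted RMSD is no worse than 2000 random rigid alternatives
        (direct evaluation of the rotation objective)."""
        a, b = _random_model(rng), _random_model(rng)
        e = ens.superpose_kabsch(_toy_ensemble([a, b]))
        fitted = ens.rmsd_between(e.coords[0], e.coords[1])
        assert fitted <= ens.rmsd_between(a, b) + 1e-9
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        for trial_rot in Rotation.random(2000, random_state=0):
            trial = ens.rmsd_between(ac, trial_rot.apply(bc))
            assert fitted <= trial + 1e-9

    def test_collinear_geometry_rejected(self):
        line = np.stack([np.linspace(0, 9, 10)] * 3, axis=1)  # x=y=z line
        with pytest.raises(ValueError, match="collinear"):
            ens.superpose_kabsch(_toy_ensemble([line, line + 1.0]))


# ---------------------------------------------------------------- RMSD math


class TestRMSDMatrix:
    def test_hand_computed_two_atom_value(self):
        a = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        b = np.array([[3.0, 0, 0], [10.0, 4.0, 0]])  # displacements 3 and 4
        e = _toy_ensemble([a, b])
        m = ens.pairwise_rmsd_matrix(e)
        assert m.values[0, 1] == pytest.approx(np.sqrt((9 + 16) / 2))

    def test_identical_models_zero_matrix(self, rng):
        a = _random_model(rng)
        m = ens.pairwise_rmsd_matrix(_toy_ensemble([a, a, a]))
        assert np.allclose(m.values, 0)

    def test_summary_arithmetic(self):
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        s = ens.ensemble_rmsd_summary(ens.RMSDMatrix(vals, (1, 2, 3)))
        assert s.mean == pytest.approx(2.0)
        assert s.min == 1.0 and s.max == 3.0
        assert s.per_model_mean == pytest.approx([1.5, 2.0, 2.5])

    def test_statistics_invariant_under_global_rigid_transform(self, rng):
        models = [_random_model(rng) for _ in range(5)]
        e1 = ens.superpose_kabsch(_toy_ensemble(models))
        rot = Rotation.from_euler("xyz", [11, 23, 37], degrees=True)
        moved = [rot.apply(m) + np.array([1.0, -2.0, 3.0]) for m in models]
        e2 = ens.superpose_kabsch(_toy_ensemble(moved))
        m1 = ens.pairwise_rmsd_matrix(e1).values
        m2 = ens.pairwise_rmsd_matrix(e2).values
        assert np.allclose(m1, m2, atol=1e-8)


# -------------------------------------------------------------- flexibility


class TestFlexibility:
    def test_rg_two_atoms(self):
        assert ens.radius_of_gyration(np.array([[0.0, 0, 0], [4.0, 0, 0]])) == pytest.approx(2.0)

    def test_rg_single_atom(self):
        assert ens.radius_of_gyration(np.array([[1.0, 2, 3]])) == 0.0

    def test_rg_matches_two_pass_oracle(self, rng):
        coords = _random_model(rng)
        centroid = coords.mean(axis=0)
        expected = np.sqrt(sum(np.sum((c - centroid) ** 2) for c in coords) / len(coords))
        assert ens.radius_of_gyration(coords) == pytest.approx(expected)

    def test_rmsf_identical_models_zero(self, rng):
        a = _random_model(rng)
        prof = ens.per_residue_rmsf(_toy_ensemble([a, a, a]))
        assert np.allclose(prof.rmsf_per_atom, 0)

    def test_oscillating_atom_rmsf_one(self, rng):
        a = _random_model(rng, n_atoms=8)
        b = a.copy()
        a2 = a.copy()
        b[0, 0] += 1.0
        a2[0, 0] -= 1.0
        prof = ens.per_residue_rmsf(_toy_ensemble([a2, b]))
        assert prof.rmsf_per_atom[0] == pytest.approx(1.0)
        assert np.allclose(prof.rmsf_per_atom[1:], 0)

    def test_isotropic_noise_closed_form(self):
        """sigma = 0.5 A isotropic noise gives atom RMSF ~ sqrt(3)*0.5."""
        rng = np.random.default_rng(5)
        base = rng.normal(0, 5, size=(20, 3))
        models = [base + rng.normal(0, 0.5, size=base.shape) for _ in range(400)]
        prof = ens.per_residue_rmsf(_toy_ensemble(models))
        assert prof.rmsf_per_residue.mean() == pytest.approx(np.sqrt(3) * 0.5, rel=0.05)

    def test_high_flex_set_matches_percentile(self, rng):
        models = [_random_model(rng, n_atoms=40) for _ in range(6)]
        prof = ens.per_residue_rmsf(_toy_ensemble(models))
        thr = np.percentile(prof.rmsf_per_residue, 75)
        expected = {k for k, v in zip(prof.residue_keys, prof.rmsf_per_residue) if v > thr}
        assert set(prof.high_flex_residues) == expected


# ----------------------------------------------------------------- outliers


class TestOutliers:
    def test_iqr_flags_extreme_value(self):
        flags = ens.outliers_iqr(np.array([1.0, 1, 1, 1, 10]))
        assert flags.tolist() == [False, False, False, False, True]

    def test_iqr_constant_vector(self):
        assert not ens.outliers_iqr(np.full(6, 2.0)).any()

    def test_isolation_forest_flags_displaced_model(self, rng):
        base = _random_model(rng, n_atoms=20, scale=2.0)
        models = [base + rng.normal(0, 0.3, base.shape) for _ in range(14)]
        models.append(base + 50.0)
        flat = np.array([m.ravel() for m in models])
        flags = ens.outliers_isolation_forest(flat, contamination=0.1, seed=0)
        assert flags[-1]

    def test_isolation_forest_deterministic(self, rng):
        flat = rng.normal(size=(12, 30))
        f1 = ens.outliers_isolation_forest(flat, seed=3)
        f2 = ens.outliers_isolation_forest(flat, seed=3)
        assert np.array_equal(f1, f2)

    def test_hier_singleton_flags_straggler(self, rng):
        base = _random_model(rng, n_atoms=16, scale=2.0)
        models = [base + rng.normal(0, 0.2, base.shape) for _ in range(9)]
        models.append(base + rng.normal(0, 15.0, base.shape))  # strong deformation
        e = ens.superpose_kabsch(_toy_ensemble(models))
        flags = ens.outliers_hier_singleton(ens.pairwise_rmsd_matrix(e))
        assert flags[-1]
        assert flags.sum() == 1

    def test_hier_singleton_two_clean_clusters(self, rng):
        base = _random_model(rng, n_atoms=16, scale=2.0)
        shifted = base + np.array([8.0, 0, 0])
        models = [base + rng.normal(0, 0.2, base.shape) for _ in range(5)]
        models += [shifted + rng.normal(0, 0.2, base.shape) for _ in range(5)]
        m = ens.pairwise_rmsd_matrix(_toy_ensemble(models))
        assert not ens.outliers_hier_singleton(m).any()

    def test_consensus_vote_arithmetic(self):
        t, f = True, False
        rep = ens.consensus_outliers(
            np.array([t, t, f]), np.array([t, f, f]), np.array([f, f, f])
        )
        assert rep.consensus.tolist() == [True, False, False]

    def test_consensus_monotone_in_votes(self, rng):
        """Adding a vote never un-flags a model."""
        for _ in range(25):
            a, b, c = (rng.random(8) < 0.3 for _ in range(3))
            before = ens.consensus_outliers(a, b, c).consensus
            extra = c | (rng.random(8) < 0.3)
            after = ens.consensus_outliers(a, b, extra).consensus
            assert np.all(after | ~before)


# --------------------------------------------------------------- clustering


class TestClustering:
    def test_choose_k_two_blobs(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (8, 12)), rng.normal(6, 0.3, (7, 12))])
        k, table = ens.choose_k(x, seed=0)
        assert k == 2
        assert table.loc[2, "silhouette"] > 0.8

    def test_choose_k_three_blobs(self, rng):
        x = np.vstack(
            [
                rng.normal(0, 0.3, (6, 12)),
                rng.normal(6, 0.3, (6, 12)),
                rng.normal(-7, 0.3, (6, 12)),
            ]
        )
        k, _ = ens.choose_k(x, seed=0)
        assert k == 3

    def test_kmeans_recovers_planted_partition(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (8, 12)), rng.normal(6, 0.3, (7, 12))])
        labels, excluded, _ = ens.cluster_kmeans(x, k=2, seed=0)
        # cluster 0 must be the larger planted blob (renumbered by occupancy)
        assert labels[:8].tolist() == [0] * 8
        assert labels[8:].tolist() == [1] * 7
        assert not excluded.any()

    def test_k1_single_cluster(self, rng):
        x = rng.normal(size=(6, 9))
        labels, _, _ = ens.cluster_kmeans(x, k=1, seed=0)
        assert set(labels) == {0}

    def test_outliers_assigned_but_excluded(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (8, 12)), rng.normal(6, 0.3, (4, 12)),
                       np.full((1, 12), 80.0)])
        mask = np.zeros(13, bool)
        mask[-1] = True
        labels, excluded, _ = ens.cluster_kmeans(x, k=2, outlier_mask=mask, seed=0)
        assert excluded[-1]
        assert labels[-1] in (0, 1)
        assert (np.bincount(labels).sum()) == 13  # occupancies cover all models


# ---------------------------------------------------------- representatives


class TestRepresentatives:
    def _line_matrix(self, xs):
        xs = np.asarray(xs, dtype=float)
        vals = np.abs(xs[:, None] - xs[None, :])
        return ens.RMSDMatrix(vals, tuple(range(1, len(xs) + 1)))

    def test_central_member_wins_all_methods(self):
        m = self._line_matrix([0.0, 1.0, 2.0])
        flat = np.array([[0.0], [1.0], [2.0]])
        rep, votes = ens.select_representative([0, 1, 2], m, flat)
        assert rep == 1
        assert all(v == 1 for v in votes.values())

    def test_singleton_cluster(self):
        m = self._line_matrix([0.0, 5.0])
        rep, votes = ens.select_representative([1], m, np.array([[0.0], [5.0]]))
        assert rep == 1
        assert all(v == 1 for v in votes.values())

    def test_quality_singleton_is_one(self):
        m = self._line_matrix([0.0, 5.0])
        score, comps = ens.representative_quality(0, [0], m)
        assert score == 1.0

    def test_quality_bounded_and_decreasing_in_avg_rmsd(self):
        """Inflating the representative's average RMSD (holding the others
        fixed) lowers the composite score."""
        base = self._line_matrix([0.0, 1.0, 2.0, 3.0])
        s1, _ = ens.representative_quality(1, [0, 1, 2, 3], base)
        worse_vals = base.values.copy()
        worse_vals[1, :] += 4.0
        worse_vals[:, 1] += 4.0
        np.fill_diagonal(worse_vals, 0.0)
        worse = ens.RMSDMatrix(np.maximum(worse_vals, worse_vals.T), (1, 2, 3, 4))
        s2, _ = ens.representative_quality(1, [0, 1, 2, 3], worse)
        assert 0.0 <= s2 <= s1 <= 1.0

    def test_quality_rejects_foreign_representative(self):
        m = self._line_matrix([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            ens.representative_quality(2, [0, 1], m)

    def test_diversity_two_members(self):
        m = self._line_matrix([0.0, 3.0])
        d = ens.cluster_diversity([0, 1], m, global_mean_rmsd=3.0)
        assert d["mean_intra_rmsd"] == 3.0
        assert d["diameter"] == 3.0
        assert d["compactness"] == pytest.approx(1.0)

    def test_diversity_singleton_convention(self):
        m = self._line_matrix([0.0, 3.0])
        d = ens.cluster_diversity([0], m)
        assert (d["mean_intra_rmsd"], d["diameter"], d["compactness"]) == (0.0, 0.0, 1.0)


# ---------------------------------------------------------------------- PCA


class TestPCA:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=12)
        x = np.outer(np.arange(5, dtype=float), direction)
        coords, evr = ens.pca_project(x)
        assert evr[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one_and_non_increasing(self, rng):
        x = rng.normal(size=(10, 18))
        _, evr = ens.pca_project(x)
        assert evr.sum() == pytest.approx(1.0)
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.all((0 <= evr) & (evr <= 1))


# ------------------------------------------------------------- orchestration


class TestAnalyzeEnsemble:
    def test_full_pipeline_recovers_planted_structure(self, two_state_pdb, tmp_path):
        path, truth = two_state_pdb
        cfg = ens.EnsembleConfig(seed=7, make_plots=False)
        rep = ens.analyze_ensemble(path, cfg, outdir=tmp_path / "out")
        assert rep.clusters.k == 2
        planted = np.array(truth["labels"])
        regular = planted >= 0
        assert np.array_equal(rep.clusters.labels[regular], planted[regular])
        assert (tmp_path / "out" / "ensemble_report.json").exists()
        assert (tmp_path / "out" / "rmsd_matrix.csv").exists()

    def test_bit_reproducible_for_fixed_seed(self, two_state_pdb):
        path, _ = two_state_pdb
        cfg = ens.EnsembleConfig(seed=11, make_plots=False)
        r1 = ens.analyze_ensemble(path, cfg)
        r2 = ens.analyze_ensemble(path, cfg)
        assert np.array_equal(r1.clusters.labels, r2.clusters.labels)
        assert np.array_equal(r1.rmsd_matrix.values, r2.rmsd_matrix.values)
        assert r1.clusters.quality_scores == r2.clusters.quality_scores

    def test_empty_file_fails_at_read_stage(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(Exception, match="read stage"):
            ens.analyze_ensemble(p, ens.EnsembleConfig(make_plots=False))

    def test_plot_panels_written(self, two_state_pdb, tmp_path):
        path, _ = two_state_pdb
        cfg = ens.EnsembleConfig(seed=7, make_plots=True)
        ens.analyze_ensemble(path, cfg, outdir=tmp_path / "out")
        plots = sorted((tmp_path / "out" / "plots").glob("*.png"))
        assert len(plots) == 9
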