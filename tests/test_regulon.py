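import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from lrcausal.datatypes import ExpressionMatrix, GeneSet
from lrcausal.regulon import (
    Regulon,
    build_regulons,
    call_temporal_tfs,
    cluster_ttfs,
    read_regulons,
    write_regulons,
)


def _noise_matrix(seed, n_genes=100, n_cells=100):
    rng = np.random.default_rng(seed)
    vals = np.abs(rng.normal(1, 0.5, (n_genes, n_cells)))
    return ExpressionMatrix(vals, [f"g{i}" for i in range(n_genes)], [f"c{j}" for j in range(n_cells)])


class TestBuildRegulons:
    def test_exact_copy_targets_recovered(self):
        rng = np.random.default_rng(0)
        tf = rng.normal(1, 1, 200)
        rows = [tf] + [tf.copy() for _ in range(5)] + [rng.normal(1, 1, 200) for _ in range(50)]
        genes = ["TF"] + [f"copy{i}" for i in range(5)] + [f"noise{i}" for i in range(50)]
        mat = ExpressionMatrix(np.abs(np.vstack(rows)), genes, [f"c{j}" for j in range(200)])
        (reg,) = build_regulons(mat, ["TF"], rng=0)
        assert {f"copy{i}" for i in range(5)} <= reg.targets
        assert "TF" not in reg.targets

    def test_null_regulons_are_small(self):
        """Permutation calibration: independent noise yields ~alpha-level regulons."""
        sizes = []
        for seed in range(5):
            mat = _noise_matrix(seed)
            regs = build_regulons(mat, ["g0", "g1", "g2"], n_perm=100, alpha_net=0.01, rng=seed)
            sizes += [len(r.targets) for r in regs]
        assert np.mean(sizes) <= 0.02 * 100

    def test_planted_network_recovery(self):
        rng = np.random.default_rng(0)
        n = 300
        tf_sigs = [rng.normal(0, 1, n) for _ in range(3)]
        rows, genes = [], []
        truth = {}
        for i, sig in enumerate(tf_sigs):
            rows.append(sig)
            genes.append(f"TF{i}")
            truth[f"TF{i}"] = set()
            for j in range(20):
                # 5 of 20 targets shared with the next TF (overlap)
                drv = sig if j >= 5 else sig + tf_sigs[(i + 1) % 3]
                rows.append(0.9 * drv + rng.normal(0, 0.5, n))
                genes.append(f"T{i}_{j}")
                truth[f"TF{i}"].add(f"T{i}_{j}")
        for j in range(40):
            rows.append(rng.normal(0, 1, n))
            genes.append(f"noise{j}")
        mat = ExpressionMatrix(np.vstack(rows) - np.vstack(rows).min(), genes, [f"c{j}" for j in range(n)])
        regs = {r.tf: r for r in build_regulons(mat, ["TF0", "TF1", "TF2"], rng=0)}
        for tf, targets in truth.items():
            recovered = len(regs[tf].targets & targets) / len(targets)
            assert recovered >= 0.8

    def test_absent_tf_skipped(self):
        mat = _noise_matrix(0)
        regs = build_regulons(mat, ["g0", "NOT_THERE"], rng=0)
        assert [r.tf for r in regs] == ["g0"]

    def test_round_trip_tsv(self, tmp_path):
        mat = _noise_matrix(1)
        regs = build_regulons(mat, ["g0", "g1"], rng=1)
        write_regulons(regs, tmp_path / "regs.tsv")
        back = read_regulons(tmp_path / "regs.tsv")
        # empty regulons have no rows to write; compare the informative ones
        assert {r.tf: r.targets for r in back} == {
            r.tf: r.targets for r in regs if r.targets
        }


class TestCallTemporalTFs:
    def _closed_form_upper(self, M, K, N, k):
        from math import comb

        return sum(comb(K, i) * comb(M - K, N - i) for i in range(k, min(K, N) + 1)) / comb(M, N)

    def test_pvalue_matches_closed_form(self):
        universe = GeneSet("u", [f"g{i}" for i in range(1000)])
        variable = GeneSet("v", [f"g{i}" for i in range(50)])
        reg = Regulon(tf="TF", targets={f"g{i}" for i in range(20)})  # fully inside variable
        called = call_temporal_tfs([reg], variable, universe, alpha_mra=0.01)
        assert called == ["TF"]
        p = self._closed_form_upper(1000, 50, 20, 20)
        assert p < 1e-20
        # and the generic overlap case agrees with scipy's tail to 1e-10
        p_scipy = scipy.stats.hypergeom.sf(6 - 1, 100, 20, 10)
        assert p_scipy == pytest.approx(self._closed_form_upper(100, 20, 10, 6), abs=1e-10)

    def test_disjoint_regulon_not_called(self):
        universe = GeneSet("u", [f"g{i}" for i in range(100)])
        variable = GeneSet("v", [f"g{i}" for i in range(30)])
        reg = Regulon(tf="TF", targets={f"g{i}" for i in range(50, 70)})
        assert call_temporal_tfs([reg], variable, universe) == []

    def test_temporal_vs_constant_tf_programs(self):
        rng = np.random.default_rng(0)
        n = 200
        t = np.linspace(0, 1, n)
        rows, genes = [], []
        temporal_tfs, constant_tfs = [], []
        for i in range(10):
            sig = np.exp(-((t - (i + 1) / 11) ** 2) / 0.02)
            rows.append(sig + rng.normal(0, 0.1, n)); genes.append(f"tTF{i}")
            temporal_tfs.append(f"tTF{i}")
            for j in range(6):
                rows.append(0.9 * sig + rng.normal(0, 0.2, n)); genes.append(f"tT{i}_{j}")
        for i in range(10):
            base = rng.normal(0, 1, n)
            rows.append(base + rng.normal(0, 0.1, n)); genes.append(f"cTF{i}")
            constant_tfs.append(f"cTF{i}")
            for j in range(6):
                rows.append(0.9 * base + rng.normal(0, 0.2, n)); genes.append(f"cT{i}_{j}")
        for j in range(60):
            rows.append(rng.normal(0, 1, n)); genes.append(f"noise{j}")
        vals = np.vstack(rows)
        mat = ExpressionMatrix(vals - vals.min(), genes, [f"c{j}" for j in range(n)])
        from lrcausal.regulon import variable_genes

        regs = build_regulons(mat, temporal_tfs + constant_tfs, rng=0)
        var = variable_genes(mat, mat.cell_ids, n_top=80)
        called = call_temporal_tfs(regs, var, GeneSet("u", mat.gene_ids))
        assert sum(tf in called for tf in temporal_tfs) >= 8
        assert sum(tf in called for tf in constant_tfs) <= 1

    def test_empty_variable_set_raises(self):
        universe = GeneSet("u", ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            call_temporal_tfs([Regulon("TF", {"a"})], GeneSet("v", ["zz"]), universe)


def _archetype_matrix(seed=0, noise_sd=0.1):
    """12 TFs from 3 disjoint temporal archetypes (early/mid/late)."""
    rng = np.random.default_rng(seed)
    n = 150
    t = np.linspace(0, 1, n)
    centers = {0: 0.15, 1: 0.5, 2: 0.85}
    rows, genes, truth = [], [], []
    for i in range(12):
        k = i % 3
        rows.append(np.exp(-((t - centers[k]) ** 2) / 0.01) + rng.normal(0, noise_sd, n))
        genes.append(f"TF{i}")
        truth.append(k)
    vals = np.vstack(rows)
    return ExpressionMatrix(vals - vals.min(), genes, [f"c{j}" for j in range(n)]), genes, truth


class TestClusterTTFs:
    def test_three_archetypes_perfectly_recovered(self):
        mat, genes, truth = _archetype_matrix()
        out = cluster_ttfs(mat, genes, mat.cell_ids, k=3)
        labels = [out.assignments[g] for g in genes]
        assert adjusted_rand_score(truth, labels) == 1.0
        # cluster 1 peaks earliest (renumbered by activity peak)
        peaks = {c: int(np.argmax(out.activity[c].values)) for c in out.activity}
        assert peaks[1] < peaks[2] < peaks[3]

    def test_k1_gives_grand_mean_activity(self):
        mat, genes, _ = _archetype_matrix()
        out = cluster_ttfs(mat, genes, mat.cell_ids, k=1)
        assert set(out.assignments.values()) == {1}
        prof = np.vstack([mat.gene(g) for g in genes])
        z = (prof - prof.mean(1, keepdims=True)) / prof.std(1, keepdims=True)
        np.testing.assert_allclose(out.activity[1].values, z.mean(0))

    def test_duplicated_profile_shares_cluster(self):
        mat, genes, _ = _archetype_matrix()
        vals = np.vstack([mat.values, mat.gene("TF0")])
        mat2 = ExpressionMatrix(vals, genes + ["TF0_dup"], mat.cell_ids)
        out = cluster_ttfs(mat2, genes + ["TF0_dup"], mat2.cell_ids, k=3)
        assert out.assignments["TF0"] == out.assignments["TF0_dup"]

    def test_single_member_cluster_activity_is_member_profile(self):
        mat, genes, _ = _archetype_matrix()
        out = cluster_ttfs(mat, ["TF0", "TF1", "TF2"], mat.cell_ids, k=3)
        for tf in ("TF0", "TF1", "TF2"):
            cid = out.assignments[tf]
            prof = mat.gene(tf)
            z = (prof - prof.mean()) / prof.std()
            np.testing.assert_allclose(out.activity[cid].values, z)

    def test_labels_invariant_to_tf_input_order(self):
        mat, genes, _ = _archetype_matrix()
        a = cluster_ttfs(mat, genes, mat.cell_ids, k=3)
        b = cluster_ttfs(mat, genes[::-1], mat.cell_ids, k=3)
        assert a.assignments == b.assignments

    def test_k_exceeding_ttfs_raises(self):
        mat, genes, _ = _archetype_matrix()
        with pytest.raises(ValueError, match="exceeds"):
            cluster_ttfs(mat, genes[:4], mat.cell_ids, k=6)
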