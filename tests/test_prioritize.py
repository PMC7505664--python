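import numpy as np
import pandas as pd
import pytest

import cellspec as cs
from cellspec.prioritize import results_to_frame


def _esmu_from_array(arr, cell_types=None):
    arr = np.asarray(arr, dtype=float)
    cell_types = cell_types or [f"ct{j}" for j in range(arr.shape[1])]
    genes = [f"g{i:04d}" for i in range(arr.shape[0])]
    return cs.ESMu(pd.DataFrame(arr, index=genes, columns=cell_types))


def _random_esmu(n_genes=300, n_types=4, seed=0):
    rng = np.random.default_rng(seed)
    arr = rng.uniform(0, 1, size=(n_genes, n_types))
    arr[rng.uniform(size=arr.shape) < 0.7] = 0.0  # sparse, like real scores
    return _esmu_from_array(arr)


def _stats_from_z(esmu, z):
    return cs.GeneLevelStats(pd.DataFrame({"z": z}, index=esmu.values.index))


class TestPrioritizeCellTypes:
    def test_perfect_linear_signal_ranks_first_with_floor_p(self):
        esmu = _random_esmu(seed=1)
        z = 2.0 * esmu.values["ct2"].to_numpy()
        res = cs.prioritize_cell_types(esmu, _stats_from_z(esmu, z))
        assert res[0].cell_type == "ct2"
        assert res[0].p_one_sided <= 1e-200  # solver floor, not exactly 0
        assert res[0].p_one_sided > 0

    def test_constant_column_reported_degenerate(self):
        arr = np.random.default_rng(2).uniform(0, 1, size=(100, 2))
        arr[:, 1] = 0.0
        esmu = _esmu_from_array(arr)
        z = np.random.default_rng(3).normal(size=100)
        res = cs.prioritize_cell_types(esmu, _stats_from_z(esmu, z))
        degen = [r for r in res if r.cell_type == "ct1"][0]
        assert degen.degenerate and degen.p_one_sided == 1.0

    def test_too_few_shared_genes_rejected(self):
        esmu = _esmu_from_array(np.random.default_rng(4).uniform(size=(20, 2)))
        z = np.zeros(20)
        with pytest.raises(ValueError, match="30"):
            cs.prioritize_cell_types(esmu, _stats_from_z(esmu, z))

    def test_results_sorted_by_p_with_bonferroni_flag(self):
        esmu = _random_esmu(seed=5)
        rng = np.random.default_rng(6)
        z = 3.0 * esmu.values["ct0"].to_numpy() + rng.normal(size=300)
        res = cs.prioritize_cell_types(esmu, _stats_from_z(esmu, z), alpha=0.05)
        ps = [r.p_one_sided for r in res]
        assert ps == sorted(ps)
        for r in res:
            assert r.bonferroni_significant == (r.p_one_sided < 0.05 / 4)

    def test_invariant_to_gene_reordering(self):
        esmu = _random_esmu(seed=7)
        rng = np.random.default_rng(8)
        z = esmu.values["ct1"].to_numpy() + rng.normal(size=300)
        res1 = cs.prioritize_cell_types(esmu, _stats_from_z(esmu, z))
        perm = rng.permutation(300)
        esmu2 = cs.ESMu(esmu.values.iloc[perm])
        stats2 = cs.GeneLevelStats(
            pd.DataFrame({"z": z}, index=esmu.values.index).iloc[perm]
        )
        res2 = cs.prioritize_cell_types(esmu2, stats2)
        for r1, r2 in zip(res1, res2):
            assert r1.cell_type == r2.cell_type
            np.testing.assert_allclose(r1.p_one_sided, r2.p_one_sided)

    def test_invariant_to_affine_covariate_rescaling(self):
        esmu = _random_esmu(seed=9)
        stats = cs.simulate_gene_stats(esmu, "ct0", effect=1.0, seed=10, with_covariates=True)
        res1 = cs.prioritize_cell_types(esmu, stats, use_covariates=True)
        table = stats.table.copy()
        for c in stats.covariates:
            table[c] = 3.7 * table[c] + 11.0
        res2 = cs.prioritize_cell_types(esmu, cs.GeneLevelStats(table), use_covariates=True)
        for r1, r2 in zip(res1, res2):
            np.testing.assert_allclose(r1.p_one_sided, r2.p_one_sided, rtol=1e-9)

    def test_covariates_requested_but_absent_rejected(self):
        esmu = _random_esmu(seed=11)
        z = np.zeros(300)
        with pytest.raises(ValueError, match="covariate"):
            cs.prioritize_cell_types(esmu, _stats_from_z(esmu, z), use_covariates=True)


class TestConditionalPrioritization:
    def test_conditioning_on_duplicate_of_itself_is_degenerate(self):
        arr = np.random.default_rng(12).uniform(0, 1, size=(200, 2))
        arr = np.column_stack([arr[:, 0], arr[:, 0], arr[:, 1]])
        esmu = _esmu_from_array(arr, ["A", "Adup", "B"])
        z = np.random.default_rng(13).normal(size=200)
        res = cs.conditional_prioritization(esmu, _stats_from_z(esmu, z), ["A"])
        by_ct = {r.cell_type: r for r in res}
        assert by_ct["A"].degenerate and by_ct["A"].p_one_sided == 1.0
        assert by_ct["Adup"].degenerate and by_ct["Adup"].p_one_sided == 1.0
        assert not by_ct["B"].degenerate

    def test_orthogonal_conditioning_leaves_p_nearly_unchanged(self):
        rng = np.random.default_rng(14)
        n = 2000
        focal = rng.uniform(0, 1, size=n)
        z = 0.15 * focal + rng.normal(size=n)  # moderate signal, p ~ 1e-2
        # conditioning column orthogonalized against [1, focal, z]; the affine
        # rescale to [0, 1] preserves zero sample correlation with the focal column
        other = rng.uniform(0, 1, size=n)
        basis = np.column_stack([np.ones(n), focal, z])
        resid = other - basis @ np.linalg.lstsq(basis, other, rcond=None)[0]
        cond = (resid - resid.min()) / (resid.max() - resid.min())
        esmu = _esmu_from_array(np.column_stack([focal, cond]), ["focal", "cond"])
        stats = _stats_from_z(esmu, z)
        p_marg = {r.cell_type: r.p_one_sided for r in cs.prioritize_cell_types(esmu, stats)}
        p_cond = {
            r.cell_type: r.p_one_sided
            for r in cs.conditional_prioritization(esmu, stats, ["cond"])
        }
        np.testing.assert_allclose(p_cond["focal"], p_marg["focal"], rtol=5e-3)

    def test_correlated_decoy_killed_by_conditioning(self):
        rng = np.random.default_rng(15)
        base = _random_esmu(n_genes=1000, n_types=3, seed=16)
        esmu = cs.make_correlated_column(base, "ct0", rho=0.9, new_label="decoy", seed=17)
        z = 2.0 * esmu.values["ct0"].to_numpy() + rng.normal(size=1000)
        stats = _stats_from_z(esmu, z)
        marg = {r.cell_type: r.p_one_sided for r in cs.prioritize_cell_types(esmu, stats)}
        cond = {
            r.cell_type: r.p_one_sided
            for r in cs.conditional_prioritization(esmu, stats, ["ct0"])
        }
        assert marg["decoy"] < 0.05          # significant marginally
        assert cond["decoy"] > marg["decoy"]  # attenuated by conditioning
        assert cond["decoy"] > 0.05

    def test_unknown_conditioning_label_rejected(self):
        esmu = _random_esmu(seed=18)
        z = np.zeros(300)
        with pytest.raises(KeyError):
            cs.conditional_prioritization(esmu, _stats_from_z(esmu, z), ["nope"])


class TestAnnotations:
    def _toy(self):
        genes = pd.DataFrame(
            {
                "gene_id": ["gA", "gB"],
                "chrom": ["1", "1"],
                "start": [100_000, 150_000],
                "end": [110_000, 160_000],
            }
        )
        variants = pd.DataFrame(
            {
                "variant_id": ["v_in_A", "v_in_both", "v_far", "v_chr2"],
                "chrom": ["1", "1", "1", "2"],
                "pos": [95_000, 120_000, 900_000, 100_000],
            }
        )
        esmu_col = pd.Series({"gA": 0.3, "gB": 0.9})
        return genes, variants, esmu_col

    def test_max_rule_and_zero_outside_window(self):
        # 30 kb windows: gA covers [70k, 140k], gB covers [120k, 190k]
        genes, variants, col = self._toy()
        with pytest.warns(UserWarning, match="chromosomes"):
            ann = cs.build_snp_annotation(col, genes, variants, window_bp=30_000)
        assert ann["v_in_A"] == 0.3          # only gA's window (gB starts at 50kb away)
        assert ann["v_in_both"] == 0.9       # overlap -> max
        assert ann["v_far"] == 0.0
        assert ann["v_chr2"] == 0.0

    def test_window_boundary_is_inclusive(self):
        genes, _, col = self._toy()
        variants = pd.DataFrame(
            {"variant_id": ["edge_lo", "edge_hi", "just_out"],
             "chrom": ["1", "1", "1"],
             "pos": [100_000 - 1000, 110_000 + 1000, 110_000 + 1001]}
        )
        ann = cs.build_snp_annotation(col, genes[:1], variants, window_bp=1000)
        assert ann["edge_lo"] == 0.3 and ann["edge_hi"] == 0.3
        assert ann["just_out"] == 0.0

    def test_all_genes_annotation_contains_cell_type_annotation(self):
        genes, variants, col = self._toy()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ct_ann = cs.build_snp_annotation(col, genes, variants, window_bp=50_000)
            all_ann = cs.all_genes_annotation(genes, variants, window_bp=50_000)
        assert np.all(all_ann.to_numpy() >= (ct_ann.to_numpy() > 0))

    def test_monotone_in_window_size(self):
        genes, variants, col = self._toy()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            smaller = cs.build_snp_annotation(col, genes, variants, window_bp=10_000)
            larger = cs.build_snp_annotation(col, genes, variants, window_bp=200_000)
        assert np.all(larger.to_numpy() >= smaller.to_numpy())

    def test_negative_window_rejected(self):
        genes, variants, col = self._toy()
        with pytest.raises(ValueError):
            cs.build_snp_annotation(col, genes, variants, window_bp=-1)

    def test_annotation_size_is_the_mean(self):
        assert cs.annotation_size(pd.Series([1.0, 1.0, 1.0, 0, 0, 0, 0, 0, 0, 0])) == 0.3
        assert cs.annotation_size(np.zeros(5)) == 0.0
        assert cs.annotation_size(np.ones(5)) == 1.0
        with pytest.raises(ValueError):
            cs.annotation_size(np.array([]))


class TestGeneLevelStats:
    def test_z_column_required_and_finite(self):
        with pytest.raises(ValueError):
            cs.GeneLevelStats(pd.DataFrame({"zz": [1.0]}, index=["g"]))
        with pytest.raises(ValueError):
            cs.GeneLevelStats(pd.DataFrame({"z": [np.inf]}, index=["g"]))

    def test_results_frame_round_trips_fields(self):
        esmu = _random_esmu(seed=19)
        z = np.random.default_rng(20).normal(size=300)
        res = cs.prioritize_cell_types(esmu, _stats_from_z(esmu, z))
        frame = results_to_frame(res)
        assert list(frame["cell_type"]) == [r.cell_type for r in res]
        assert frame["n_genes"].nunique() == 1
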