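"""Program clustering: spearman distances, agglomerative cut, template
labeling, z-scores, percent medians."""

import numpy as np
import pandas as pd
import pytest

from erp import expression, programs, synthetic


def _frame(rows, index=None):
    return pd.DataFrame(
        rows, index=index or [f"g{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(len(rows[0]))],
    )


class TestSpearmanDistance:
    def test_identical_profiles(self):
        d = programs.spearman_distance(_frame([[1, 2, 3, 4], [2, 4, 6, 8]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_antimonotone_profiles(self):
        d = programs.spearman_distance(_frame([[1, 2, 3, 4], [4, 3, 2, 1]]))
        assert d.iloc[0, 1] == pytest.approx(2.0)

    def test_brute_force_rank_oracle(self):
        # rho by hand for [1,2,3,4] vs [1,3,2,4]: d^2 = 0+1+1+0 = 2,
        # rho = 1 - 6*2/(4*15) = 0.8 -> distance 0.2
        d = programs.spearman_distance(_frame([[1, 2, 3, 4], [1, 3, 2, 4]]))
        assert d.iloc[0, 1] == pytest.approx(0.2)

    def test_constant_profile_distance_one(self):
        d = programs.spearman_distance(_frame([[5, 5, 5, 5], [1, 2, 3, 4]]))
        assert d.iloc[0, 1] == 1.0
        assert d.iloc[0, 0] == 0.0

    def test_monotone_transform_invariance(self, rng):
        base = _frame(rng.normal(size=(6, 8)).tolist())
        d1 = programs.spearman_distance(base)
        d2 = programs.spearman_distance(np.exp(base))
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)


class TestHierarchicalCluster:
    def test_planted_blocks_are_pure(self, rng):
        archetypes = [[1, 5, 4, 2, 1], [1, 1, 2, 4, 5], [5, 4, 3, 2, 1]]
        rows, truth = [], []
        for b, arch in enumerate(archetypes):
            for _ in range(30):
                rows.append(list(arch))
                truth.append(b)
        d = programs.spearman_distance(_frame(rows))
        result = programs.hierarchical_cluster(d, k=3)
        purity = pd.crosstab(result.labels.values, truth).max(axis=0).sum() / len(truth)
        assert purity == 1.0

    def test_k_one(self):
        d = programs.spearman_distance(_frame([[1, 2, 3], [3, 2, 1], [1, 3, 2]]))
        assert set(programs.hierarchical_cluster(d, k=1).labels) == {1}

    def test_k_too_large(self):
        d = programs.spearman_distance(_frame([[1, 2, 3], [3, 2, 1]]))
        with pytest.raises(ValueError, match="exceeds"):
            programs.hierarchical_cluster(d, k=5)

    def test_noisy_archetypes_recovered(self, rng):
        archetypes = np.array(
            [[10, 40, 38, 20, 15], [10, 11, 14, 30, 45], [40, 20, 15, 12, 10]], float
        )
        rows, truth = [], []
        for b in range(3):
            for _ in range(100):
                rows.append(archetypes[b] * rng.lognormal(0, 0.15, 5))
                truth.append(b)
        d = programs.spearman_distance(_frame([list(r) for r in rows]))
        labels = programs.hierarchical_cluster(d, k=3).labels
        purity = pd.crosstab(labels.values, truth).max(axis=0).sum() / len(truth)
        assert purity >= 0.95


class TestAssignProgramLabels:
    def _assignment(self, mean_profiles):
        genes, rows, cluster = [], [], []
        for ci, prof in enumerate(mean_profiles, start=1):
            for j in range(3):
                genes.append(f"c{ci}g{j}")
                rows.append(prof)
                cluster.append(ci)
        lfc = pd.DataFrame(rows, index=genes, columns=[1.0, 2.0, 5.0, 8.0])
        clusters = programs.ClusterResult(
            linkage=np.empty((0, 4)),
            labels=pd.Series(cluster, index=genes),
            distance_metric="1-spearman",
            linkage_method="average",
            k=3,
        )
        return programs.assign_program_labels(clusters, lfc)

    def test_three_archetypes_labeled(self):
        assignment = self._assignment(
            [[1.5, 1.2, 0.4, 0.3], [0.1, 0.3, 1.0, 1.2], [-1, -1, -0.8, -0.9]]
        )
        assert assignment.table.loc["c1g0", "program"] == "early"
        assert assignment.table.loc["c2g0", "program"] == "late"
        assert assignment.table.loc["c3g0", "program"] == "repression"
        assert assignment.sizes == {"early": 3, "late": 3, "repression": 3}

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            self._assignment(
                [[1.5, 1.2, 0.4, 0.3], [1.4, 1.1, 0.3, 0.2], [-1, -1, -0.8, -0.9]]
            )


class TestZscoreRows:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([4, 4, 4, 4], [0, 0, 0, 0]),
            ([1, 3], [-1, 1]),
            ([2, 4, 6], [-1.2247448714, 0.0, 1.2247448714]),
        ],
    )
    def test_values(self, row, expected):
        out = programs.zscore_rows(_frame([row]))
        np.testing.assert_allclose(out.iloc[0].to_numpy(), expected, atol=1e-9)


class TestProgramMedians:
    def test_induction(self):
        lfc = pd.DataFrame({8.0: np.log2([1.5, 1.8, 2.0])}, index=["a", "b", "c"])
        assert programs.program_medians(lfc, {"a", "b", "c"}, 8.0) == pytest.approx(80.0)

    def test_repression(self):
        lfc = pd.DataFrame({8.0: np.log2([0.5, 0.5, 0.5])}, index=["a", "b", "c"])
        assert programs.program_medians(
            lfc, {"a", "b", "c"}, 8.0, direction="repression"
        ) == pytest.approx(50.0)

    def test_empty_set(self):
        lfc = pd.DataFrame({8.0: [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="empty"):
            programs.program_medians(lfc, set(), 8.0)


class TestEndToEndRecovery:
    def test_gene_order_permutation_invariance(self):
        m, truth = synthetic.generate_expression(
            synthetic.ExpressionConfig(
                seed=3, n_background=50, n_early=25, n_late=25, n_repression=25,
                n_target_independent=0, n_target_attenuated=0,
            )
        )
        floored = expression.filter_and_floor(m)
        lfc = expression.compute_lfc(floored, "ribo")
        regulated = sorted(expression.select_regulated(lfc, "WT"))
        tpm = floored.subset(assay="ribo", genotype="WT").values.loc[regulated]

        def _assign(frame):
            d = programs.spearman_distance(frame)
            clusters = programs.hierarchical_cluster(d, k=3)
            return programs.assign_program_labels(
                clusters, lfc.genotype_frame("WT")
            ).table["program"]

        direct = _assign(tpm)
        permuted = _assign(tpm.sample(frac=1, random_state=1))
        assert (permuted.sort_index() == direct.sort_index()).all()
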