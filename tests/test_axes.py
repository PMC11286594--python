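import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.stats import rankdata, t as t_dist

import graftaxis as ga
from graftaxis.errors import TooFewPairsError, UnknownNetworkIdError


def oracle_spearman(x, y):
    """Brute-force rank-then-Pearson with the two-sided t approximation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    rx, ry = rankdata(x[mask]), rankdata(y[mask])
    n = mask.sum()
    rho = np.corrcoef(rx, ry)[0, 1]
    if abs(rho) >= 1:
        return rho, 0.0, n
    tstat = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return rho, 2 * t_dist.sf(abs(tstat), n - 2), n


class TestSpearman:
    def test_identity_gives_one(self):
        rho, p, n = ga.spearman([1, 3, 2, 5, 4], [1, 3, 2, 5, 4])
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_reversed_ranks_give_minus_one(self):
        rho, _, _ = ga.spearman([1, 2, 3, 4], [9, 7, 5, 3])
        assert rho == pytest.approx(-1.0)

    def test_untied_worked_example(self):
        # y ranks (1,2,3,5,4): sum of squared rank differences 2 -> 1 - 12/120
        rho, _, _ = ga.spearman([1, 2, 3, 4, 5], [5, 6, 7, 9, 8])
        assert rho == pytest.approx(0.9)

    def test_tied_values_use_average_ranks(self):
        # y = (5,6,7,8,7): average ranks (1,2,3.5,5,3.5) -> rho = 8/sqrt(95)
        rho, _, _ = ga.spearman([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert rho == pytest.approx(8 / np.sqrt(95), abs=1e-12)

    def test_pairwise_deletion_and_n_used(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        rho, _, n = ga.spearman(x, y)
        assert n == 3
        assert rho == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(TooFewPairsError):
            ga.spearman([1.0, np.nan, 3.0], [np.nan, 2.0, 4.0])

    def test_matches_brute_force_oracle(self, rng):
        """rho and p match rank-then-Pearson to 1e-12 on random vectors with
        ties (n = 5..30)."""
        for _ in range(20):
            n = int(rng.integers(5, 31))
            x = rng.integers(0, 8, n).astype(float)  # discrete -> ties
            y = 0.5 * x + rng.integers(0, 6, n)
            rho, p, n_used = ga.spearman(x, y)
            rho_o, p_o, n_o = oracle_spearman(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-12)
            assert n_used == n_o


class TestCorrelateActivityProteins:
    def test_protein_equal_to_activity_row_has_rho_one(self, tiny_panel):
        activity = pd.DataFrame(
            [tiny_panel.data.loc["A"].to_numpy(), [4.0, 1.0, 3.0, 2.0]],
            index=[1, 2], columns=tiny_panel.sample_ids)
        corr = ga.correlate_activity_proteins(activity, tiny_panel)
        assert corr.rho.loc[1, "A"] == pytest.approx(1.0)
        assert corr.rho.shape == (2, 4)
        assert (corr.n_used.to_numpy() == 4).all()

    def test_three_leaf_complete_linkage_merge_order(self, tiny_panel):
        """Profiles with pairwise rho (AB -1, AC 0.8, BC -0.8): A and C merge
        first; B joins last, so the leaf order keeps A next to C."""
        sub = ga.ProteinPanel(tiny_panel.data.loc[["A", "B", "C"]])
        activity = pd.DataFrame(np.eye(3) + 1.0, index=[1, 2, 3],
                                columns=["s1", "s2", "s3"])
        activity["s4"] = [0.5, 1.2, 2.0]
        corr = ga.correlate_activity_proteins(activity, sub)
        order = corr.col_order
        ia, ic, ib = order.index("A"), order.index("C"), order.index("B")
        assert abs(ia - ic) == 1  # A adjacent to C
        assert ib in (0, 2)

    def test_dendrogram_order_deterministic(self, reference_cohort):
        bundle, truth = reference_cohort
        labels = truth.gene_to_module[truth.gene_to_module > 0]
        z = ga.zscore_genes(ga.ExpressionMatrix(bundle.expression.data.loc[labels.index]))
        act = ga.network_activity(z, labels)
        panel = ga.ProteinPanel(bundle.proteins.data.iloc[:25])
        c1 = ga.correlate_activity_proteins(act, panel)
        c2 = ga.correlate_activity_proteins(act, panel)
        assert c1.row_order == c2.row_order
        assert c1.col_order == c2.col_order

    def test_rho_matrix_matches_oracle_on_random_instances(self, rng):
        """Full matrix equals the brute-force oracle to 1e-12 on 20 random
        small instances."""
        for _ in range(20):
            n_s = int(rng.integers(5, 10))
            samples = [f"s{j}" for j in range(n_s)]
            act = pd.DataFrame(rng.standard_normal((3, n_s)), index=[1, 2, 3],
                               columns=samples)
            panel = ga.ProteinPanel(pd.DataFrame(
                rng.integers(0, 5, (4, n_s)).astype(float),
                index=list("WXYZ"), columns=samples))
            corr = ga.correlate_activity_proteins(act, panel)
            for i in [1, 2, 3]:
                for prot in "WXYZ":
                    rho_o, p_o, _ = oracle_spearman(act.loc[i], panel.data.loc[prot])
                    if np.isnan(rho_o):
                        continue  # constant protein draw
                    assert corr.rho.loc[i, prot] == pytest.approx(rho_o, abs=1e-12)
                    assert corr.pval.loc[i, prot] == pytest.approx(p_o, abs=1e-12)


class TestAxisActivity:
    @pytest.fixture()
    def z_and_labels(self):
        data = pd.DataFrame(
            [[1.0, -1.0, 0.0], [0.0, 1.0, -1.0], [2.0, 0.0, -2.0], [-1.0, 1.0, 0.0]],
            index=["g1", "g2", "g3", "g4"], columns=["s1", "s2", "s3"])
        z = ga.ExpressionMatrix(data, zscored=True)
        labels = pd.Series([1, 2, 2, 2], index=data.index)
        return z, labels

    def test_single_network_axis_equals_activity_row(self, z_and_labels):
        z, labels = z_and_labels
        act = ga.network_activity(z, labels)
        axis_act = ga.axis_activity(z, labels, [ga.AxisDefinition("MB", [1])])
        assert np.allclose(axis_act.loc["MB"], act.loc[1])

    def test_gene_weighted_pooling(self, z_and_labels):
        z, labels = z_and_labels
        # networks of sizes 1 and 3: axis = 1/4*g1 + 3/4*mean(g2..g4)
        axis_act = ga.axis_activity(z, labels, [ga.AxisDefinition("MB", [1, 2])])
        expected = 0.25 * z.data.loc["g1"] + 0.75 * z.data.loc[["g2", "g3", "g4"]].mean()
        assert np.allclose(axis_act.loc["MB"], expected)

    def test_two_disjoint_axes_two_rows(self, z_and_labels):
        z, labels = z_and_labels
        out = ga.axis_activity(z, labels, [ga.AxisDefinition("MB", [1]),
                                           ga.AxisDefinition("INF", [2])])
        assert list(out.index) == ["MB", "INF"]

    def test_unknown_network_raises(self, z_and_labels):
        z, labels = z_and_labels
        with pytest.raises(UnknownNetworkIdError):
            ga.axis_activity(z, labels, [ga.AxisDefinition("MB", [9])])

    def test_overlapping_axes_rejected(self, z_and_labels):
        z, labels = z_and_labels
        with pytest.raises(ValueError):
            ga.axis_activity(z, labels, [ga.AxisDefinition("MB", [1]),
                                         ga.AxisDefinition("INF", [1, 2])])

    def test_from_networks_with_sizes_matches_gene_weighted(self, z_and_labels):
        z, labels = z_and_labels
        act = ga.network_activity(z, labels)
        sizes = labels.value_counts()
        a1 = ga.axis_activity(z, labels, [ga.AxisDefinition("MB", [1, 2])])
        a2 = ga.axis_activity_from_networks(act, [ga.AxisDefinition("MB", [1, 2])],
                                            sizes=sizes)
        assert np.allclose(a1.to_numpy(), a2.to_numpy())


def _table(rows):
    """rows: protein -> (rho_MB, p_MB, rho_INF, p_INF)."""
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["rho_MB", "p_MB", "rho_INF", "p_INF"])
    df.index.name = "protein"
    df["n_MB"] = 15
    df["n_INF"] = 15
    return df


class TestExtractSignature:
    @pytest.fixture()
    def table(self):
        return _table({
            "P1": (-0.9, 0.01, 0.8, 0.01),
            "P2": (-0.2, 0.5, 0.7, 0.02),
            "P3": (0.9, 0.01, -0.85, 0.01),
            "P4": (0.1, 0.8, 0.1, 0.8),
        })

    def test_injury_union_and_ranking(self, table):
        sig = ga.extract_signature(table, "INJURY", rho_min=0.6, p_max=0.05, k=2)
        assert sig.members == ["P1", "P2"]
        assert list(sig.proteins["rank"]) == [1, 2]

    def test_health(self, table):
        sig = ga.extract_signature(table, "HEALTH", rho_min=0.6, p_max=0.05, k=2)
        assert sig.members == ["P3"]

    def test_directional_categories(self, table):
        assert ga.extract_signature(table, "MB_down").members == ["P1"]
        assert ga.extract_signature(table, "MB_up").members == ["P3"]
        assert ga.extract_signature(table, "INF_up").members == ["P1", "P2"]
        assert ga.extract_signature(table, "INF_down").members == ["P3"]

    def test_empty_signature_allowed(self, table):
        sig = ga.extract_signature(table, "INJURY", rho_min=0.99)
        assert sig.members == []

    def test_insignificant_rho_excluded(self):
        table = _table({"P1": (-0.9, 0.2, 0.0, 0.9), "P2": (-0.7, 0.01, 0.0, 0.9)})
        sig = ga.extract_signature(table, "INJURY")
        assert sig.members == ["P2"]

    def test_up_down_mutually_exclusive_and_health_injury_disjoint(self, rng):
        rows = {}
        for i in range(40):
            rows[f"Q{i:02d}"] = tuple(rng.uniform(-1, 1, 1)) + (rng.uniform(0, 0.1),) \
                + tuple(rng.uniform(-1, 1, 1)) + (rng.uniform(0, 0.1),)
        table = _table(rows)
        up = set(ga.extract_signature(table, "MB_up", k=40).members)
        down = set(ga.extract_signature(table, "MB_down", k=40).members)
        assert not (up & down)
        health = set(ga.extract_signature(table, "HEALTH", k=40).members)
        injury = set(ga.extract_signature(table, "INJURY", k=40).members)
        assert not (health & injury)

    def test_ties_broken_by_protein_id(self):
        table = _table({"B": (-0.8, 0.01, 0.0, 0.9), "A": (-0.8, 0.01, 0.0, 0.9)})
        sig = ga.extract_signature(table, "MB_down", k=2)
        assert sig.members == ["A", "B"]


class TestProteinAxisTable:
    def test_protein_equal_to_axis_activity(self, tiny_panel):
        axis_act = pd.DataFrame([tiny_panel.data.loc["A"].to_numpy()],
                                index=["MB"], columns=tiny_panel.sample_ids)
        table = ga.protein_axis_table(axis_act, tiny_panel)
        assert table.loc["A", "rho_MB"] == pytest.approx(1.0)

    def test_planted_coupling_recovered(self, small_config):
        cfg = replace(small_config, n_samples=500)
        bundle, truth = ga.generate_cohort(cfg, seed=11)
        labels = truth.gene_to_module[truth.gene_to_module > 0]
        z = ga.zscore_genes(ga.ExpressionMatrix(bundle.expression.data.loc[labels.index]))
        axes = [ga.AxisDefinition("MB", [1, 2]), ga.AxisDefinition("INF", [3, 4])]
        table = ga.protein_axis_table(ga.axis_activity(z, labels, axes), bundle.proteins)
        # P001 planted at rho +0.85 to INF; axis activity dilutes it somewhat
        assert 0.6 < table.loc["P001", "rho_INF"] < 0.95
        assert table.loc["P001", "rho_MB"] < -0.4

    def test_null_proteins_mostly_insignificant(self, small_config):
        """Uncoupled proteins vs the MB axis: p > 0.05 in >=90% of 20 seeds."""
        cfg = replace(small_config, n_samples=500, n_modules=2,
                      genes_per_module=10, n_background_genes=5,
                      axis_map={1: "MB", 2: "INF"}, n_proteins=2,
                      protein_couplings=[])
        ok = 0
        for seed in range(20):
            bundle, truth = ga.generate_cohort(cfg, seed=seed)
            labels = truth.gene_to_module[truth.gene_to_module > 0]
            z = ga.zscore_genes(
                ga.ExpressionMatrix(bundle.expression.data.loc[labels.index]))
            axes = [ga.AxisDefinition("MB", [1])]
            table = ga.protein_axis_table(ga.axis_activity(z, labels, axes),
                                          bundle.proteins)
            ok += table.loc["P001", "p_MB"] > 0.05
        assert ok >= 18
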