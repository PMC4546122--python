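import numpy as np
import pandas as pd
import pytest

from embryovar import (
    GeneList,
    catalogue_enrichment,
    classify_expression_modes,
    identify_stable_genes,
    log_transform,
    stage_overlap_of_modes,
)
from embryovar.simulate import generate_dataset, stable_recovery_config

from conftest import make_dataset


@pytest.fixture(scope="module")
def recovered():
    ds, truth = generate_dataset(stable_recovery_config(seed=1))
    dsl = log_transform(ds)
    res = identify_stable_genes(dsl, seed=1)
    return dsl, truth, res


def test_planted_stable_recovery(recovered):
    _, truth, res = recovered
    stable = set(res.stable_genes)
    planted = set(truth.index[truth["class"] == "stable"])
    shift = set(truth.index[truth["class"] == "shift"])
    assert len(stable & planted) / len(planted) >= 0.85
    assert len(stable & shift) / len(shift) <= 0.15


def test_constant_gene_is_stable():
    rng = np.random.default_rng(0)
    vals = rng.uniform(1, 5, size=(40, 8))
    vals[0, :] = 3.0  # identical in every cell of every stage
    ds = make_dataset(vals, ["A", "A", "B", "B", "C", "C", "D", "D"],
                      {"A": "s1", "B": "s1", "C": "s2", "D": "s2"})
    res = identify_stable_genes(ds, seed=1)
    assert res.table.loc["g0", "is_stable"]


def test_stable_set_invariant_to_gene_order(recovered):
    dsl, _, res = recovered
    from dataclasses import replace

    perm = np.random.default_rng(3).permutation(dsl.n_genes)
    shuffled = replace(dsl, values=dsl.values.iloc[perm])
    res2 = identify_stable_genes(shuffled, seed=1)
    assert set(res.stable_genes) == set(res2.stable_genes)


def test_alpha_monotonicity(recovered):
    dsl, _, _ = recovered
    pools = [
        (identify_stable_genes(dsl, alpha=a, seed=1).table["levene_p_adj"] > a).sum()
        for a in (0.01, 0.05, 0.2)
    ]
    assert pools == sorted(pools, reverse=True)


class TestExpressionModes:
    def test_planted_trimodal_recovery(self):
        rng = np.random.default_rng(1)
        n = 600
        modes = np.repeat([0, 1, 2], n // 3)
        centers = np.array([0.5, 4.0, 9.0])
        vals = np.maximum(centers[modes][:, None] + rng.normal(0, 0.3, (n, 8)), 0.0)
        ds = make_dataset(vals, ["A"] * 4 + ["B"] * 4, {"A": "s", "B": "s"})
        labels, fit, bounds = classify_expression_modes(ds, ds.gene_ids, "s", seed=1)
        assert fit.K == 3
        expected = np.array(["low", "medium", "high"])[modes]
        assert (labels.to_numpy() == expected).mean() >= 0.98
        assert len(bounds) == 2

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(1, 0.2, (30, 4)),
                               rng.normal(6, 0.2, (30, 4))])
        ds = make_dataset(vals, ["A", "A", "B", "B"], {"A": "s", "B": "s"})
        labels, _, _ = classify_expression_modes(ds, ds.gene_ids, "s", seed=1)
        perm = list(ds.gene_ids[::-1])
        labels2, _, _ = classify_expression_modes(ds, perm, "s", seed=1)
        assert labels.sort_index().equals(labels2.sort_index())

    def test_too_few_stable_genes_rejected(self, two_stage_dataset):
        with pytest.raises(ValueError):
            classify_expression_modes(two_stage_dataset,
                                      two_stage_dataset.gene_ids[:2], "s1")


class TestModeOverlap:
    def test_identical_labels_fraction_one(self):
        s = pd.Series(["low", "medium"], index=["g1", "g2"])
        out = stage_overlap_of_modes({"s1": s, "s2": s})
        assert out.loc["low", "frac_of_any"] == 1.0
        assert out.loc["medium", "n_all_stages"] == 1

    def test_disjoint_labels_fraction_zero(self):
        a = pd.Series(["low"], index=["g1"])
        b = pd.Series(["low"], index=["g2"])
        out = stage_overlap_of_modes({"s1": a, "s2": b})
        assert out.loc["low", "frac_of_any"] == 0.0


class TestEnrichment:
    def test_catalogue_equals_gene_set(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(20)}
        cat = GeneList("cat", frozenset(gene_set))
        row = catalogue_enrichment(gene_set, cat, universe)
        assert row.overlap == 20
        assert row.fisher.direction == "enrichment"
        assert row.fisher.p_two_sided < 1e-15

    def test_margin_identities(self):
        rng = np.random.default_rng(0)
        universe = {f"g{i}" for i in range(60)}
        gene_set = set(rng.choice(sorted(universe), 25, replace=False))
        cat = GeneList("c", frozenset(rng.choice(sorted(universe), 30, replace=False)))
        row = catalogue_enrichment(gene_set, cat, universe)
        assert row.overlap <= min(row.n_set, row.n_catalogue)
        assert row.n_catalogue <= row.n_universe

    def test_empty_intersection_p_one(self):
        universe = {"g1", "g2", "g3"}
        cat = GeneList("c", frozenset({"x1"}))
        row = catalogue_enrichment({"g1"}, cat, universe)
        assert row.fisher.p_two_sided == 1.0
        assert row.overlap == 0

    def test_null_calibration(self):
        """Random catalogues from the universe reject at ~ the nominal rate."""
        rng = np.random.default_rng(42)
        universe = [f"g{i}" for i in range(400)]
        gene_set = set(universe[:80])
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            cat = GeneList(
                "c", frozenset(rng.choice(universe, 40, replace=False))
            )
            if catalogue_enrichment(gene_set, cat, set(universe)).fisher.p_two_sided < 0.05:
                rejections += 1
        # Fisher is conservative for discrete tables: rate at or below ~5%
        assert rejections / n_sims <= 0.07
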