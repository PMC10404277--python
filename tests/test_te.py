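"""Translation efficiency, TE-change classification, and NB differential expression."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from polyte.normalize import compute_size_factors, normalize_counts
from polyte.simulate import (
    SimulationDesign,
    generate_fraction_counts,
    make_spikein_reference,
)
from polyte.te import (
    TE_DOWN,
    TE_UNCHANGED,
    TE_UP,
    classify_te_change,
    compute_te,
    differential_expression,
    estimate_common_dispersion,
    nb_exact_test_pvalue,
    rna_log2fc,
    te_log2fc,
    te_table,
)


def series(vals):
    return pd.Series(vals, index=[f"g{i}" for i in range(len(vals))], dtype=float)


class TestComputeTe:
    def test_equal_fractions_give_unit_te(self):
        te = compute_te(series([10, 20]), series([10, 20]), pseudocount=0)
        np.testing.assert_allclose(te, 1.0)

    def test_hand_arithmetic_with_pseudocount(self):
        te = compute_te(series([40]), series([10]), pseudocount=1.0)
        assert te.iloc[0] == pytest.approx(41 / 11)

    def test_common_scaling_cancels_without_pseudocount(self):
        p, m = series([40, 8]), series([10, 2])
        te1 = compute_te(p, m, pseudocount=0)
        te2 = compute_te(7 * p, 7 * m, pseudocount=0)
        np.testing.assert_allclose(te1, te2)

    def test_replicates_combined_by_geometric_mean(self):
        poly = pd.DataFrame({"r1": [4.0], "r2": [16.0]}, index=["g"])
        mono = pd.DataFrame({"r1": [1.0], "r2": [1.0]}, index=["g"])
        te = compute_te(poly, mono, pseudocount=0)
        assert te["g"] == pytest.approx(8.0)  # sqrt(4 * 16)
        pooled = compute_te(poly, mono, pseudocount=0, method="pooled")
        assert pooled["g"] == pytest.approx(10.0)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            compute_te(series([-1]), series([1]))


class TestLog2FoldChanges:
    def test_equal_te_gives_zero(self):
        te = series([1.5, 2.0])
        np.testing.assert_allclose(te_log2fc(te, te), 0.0)

    def test_fourfold_te_gives_two(self):
        te = series([1.0, 3.0])
        np.testing.assert_allclose(te_log2fc(4 * te, te), 2.0)

    def test_noise_free_planted_te_recovered_exactly(self):
        # dispersion 0: counts equal rounded means, planted delta recovered
        delta = {"gene001": 2.0, "gene002": -4.0}
        design = SimulationDesign(
            mean_depth=4096.0, dispersion=0.0, te_effects=delta, seed=7
        )
        cm, lib_design = generate_fraction_counts(
            [f"gene{i:03d}" for i in range(1, 6)], design
        )
        table = te_table(cm.counts.astype(float), lib_design, pseudocount=1e-9)
        got = table.set_index("gene_id")["te_log2fc"]
        for g, d in delta.items():
            assert got[g] == pytest.approx(d, abs=1e-6)
        assert got["gene003"] == pytest.approx(0.0, abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize(
        "te_lfc,rna_lfc,expected",
        [
            (1.5, 0.2, TE_UP),
            (-1.2, 0.5, TE_DOWN),
            (1.5, 1.2, TE_UNCHANGED),   # RNA moved too
            (1.0, 0.0, TE_UNCHANGED),   # boundary: strict inequality
            (-1.0, 0.0, TE_UNCHANGED),
            (1.5, 1.0, TE_UNCHANGED),   # RNA boundary also strict
            (0.0, 0.0, TE_UNCHANGED),
        ],
    )
    def test_rule_examples(self, te_lfc, rna_lfc, expected):
        assert classify_te_change(te_lfc, rna_lfc) == expected

    def test_agrees_with_brute_force_rule_on_grid(self):
        grid = np.linspace(-3, 3, 41)
        for te in grid:
            for rna in grid:
                got = classify_te_change(te, rna, 1.0, 1.0)
                if abs(rna) < 1.0 and te > 1.0:
                    assert got == TE_UP
                elif abs(rna) < 1.0 and te < -1.0:
                    assert got == TE_DOWN
                else:
                    assert got == TE_UNCHANGED

    def test_antisymmetry_under_genotype_swap(self, rng):
        design = SimulationDesign(
            mean_depth=300.0, dispersion=0.05,
            te_effects={"g005": 2.0}, seed=11,
        )
        genes = [f"g{i:03d}" for i in range(20)]
        cm, lib_design = generate_fraction_counts(genes, design)
        fwd = te_table(cm.counts.astype(float), lib_design)
        swapped = lib_design.copy()
        swapped["genotype"] = swapped["genotype"].map(
            {"control": "mutant", "mutant": "control"}
        )
        rev = te_table(cm.counts.astype(float), swapped)
        np.testing.assert_allclose(fwd["te_log2fc"], -rev["te_log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["rna_log2fc"], -rev["rna_log2fc"], atol=1e-12)
        flip = {TE_UP: TE_DOWN, TE_DOWN: TE_UP, TE_UNCHANGED: TE_UNCHANGED}
        assert list(fwd["te_class"].map(flip)) == list(rev["te_class"])

    def test_te_lfc_monotone_in_polysome_counts(self):
        mono = pd.DataFrame({"r1": [10.0], "r2": [12.0]}, index=["g"])
        prev = -np.inf
        for poly_level in [5.0, 10.0, 20.0, 40.0, 80.0]:
            poly = pd.DataFrame({"r1": [poly_level], "r2": [poly_level]}, index=["g"])
            te = compute_te(poly, mono)
            lfc = te_log2fc(te, pd.Series({"g": 1.0}))["g"]
            assert lfc > prev
            prev = lfc


class TestDifferentialExpression:
    def test_bh_step_up_hand_example(self):
        fdr = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(fdr, 0.04)

    def test_identical_groups_are_ns(self):
        counts = pd.DataFrame(
            {
                "control_total_rep1": [100, 50],
                "control_total_rep2": [110, 55],
                "mutant_total_rep1": [100, 50],
                "mutant_total_rep2": [110, 55],
            },
            index=["g1", "g2"],
        )
        design = pd.DataFrame(
            {
                "library_id": counts.columns,
                "genotype": ["control", "control", "mutant", "mutant"],
                "fraction": "total",
                "replicate": [1, 2, 1, 2],
            }
        )
        res = differential_expression(counts, design)
        np.testing.assert_allclose(res["log2fc"], 0.0)
        assert (res["de_class"] == "ns").all()

    def test_planted_fourfold_changes_recovered(self):
        genes = [f"g{i:04d}" for i in range(300)]
        effects = {g: 2.0 for g in genes[:20]}
        design = SimulationDesign(
            fractions=("total",), mean_depth=500.0, dispersion=0.05,
            rna_effects=effects, seed=5,
        )
        cm, lib_design = generate_fraction_counts(genes, design)
        res = differential_expression(cm.counts.astype(float), lib_design)
        res = res.set_index("gene_id")
        hits = (res.loc[list(effects), "de_class"] == "up").mean()
        assert hits >= 0.8
        false_up = (res.drop(index=list(effects))["de_class"] != "ns").mean()
        assert false_up <= 0.05

    def test_single_replicate_design_error(self):
        counts = pd.DataFrame(
            {"control_total_rep1": [10], "mutant_total_rep1": [12]}, index=["g"]
        )
        design = pd.DataFrame(
            {
                "library_id": counts.columns,
                "genotype": ["control", "mutant"],
                "fraction": "total",
                "replicate": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(counts, design)

    def test_exact_pvalue_symmetry_and_range(self):
        p_eq = nb_exact_test_pvalue(50, 50, 2, 2, 0.05)
        assert p_eq == pytest.approx(1.0, abs=0.05)
        p_ab = nb_exact_test_pvalue(20, 120, 2, 2, 0.05)
        p_ba = nb_exact_test_pvalue(120, 20, 2, 2, 0.05)
        assert p_ab == pytest.approx(p_ba, rel=1e-9)
        assert 0 < p_ab < 0.2

    def test_exact_pvalue_matches_dispersion_free_conditional_law(self):
        # independent oracle: the conditional null distribution of the
        # group-A sum given the total is negative hypergeometric
        # (beta-binomial with integer shape parameters), free of mu
        from scipy.stats import betabinom

        n_a = n_b = 2
        alpha = 0.1
        r_a, r_b = n_a / alpha, n_b / alpha
        total = 60
        k = np.arange(total + 1)
        oracle = betabinom.pmf(k, total, r_a, r_b)
        for s_a in (5, 20, 30, 55):
            f_obs = oracle[s_a]
            expected = oracle[oracle <= f_obs * (1 + 1e-10)].sum()
            got = nb_exact_test_pvalue(s_a, total - s_a, n_a, n_b, alpha)
            assert got == pytest.approx(expected, rel=1e-8)

    def test_moment_dispersion_estimate_recovers_planted_alpha(self, rng):
        mu, alpha, n = 500.0, 0.08, 4000
        lam = rng.gamma(1 / alpha, alpha * mu, size=(n, 4))
        counts = pd.DataFrame(rng.poisson(lam), index=[f"g{i}" for i in range(n)],
                              columns=list("abcd"))
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        est = estimate_common_dispersion(counts, groups)
        assert est == pytest.approx(alpha, rel=0.2)
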