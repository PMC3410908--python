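"""Pairwise interaction tests: tabulation, the two screening tests, the
case-only variant and the 1-df constrained tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize

from episcreen.cohort import SnpSpec, simulate_genotypes
from episcreen.pairtests import (PairTestResult, TwoLocusInteraction,
                                 TwoLocusTable, compound_table)
from episcreen.pairtests import test_allelic as allelic_test
from episcreen.pairtests import test_case_only as case_only_test
from episcreen.pairtests import test_genotypic as genotypic_test
from episcreen.pairtests import test_model_constrained as constrained_test

from conftest import interaction_model, make_cohort


def table_from_counts(case: np.ndarray, ctrl: np.ndarray) -> TwoLocusTable:
    return TwoLocusTable(np.stack([np.asarray(ctrl), np.asarray(case)]))


class TestCompoundTable:
    def test_direct_tabulation(self):
        g1 = np.array([0, 1, 2, 0])
        g2 = np.array([0, 1, 2, 2])
        y = np.ones(4, dtype=int)
        with pytest.raises(ValueError):
            compound_table(g1, g2, y)  # no controls
        y = np.array([1, 1, 1, 0])
        t = compound_table(g1, g2, y)
        assert t.counts[1].sum() == 3
        assert t.counts[1, 0, 0] == 1
        assert t.counts[1, 1, 1] == 1
        assert t.counts[1, 2, 2] == 1
        assert t.counts[0, 0, 2] == 1

    def test_double_het_splits_evenly(self):
        t = table_from_counts(case=[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
                              ctrl=[[1, 0, 0], [0, 0, 0], [0, 0, 0]])
        assert np.all(t.allele_collapsed[1] == 1)

    @given(st.lists(st.integers(0, 20), min_size=18, max_size=18))
    @settings(max_examples=50, deadline=None)
    def test_collapsed_margins_conserved(self, flat):
        """Collapsed margins equal 2x the per-locus allele counts in each
        group."""
        counts = np.array(flat).reshape(2, 3, 3)
        t = TwoLocusTable(counts)
        collapsed = t.allele_collapsed
        for g in (0, 1):
            c = counts[g]
            n = c.sum()
            minor_a = (c * np.array([0, 1, 2])[:, None]).sum()
            minor_b = (c * np.array([0, 1, 2])[None, :]).sum()
            assert collapsed[g].sum() == 4 * n
            # locus-A margin: rows of the collapsed table
            assert collapsed[g][1].sum() == 2 * minor_a
            assert collapsed[g][:, 1].sum() == 2 * minor_b


def _oracle_lrt(table: TwoLocusTable) -> float:
    """Independent brute-force LRT: direct minimisation of the binomial
    negative log-likelihood of the main-effects logistic model, against the
    saturated 2x9 fit."""
    n = table.counts
    obs = np.argwhere(n.sum(axis=0) > 0)
    cases = n[1][tuple(obs.T)].astype(float)
    ctrls = n[0][tuple(obs.T)].astype(float)
    i, j = obs[:, 0], obs[:, 1]
    X = np.column_stack([np.ones(len(obs)), i == 1, i == 2, j == 1, j == 2]
                        ).astype(float)

    def nll(beta):
        eta = X @ beta
        return float(np.sum((cases + ctrls) * np.logaddexp(0, eta) - cases * eta))

    best = min((minimize(nll, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12,
                                  "maxiter": 20000})
                for x0 in (np.zeros(5), np.full(5, 0.1))),
               key=lambda r: r.fun)
    tot = cases + ctrls
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_sat = np.nansum(cases * np.log(cases / tot)) + \
            np.nansum(ctrls * np.log(ctrls / tot))
    return 2.0 * (best.fun + ll_sat)


class TestGenotypic:
    def test_factorizable_table_null(self):
        """Independent loci with equal case/control frequencies give a
        statistic of ~0."""
        pa = np.array([0.49, 0.42, 0.09])
        cell = np.outer(pa, pa) * 100000
        t = table_from_counts(cell.astype(int), cell.astype(int))
        r = genotypic_test(t)
        assert r.df == 4
        assert r.statistic == pytest.approx(0.0, abs=1e-6)
        assert r.p > 0.999

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_loglinear_oracle(self, seed):
        """LRT equals an independent brute-force fit on complete tables."""
        rng = np.random.default_rng(seed)
        case = rng.integers(5, 80, size=(3, 3))
        ctrl = rng.integers(5, 80, size=(3, 3))
        t = table_from_counts(case, ctrl)
        r = genotypic_test(t)
        assert r.feasible and r.df == 4
        assert r.statistic == pytest.approx(_oracle_lrt(t), abs=1e-6)

    def test_locus_swap_and_allele_flip_invariance(self, interacting_cohort):
        g = interacting_cohort
        r1 = TwoLocusInteraction.from_matrix(g, "s0", "s1").fit("genotypic")
        r2 = TwoLocusInteraction(g.column("s1"), g.column("s0"),
                                 g.phenotype).fit("genotypic")
        r3 = TwoLocusInteraction(2 - g.column("s0"), g.column("s1"),
                                 g.phenotype).fit("genotypic")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-8)
        assert r1.statistic == pytest.approx(r3.statistic, rel=1e-6)

    def test_empty_cell_reduces_df(self):
        case = np.array([[30, 20, 5], [20, 10, 2], [5, 2, 0]])
        ctrl = np.array([[32, 18, 6], [19, 11, 3], [6, 3, 0]])
        r = genotypic_test(table_from_counts(case, ctrl))
        assert r.feasible
        assert r.df == 3  # (2,2) unobserved -> one interaction column dropped

    def test_monomorphic_infeasible(self):
        case = np.zeros((3, 3), int)
        case[0, 0] = 50
        case[0, 1] = 30
        r = genotypic_test(table_from_counts(case, case))
        assert not r.feasible and "monomorphic" in r.reason

    def test_detects_strong_interaction(self, interacting_cohort):
        r = TwoLocusInteraction.from_matrix(
            interacting_cohort, "s0", "s1").fit("genotypic")
        assert r.p < 1e-6


class TestAllelic:
    def test_worked_example(self):
        """Hand-evaluated z: case cells (40,10,10,40) vs control
        (25,25,25,25) give z = ln(16)/sqrt(0.25+0.16)."""
        from episcreen.pairtests import _allelic_z
        collapsed = np.array([[[25, 25], [25, 25]],
                              [[40, 10], [10, 40]]], dtype=float)
        z, p = _allelic_z(collapsed)
        z_expected = np.log(16) / np.sqrt(0.25 + 0.16)
        assert z == pytest.approx(z_expected, rel=1e-12)
        assert z == pytest.approx(4.33, abs=0.005)
        assert p == pytest.approx(2 * stats.norm.sf(z_expected), rel=1e-12)

    def test_collapsing_feeds_z(self):
        """test_allelic wires collapsing into the z formula consistently."""
        rng = np.random.default_rng(19)
        case = rng.integers(5, 60, (3, 3))
        ctrl = rng.integers(5, 60, (3, 3))
        t = table_from_counts(case, ctrl)
        from episcreen.pairtests import _allelic_z
        z, p = _allelic_z(t.allele_collapsed)
        r = allelic_test(t)
        assert r.statistic == pytest.approx(z)
        assert r.p == pytest.approx(p)

    def test_identical_groups_z_zero(self):
        cell = np.array([[40, 20, 4], [20, 10, 2], [4, 2, 1]])
        r = allelic_test(table_from_counts(cell, cell))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_zero_cell_infeasible(self):
        # locus B carries no minor allele in either group -> collapsed
        # minor-B cells are zero
        case = np.array([[50, 0, 0], [10, 0, 0], [5, 0, 0]])
        r = allelic_test(table_from_counts(case, case))
        assert not r.feasible
        assert r.reason == "low allele frequencies"

    def test_allele_flip_changes_sign_only(self, interacting_cohort):
        g = interacting_cohort
        r1 = TwoLocusInteraction.from_matrix(g, "s0", "s1").fit("allelic")
        r2 = TwoLocusInteraction(2 - g.column("s0"), g.column("s1"),
                                 g.phenotype).fit("allelic")
        assert r2.statistic == pytest.approx(-r1.statistic, rel=1e-10)
        assert r2.p == pytest.approx(r1.p, rel=1e-10)


class TestCaseOnly:
    def test_or_one_gives_z_zero(self):
        case = np.array([[40, 20, 0], [20, 10, 0], [0, 0, 0]])
        # collapsed case OR exactly 1 by construction
        r = case_only_test(table_from_counts(case, case))
        assert r.feasible
        assert r.statistic == pytest.approx(0.0, abs=1e-10)

    def test_calibrated_under_independence(self):
        """Independent loci: nominal type-I error."""
        rng = np.random.default_rng(20)
        rejects = 0
        n_rep = 400
        for _ in range(n_rep):
            g = make_cohort(250, 250, seed=int(rng.integers(2**31)))
            r = TwoLocusInteraction.from_matrix(g, "s0", "s1").fit("case_only")
            rejects += r.feasible and r.p < 0.05
        rate = rejects / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_ld_inflates_rejections(self):
        """Known bias: with LD between loci and no interaction the case-only
        test rejects far above nominal."""
        from episcreen.cohort import CohortConfig, DiseaseModel, simulate_case_control
        specs = (SnpSpec("s0", 0.3),
                 SnpSpec("s1", 0.3, ld_partner="s0", ld_r=0.6))
        model = DiseaseModel(intercept=float(np.log(0.1 / 0.9)))
        rng = np.random.default_rng(21)
        rejects = 0
        n_rep = 50
        for _ in range(n_rep):
            g = simulate_case_control(CohortConfig(
                300, 300, specs, model, seed=int(rng.integers(2**31))))
            r = TwoLocusInteraction.from_matrix(g, "s0", "s1").fit("case_only")
            rejects += r.feasible and r.p < 0.05
        assert rejects / n_rep > 0.5


class TestModelConstrained:
    def test_null_calibration(self):
        rng = np.random.default_rng(22)
        rejects = 0
        n_rep = 500
        for _ in range(n_rep):
            g = make_cohort(300, 300, seed=int(rng.integers(2**31)))
            r = TwoLocusInteraction.from_matrix(g, "s0", "s1").fit("addxadd")
            rejects += r.feasible and r.p < 0.05
        assert abs(rejects / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_recxrec_degenerate_support(self):
        rng = np.random.default_rng(23)
        g1 = rng.binomial(1, 0.3, 200)  # no dosage-2 at all
        g2 = rng.binomial(1, 0.3, 200)
        y = rng.integers(0, 2, 200)
        r = constrained_test(g1, g2, y, "recxrec")
        assert not r.feasible
        assert "constant" in r.reason

    def test_power_ordering_on_addxadd_data(self):
        """Matched 1-df test >= model-free 4-df >= recessive-coded, on
        additive x additive simulations."""
        gamma = np.log(2.2)
        rng = np.random.default_rng(24)
        wins = {"addxadd": 0, "genotypic": 0, "recxrec": 0}
        n_rep = 150
        alpha = 1e-3
        for _ in range(n_rep):
            g = make_cohort(500, 500, model=interaction_model(gamma),
                            seed=int(rng.integers(2**31)))
            m = TwoLocusInteraction.from_matrix(g, "s0", "s1")
            for method in wins:
                r = m.fit(method)
                wins[method] += r.feasible and r.p < alpha
        assert wins["addxadd"] >= wins["genotypic"] >= wins["recxrec"]

    def test_missing_pairwise_deletion(self, null_cohort):
        from episcreen.cohort import MISSING
        g1 = null_cohort.column("s0").copy()
        g1[:17] = MISSING
        r = constrained_test(g1, null_cohort.column("s1"),
                                   null_cohort.phenotype, "addxadd")
        assert r.feasible
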