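import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwaskit import simcohort as sc
from gwaskit.gwasio import DosageMatrix, VariantRecord
from gwaskit.prs import (
    DEFAULT_PT_GRID,
    ScoreModel,
    build_score,
    liability_scale_r2,
    nagelkerke_r2,
    prs_association,
    pseudo_controls,
    score_individuals,
    trio_transmission_score,
    variance_explained_loci,
)
from gwaskit.simcohort import TrioCohort


def make_discovery(n=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "snp": [f"v{i}" for i in range(n)],
            "chr": "1",
            "pos": np.arange(1, n + 1) * 1000,
            "effect_allele": "G",
            "other_allele": "A",
            "freq": rng.uniform(0.1, 0.5, n),
            "info": np.ones(n),
            "beta": rng.normal(0, 0.2, n),
            "se": np.full(n, 0.05),
            "p": rng.uniform(size=n),
        }
    )


def make_target(dosages, freqs=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if freqs is None:
        freqs = dosages.mean(axis=0) / 2
    variants = [
        VariantRecord(id=f"v{j}", chrom="1", pos=(j + 1) * 1000, ref="A", alt="G",
                      af=float(freqs[j]))
        for j in range(m)
    ]
    return DosageMatrix([f"S{i}" for i in range(n)], variants, dosages)


class TestBuildScore:
    def test_threshold_one_keeps_everything(self):
        disc = make_discovery()
        model = build_score(disc, p_threshold=1.0)
        assert len(model) == 10

    def test_pruning_keeps_smaller_p_of_perfect_pair(self):
        disc = make_discovery(n=2)
        disc.loc[0, "p"] = 1e-4
        disc.loc[1, "p"] = 1e-6
        rng = np.random.default_rng(1)
        col = rng.binomial(2, 0.4, size=200).astype(float)
        ld = make_target(np.column_stack([col, col]))  # r^2 = 1
        model = build_score(disc, 1.0, prune=True, r2_max=0.25, ld_panel=ld)
        assert model.variants["snp"].tolist() == ["v1"]

    def test_low_target_info_excluded(self):
        disc = make_discovery(n=3)
        info = np.array([0.9, 0.75, 0.85])
        model = build_score(disc, 1.0, target_info={"cohortA": info})
        assert "v1" not in model.variants["snp"].tolist()

    def test_empty_model_names_binding_filter(self):
        disc = make_discovery()
        with pytest.raises(ValueError, match="p_threshold"):
            build_score(disc, p_threshold=1e-30)

    def test_model_sizes_monotone_over_pt_grid(self):
        disc = make_discovery(n=200, seed=3)
        sizes = []
        for pt in DEFAULT_PT_GRID:
            try:
                sizes.append(len(build_score(disc, pt)))
            except ValueError:
                sizes.append(0)
        assert sizes == sorted(sizes)
        assert len(DEFAULT_PT_GRID) == 11


class TestScoreIndividuals:
    def test_zero_weights_zero_scores(self):
        disc = make_discovery(n=3)
        disc["beta"] = 0.0
        model = build_score(disc, 1.0)
        target = make_target(np.ones((5, 3)))
        scores, _ = score_individuals(model, target)
        np.testing.assert_allclose(scores, 0.0)

    def test_single_variant_arithmetic(self):
        disc = make_discovery(n=1)
        disc["beta"] = np.log(1.5)
        model = build_score(disc, 1.0)
        target = make_target(np.array([[2.0], [0.0]]))
        scores, _ = score_individuals(model, target)
        assert scores[0] == pytest.approx(2 * np.log(1.5))
        assert scores[1] == pytest.approx(0.0)

    def test_allele_flip_invariance_up_to_constant(self):
        disc = make_discovery(n=4, seed=5)
        model = build_score(disc, 1.0)
        rng = np.random.default_rng(6)
        target = make_target(rng.uniform(0, 2, size=(30, 4)))
        scores, _ = score_individuals(model, target)
        flipped = disc.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            disc["other_allele"], disc["effect_allele"],
        )
        flipped["beta"] = -disc["beta"]
        flipped["freq"] = 1 - disc["freq"]
        model_f = build_score(flipped, 1.0)
        scores_f, _ = score_individuals(model_f, target)
        diff = scores - scores_f
        np.testing.assert_allclose(diff, diff[0], atol=1e-10)

    def test_missing_variant_imputed_from_frequency(self):
        disc = make_discovery(n=2)
        disc.loc[1, "snp"] = "not_in_target"
        model = build_score(disc, 1.0)
        target = make_target(np.zeros((3, 2)))  # only v0 matches
        scores, report = score_individuals(model, target)
        assert "imputed_from_frequency" in report["note"].tolist()

    def test_strand_ambiguous_flagged(self):
        disc = make_discovery(n=1)
        disc["effect_allele"], disc["other_allele"] = "A", "T"
        model = build_score(disc, 1.0)
        variants = [VariantRecord(id="v0", chrom="1", pos=1000, ref="T", alt="A",
                                  af=0.5)]
        target = DosageMatrix(["S0"], variants, np.array([[1.0]]))
        _, report = score_individuals(model, target)
        assert "strand_ambiguous" in report["note"].tolist()


class TestPseudoControls:
    def test_both_parents_homozygous_forced(self):
        trios = TrioCohort(child=np.array([[2]]), father=np.array([[2]]),
                           mother=np.array([[2]]))
        case, pseudo, valid = pseudo_controls(trios)
        assert case[0, 0] == 2
        assert sorted(pseudo[0, :, 0].tolist()) == [2, 2, 2]
        assert valid.all()

    def test_het_het_child_homalt(self):
        trios = TrioCohort(child=np.array([[2]]), father=np.array([[1]]),
                           mother=np.array([[1]]))
        _, pseudo, valid = pseudo_controls(trios)
        assert sorted(pseudo[0, :, 0].tolist()) == [0, 1, 1]
        assert valid.all()

    def test_mendelian_inconsistency_masked(self):
        trios = TrioCohort(child=np.array([[2]]), father=np.array([[0]]),
                           mother=np.array([[0]]))
        case, pseudo, valid = pseudo_controls(trios)
        assert not valid[0, 0]
        assert case[0, 0] == 0  # masked

    def test_null_case_pseudo_score_difference(self, independent_panel):
        trios = sc.simulate_trios(independent_panel, sc.RiskModel.null(0.05),
                                  2000, seed=40)
        case, pseudo, valid = pseudo_controls(trios)
        rng = np.random.default_rng(41)
        w = rng.normal(0, 0.2, size=trios.n_variants)
        case_scores = case @ w
        pseudo_scores = np.einsum("ncm,m->nc", pseudo, w)
        diff = case_scores - pseudo_scores.mean(axis=1)
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert abs(t) < 3


class TestPrsAssociation:
    def test_constant_scores_no_information(self):
        out = prs_association(np.ones(100), np.repeat([0, 1], 50))
        assert out["r2_nagelkerke"] == 0.0
        assert np.isnan(out["p"])

    def test_unmatched_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        scores = rng.normal(size=300)
        eta = -0.2 + 0.8 * scores
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(int)
        out = prs_association(scores, y)
        fit = sm.Logit(y, np.column_stack([np.ones(300), scores])).fit(disp=0)
        assert out["beta"] == pytest.approx(fit.params[1], rel=1e-6)
        assert out["se"] == pytest.approx(fit.bse[1], rel=1e-5)

    def test_matched_matches_statsmodels_conditional_logit(self):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(8)
        n_strata = 150
        case_scores = rng.normal(0.3, 1.0, n_strata)
        pseudo = rng.normal(0.0, 1.0, (n_strata, 3))
        out = prs_association(case_scores, pseudo_scores=pseudo)
        # expanded representation for statsmodels
        ys, xs, gs = [], [], []
        for s in range(n_strata):
            ys += [1, 0, 0, 0]
            xs += [case_scores[s], *pseudo[s]]
            gs += [s] * 4
        fit = ConditionalLogit(np.array(ys), np.array(xs)[:, None],
                               groups=np.array(gs)).fit(disp=0)
        # statsmodels' default optimizer converges less tightly than the
        # Newton solver here
        assert out["beta"] == pytest.approx(fit.params[0], rel=1e-3)
        assert out["se"] == pytest.approx(fit.bse[0], rel=1e-3)

    def test_predictive_score_power_single_run(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=800)
        eta = -0.5 + scores
        y = (rng.random(800) < 1 / (1 + np.exp(-eta))).astype(int)
        out = prs_association(scores, y)
        assert out["p"] < 1e-4
        assert 0 < out["r2_nagelkerke"] < 1

    def test_null_score_calibration_small(self):
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200):
            scores = rng.normal(size=200)
            y = rng.integers(0, 2, size=200)
            pvals.append(prs_association(scores, y)["p"])
        frac = np.mean(np.array(pvals) <= 0.05)
        assert 0.02 <= frac <= 0.09


class TestNagelkerke:
    def test_bounds(self):
        assert 0.0 <= nagelkerke_r2(-100.0, -50.0, 100) < 1.0

    def test_zero_iff_no_improvement(self):
        assert nagelkerke_r2(-70.0, -70.0, 100) == 0.0


def trio_panel_df(trios, weights, risk_alleles=None):
    n = trios.n_variants
    return pd.DataFrame(
        {
            "snp": [v.id for v in trios.variants],
            "chr": "1",
            "pos": [v.pos for v in trios.variants],
            "risk_allele": risk_alleles if risk_alleles is not None
            else [v.alt for v in trios.variants],
            "log_rr": weights,
        }
    )


class TestTrioTransmissionScore:
    def test_homozygous_parents_zero_difference(self):
        trios = TrioCohort(
            child=np.array([[1, 2], [1, 0]]),
            father=np.array([[2, 2], [2, 0]]),
            mother=np.array([[0, 2], [0, 0]]),
            variants=[
                VariantRecord(id=f"v{j}", chrom="1", pos=(j + 1) * 100,
                              ref="A", alt="G") for j in range(2)
            ],
        )
        panel = trio_panel_df(trios, [0.3, 0.2])
        res = trio_transmission_score(trios, panel)
        np.testing.assert_allclose(res.difference, 0.0)

    def test_antisymmetry_under_label_swap(self, independent_panel):
        trios = sc.simulate_trios(independent_panel, sc.RiskModel.null(0.05),
                                  300, seed=50)
        weights = np.random.default_rng(51).normal(0, 0.2, trios.n_variants)
        panel = trio_panel_df(trios, weights)
        res = trio_transmission_score(trios, panel)
        swapped = TrioCohort(
            child=trios.nontransmitted(), father=trios.father,
            mother=trios.mother, variants=trios.variants,
        )
        res_swapped = trio_transmission_score(swapped, panel)
        np.testing.assert_allclose(res_swapped.difference, -res.difference,
                                   atol=1e-10)

    def test_shared_etiology_positive_difference(self, independent_panel):
        idx = np.arange(0, 24)
        log_rr = np.random.default_rng(52).uniform(np.log(1.3), np.log(1.8), 24)
        model = sc.RiskModel(idx, log_rr, 0.05)
        trios = sc.simulate_trios(independent_panel, model, 1500, seed=53)
        panel = trio_panel_df(trios, np.zeros(trios.n_variants))
        panel = panel.iloc[idx].copy()
        panel["log_rr"] = log_rr
        res = trio_transmission_score(trios, panel)
        assert res.mean_difference > 0
        assert res.p_value < 0.05

    def test_independent_trait_null(self, independent_panel):
        # trait driven by variants 50..73; scored panel is variants 0..23
        idx_true = np.arange(50, 74)
        log_rr = np.random.default_rng(54).uniform(np.log(1.2), np.log(1.5), 24)
        model = sc.RiskModel(idx_true, log_rr, 0.05)
        trios = sc.simulate_trios(independent_panel, model, 800, seed=55)
        panel = trio_panel_df(trios, np.zeros(trios.n_variants)).iloc[:24].copy()
        panel["log_rr"] = np.random.default_rng(56).uniform(0.1, 0.4, 24)
        res = trio_transmission_score(trios, panel)
        bound = 3 * res.sd_difference / np.sqrt(res.n_trios)
        assert abs(res.mean_difference) < bound

    def test_risk_allele_on_ref_strand_oriented(self):
        trios = TrioCohort(
            child=np.array([[2]]), father=np.array([[1]]), mother=np.array([[1]]),
            variants=[VariantRecord(id="v0", chrom="1", pos=100, ref="A", alt="G")],
        )
        panel_alt = trio_panel_df(trios, [0.5], risk_alleles=["G"])
        panel_ref = trio_panel_df(trios, [0.5], risk_alleles=["A"])
        res_alt = trio_transmission_score(trios, panel_alt)
        res_ref = trio_transmission_score(trios, panel_ref)
        assert res_alt.difference[0] == pytest.approx(-res_ref.difference[0])


class TestVarianceExplained:
    def test_null_panel_near_zero(self, independent_panel):
        cohort = sc.simulate_case_control(
            independent_panel, sc.RiskModel.null(0.05), 2000, 2000, seed=60
        )
        out = variance_explained_loci(cohort, np.arange(24), prevalence=0.05)
        assert out["r2_nagelkerke"] < 0.01

    def test_duplicate_panel_member_handled(self, independent_panel):
        cohort = sc.simulate_case_control(
            independent_panel, sc.RiskModel.null(0.05), 500, 500, seed=61
        )
        base = variance_explained_loci(cohort, np.arange(5), prevalence=0.05)
        dup = variance_explained_loci(cohort, np.array([0, 1, 2, 3, 4, 4]),
                                      prevalence=0.05)
        assert dup["r2_nagelkerke"] == pytest.approx(base["r2_nagelkerke"], abs=1e-9)
        assert dup["collinear_dropped"] == [4]

    def test_liability_recovery_small(self):
        # scaled-down version of the acceptance parameter-recovery experiment
        vals = []
        for rep in range(5):
            panel = sc.simulate_panel(400, 24, (0.1, 0.5), 1, 0.0, seed=rep)
            cohort, _ = sc.simulate_liability_case_control(
                panel, np.arange(24), 0.25, 0.001, 800, 800, seed=100 + rep
            )
            out = variance_explained_loci(cohort, np.arange(24), prevalence=0.001)
            vals.append(out["r2_liability"])
        assert abs(np.mean(vals) - 0.25) < 0.07

    def test_liability_conversion_bounds(self):
        with pytest.raises(ValueError):
            liability_scale_r2(0.1, 0.0, 0.5)
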