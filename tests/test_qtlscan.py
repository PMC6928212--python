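"""Genome-scan correctness: genotype probabilities, TS, thresholds, anchoring."""

import numpy as np
import pandas as pd
import pytest

import oracles
from protqtl import (
    GeneticMap,
    QTLLocus,
    QTLModel,
    QTLScanner,
    anchored_scan,
    genotype_probabilities,
    permutation_threshold,
    scan,
    simulate_phenotypes,
    simulate_ril_population,
    uniform_map,
    variance_explained,
)
from protqtl.qtlscan import _dosage_at
from protqtl.simstudy import single_qtl_recovery


def _two_marker_map(d_cm):
    t = pd.DataFrame({"marker": ["a", "b"], "chrom": "c1", "cm": [0.0, d_cm]})
    return GeneticMap(t)


class TestGenotypeProbabilities:
    def test_point_mass_at_observed_markers(self, ril_small):
        gp = genotype_probabilities(ril_small, step_cm=5.0)
        gmap = ril_small.gmap
        for j, marker in enumerate(gmap.marker_names[:20]):
            row = gmap.table.iloc[j]
            k = gp.point_index(row["chrom"], row["cm"])
            for i in range(0, ril_small.n_lines, 25):
                code = ril_small.codes[i, j]
                if code == -1:
                    continue
                assert gp.probs[i, k, code] == 1.0
                assert gp.dosage[i, k] == float(code) - 1.0

    def test_probabilities_sum_to_one(self, ril_small):
        gp = genotype_probabilities(ril_small, step_cm=2.0)
        assert np.allclose(gp.probs.sum(axis=2), 1.0)

    def test_uninformative_line_gets_ril_prior(self, small_map):
        ril = simulate_ril_population(small_map, 10, 5, seed=1)
        ril.codes[0, :] = -1  # wipe one line entirely
        gp = genotype_probabilities(ril, step_cm=10.0)
        h = ril.expected_heterozygosity()
        assert np.allclose(gp.probs[0, :, 1], h)
        assert np.allclose(gp.probs[0, :, 0], (1 - h) / 2)
        assert np.allclose(gp.dosage[0], 0.0)

    def test_midpoint_between_opposite_flanks_matches_ssd_enumeration(self):
        """P(state | A...B flanks, 20 cM apart) vs exact 3-locus SSD
        enumeration near fixation (the scan's fully-inbred approximation)."""
        d = 20.0
        r = oracles.haldane(d / 2)
        cond = oracles.conditional_middle_prob(r, r, generations=18,
                                               left_code=0, right_code=2)
        gmap = GeneticMap(pd.DataFrame(
            {"marker": ["a", "b"], "chrom": "c1", "cm": [0.0, d]}
        ))
        codes = np.array([[0, 2]], dtype=np.int8)
        from protqtl import RILGenotypes

        ril = RILGenotypes(codes=codes, lines=["L1"], gmap=gmap, generation=8)
        gp = genotype_probabilities(ril, step_cm=d / 2)
        k = gp.point_index("c1", d / 2)
        # by symmetry P(A) = P(B) exactly
        assert gp.probs[0, k, 0] == pytest.approx(gp.probs[0, k, 2])
        # two-state Markov value vs enumeration (hom states renormalized)
        p_hom = cond[0] + cond[2]
        assert gp.probs[0, k, 2] == pytest.approx(cond[2] / p_hom, abs=0.02)

    def test_heterozygous_flank_is_marginalized(self):
        # an H call between two A calls must not drag the dosage off -1 side
        gmap = GeneticMap(pd.DataFrame(
            {"marker": list("abc"), "chrom": "c1", "cm": [0.0, 10.0, 20.0]}
        ))
        from protqtl import RILGenotypes

        ril = RILGenotypes(np.array([[0, 1, 0]], dtype=np.int8), ["L1"], gmap)
        gp = genotype_probabilities(ril, step_cm=5.0)
        k = gp.point_index("c1", 5.0)
        assert gp.dosage[0, k] < -0.8
        # but the observed H marker itself stays a point mass
        kh = gp.point_index("c1", 10.0)
        assert gp.probs[0, kh, 1] == 1.0

    def test_rejects_nonpositive_step(self, ril_small):
        with pytest.raises(ValueError):
            genotype_probabilities(ril_small, step_cm=0.0)


class TestScan:
    def test_ts_at_marker_equals_single_marker_regression(
        self, ril_small, major_qtl_phenotypes
    ):
        res = scan(ril_small, major_qtl_phenotypes, mode="SIM", step_cm=2.0)
        y = major_qtl_phenotypes.line_means().to_numpy()
        n = len(y)
        gmap = ril_small.gmap
        for j in [0, 4, 22, 40]:
            row = gmap.table.iloc[j]
            # oracle: plain regression statistic at the marker itself
            x = ril_small.marker_dosage(row["marker"])
            if np.all(ril_small.codes[:, j] != -1):
                r2 = np.corrcoef(x, y)[0, 1] ** 2
                expected = -n * np.log(1 - r2)
                k = (res.grid["chrom"] == row["chrom"]) & (
                    np.abs(res.grid["cm"] - row["cm"]) < 1e-9
                )
                assert res.statistic[k.to_numpy()][0] == pytest.approx(expected, rel=1e-9)

    def test_major_qtl_produces_single_declared_peak(
        self, ril_small, major_qtl_phenotypes
    ):
        thr = permutation_threshold(
            ril_small, major_qtl_phenotypes, n_permutations=300, seed=4
        )
        res = scan(ril_small, major_qtl_phenotypes, threshold=thr)
        assert len(res.peaks) >= 1
        best = res.peaks.loc[res.peaks["ts"].idxmax()]
        assert best["chrom"] == "Gm01"
        assert 0.4 < best["r2"] < 0.8

    def test_affine_phenotype_invariance(self, ril_small, major_qtl_phenotypes):
        y = major_qtl_phenotypes.line_means()
        a = scan(ril_small, y)
        b = scan(ril_small, 3.5 * y - 40.0)
        assert np.allclose(a.statistic, b.statistic)

    def test_scim_with_no_cofactors_equals_sim(self, ril_small, major_qtl_phenotypes):
        a = scan(ril_small, major_qtl_phenotypes, mode="SIM")
        b = scan(ril_small, major_qtl_phenotypes, mode="sCIM", cofactors=None)
        assert np.array_equal(a.statistic, b.statistic)

    def test_scim_with_cofactors_controls_background(self, ril_small, major_qtl_phenotypes):
        res = scan(ril_small, major_qtl_phenotypes, mode="sCIM", cofactors="auto")
        assert res.statistic.min() >= 0.0
        k = int(np.argmax(res.statistic))
        assert res.grid["chrom"].iloc[k] == "Gm01"

    def test_constant_phenotype_warns_and_zeroes(self, ril_small):
        y = pd.Series(1.0, index=ril_small.lines)
        with pytest.warns(UserWarning, match="constant"):
            res = scan(ril_small, y)
        assert np.all(res.statistic == 0)

    def test_statistic_nonnegative(self, ril_small, null_phenotypes):
        res = scan(ril_small, null_phenotypes)
        assert res.statistic.min() >= 0.0


class TestPermutationThreshold:
    def test_threshold_is_order_statistic(self, ril_small, null_phenotypes):
        thr, null = permutation_threshold(
            ril_small, null_phenotypes, n_permutations=200, alpha=0.05,
            seed=8, return_null=True,
        )
        assert thr == np.sort(null)[int(np.ceil(0.95 * 200)) - 1]

    def test_alpha_one_gives_minimum_of_null_maxima(self, ril_small, null_phenotypes):
        thr, null = permutation_threshold(
            ril_small, null_phenotypes, n_permutations=150, alpha=1.0,
            seed=8, return_null=True,
        )
        assert thr == null.min()

    def test_threshold_monotone_in_alpha(self, ril_small, null_phenotypes):
        t01 = permutation_threshold(ril_small, null_phenotypes,
                                    n_permutations=300, alpha=0.01, seed=5)
        t05 = permutation_threshold(ril_small, null_phenotypes,
                                    n_permutations=300, alpha=0.05, seed=5)
        assert t01 >= t05

    def test_too_few_permutations_rejected(self, ril_small, null_phenotypes):
        with pytest.raises(ValueError):
            permutation_threshold(ril_small, null_phenotypes, n_permutations=50)

    def test_small_population_warns(self, small_map):
        ril = simulate_ril_population(small_map, 10, 5, seed=2)
        model = QTLModel(loci=[], residual_sd=1.0)
        ph = simulate_phenotypes(ril, model, n_trials=2, seed=3)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_threshold(ril, ph, n_permutations=100, seed=1)


class TestVarianceExplained:
    def test_equals_squared_pearson_correlation(self, ril_small, major_qtl_phenotypes):
        gmap = ril_small.gmap
        row = gmap.table.iloc[13]
        r2 = variance_explained(
            ril_small, major_qtl_phenotypes, (row["chrom"], float(row["cm"]))
        )
        x = _dosage_at(ril_small, row["chrom"], float(row["cm"]))
        y = major_qtl_phenotypes.line_means().to_numpy()
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_null_position_near_zero(self, ril_small, major_qtl_phenotypes):
        # a marker on an unlinked chromosome explains ~nothing
        r2 = variance_explained(ril_small, major_qtl_phenotypes, ("Gm05", 40.0))
        assert r2 < 0.1


@pytest.fixture(scope="module")
def interaction_data():
    gmap = uniform_map(6, 9, 80.0)
    cm = lambda c: float(gmap.chrom_table(c)["cm"].iloc[4])
    from protqtl import EpistaticPair

    model = QTLModel(
        loci=[QTLLocus("Gm01", cm("Gm01")), QTLLocus("Gm05", cm("Gm05"))],
        epistatic_pairs=[EpistaticPair(0, 1, variance_fraction=0.25)],
        target_variance_fractions=[0.45, 0.0],
    )
    ril = simulate_ril_population(gmap, 150, 5, seed=71)
    ph = simulate_phenotypes(ril, model, n_trials=3, seed=72)
    return gmap, ril, ph, ("Gm01", cm("Gm01")), cm("Gm05")


class TestAnchoredScan:
    def test_interaction_ts_peaks_at_interacting_locus(self, interaction_data):
        gmap, ril, ph, anchor, cm5 = interaction_data
        res = anchored_scan(ril, ph, anchor=anchor, step_cm=2.0)
        k = int(np.argmax(res.interaction_ts))
        assert res.grid["chrom"].iloc[k] == "Gm05"
        assert abs(res.grid["cm"].iloc[k] - cm5) <= 10.0

    def test_no_epistasis_keeps_interaction_ts_low(self, ril_small, major_qtl_phenotypes):
        anchor = ("Gm01", 40.0)
        res = anchored_scan(ril_small, major_qtl_phenotypes, anchor=anchor, step_cm=2.0)
        # null interaction profile: nothing approaching the additive signal
        a = scan(ril_small, major_qtl_phenotypes, step_cm=2.0)
        assert res.interaction_ts.max() < 0.5 * a.statistic.max()

    def test_additive_ts_matches_unanchored_for_independent_locus(self):
        gmap = uniform_map(4, 9, 80.0)
        cm = lambda c: float(gmap.chrom_table(c)["cm"].iloc[4])
        model = QTLModel(
            loci=[QTLLocus("Gm01", cm("Gm01")), QTLLocus("Gm03", cm("Gm03"))],
            target_variance_fractions=[0.5, 0.25],
        )
        ril = simulate_ril_population(gmap, 200, 5, seed=81)
        ph = simulate_phenotypes(ril, model, n_trials=3, seed=82)
        anchored = anchored_scan(ril, ph, anchor=("Gm01", cm("Gm01")), step_cm=2.0)
        # oracle: scanning the anchor-adjusted phenotype reproduces the
        # anchored additive profile when the loci are unlinked
        y = ph.line_means()
        a = _dosage_at(ril, "Gm01", cm("Gm01"))
        A = np.column_stack([np.ones(len(y)), a])
        beta, *_ = np.linalg.lstsq(A, y.to_numpy(), rcond=None)
        resid = pd.Series(y.to_numpy() - A @ beta, index=y.index)
        plain = scan(ril, resid, step_cm=2.0)
        m = (plain.grid["chrom"] == "Gm03").to_numpy()
        k = np.flatnonzero(m)[np.argmax(plain.statistic[m])]
        assert anchored.additive_ts[k] == pytest.approx(plain.statistic[k], rel=0.02)
        off = ~anchored.excluded
        assert np.max(np.abs(anchored.additive_ts[off] - plain.statistic[off])) < 1.0
        # and the unanchored scan still finds the second locus on Gm03
        full = scan(ril, ph, step_cm=2.0)
        k2 = int(np.argmax(np.where(m, full.statistic, 0)))
        assert abs(full.grid["cm"].iloc[k2] - cm("Gm03")) <= 10.0

    def test_anchor_window_excluded_and_constant_anchor_rejected(
        self, ril_small, major_qtl_phenotypes
    ):
        res = anchored_scan(ril_small, major_qtl_phenotypes, anchor=("Gm01", 40.0))
        inside = res.excluded
        assert inside.any()
        assert np.all(res.additive_ts[inside] == 0)
        ril = simulate_ril_population(ril_small.gmap, 30, 5, seed=3)
        ril.codes[:, :] = 0  # degenerate: population fixed everywhere
        ph = pd.Series(np.random.default_rng(0).normal(size=30), index=ril.lines)
        with pytest.raises(ValueError, match="constant"):
            anchored_scan(ril, ph, anchor=("Gm01", 40.0))


class TestQTLScannerEstimator:
    def test_sklearn_params_roundtrip(self):
        s = QTLScanner(mode="sCIM", n_permutations=200, alpha=0.1)
        params = s.get_params()
        s2 = QTLScanner(**params)
        assert s2.get_params() == params
        s2.set_params(alpha=0.02)
        assert s2.alpha == 0.02

    def test_fit_sets_profile_threshold_and_peaks(self, ril_small, major_qtl_phenotypes):
        s = QTLScanner(n_permutations=200, random_state=3).fit(
            ril_small, major_qtl_phenotypes
        )
        assert s.threshold_ > 0
        assert (s.peaks_["ts"] >= s.threshold_).all()
        assert ((s.peaks_["r2"] >= 0) & (s.peaks_["r2"] <= 1)).all()

    def test_position_recovery_over_replicates(self):
        out = single_qtl_recovery(n_reps=25, n_lines=100, seed=3)
        assert out["median_position_error_cm"] <= 5.0
        assert out["fraction_on_true_chromosome"] > 0.9
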