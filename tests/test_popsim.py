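"""Simulator correctness: panels, descent, RIL meiosis, phenotypes."""

import numpy as np
import pandas as pd
import pytest

import oracles
from protqtl import (
    EpistaticPair,
    QTLLocus,
    QTLModel,
    demo_pedigree,
    ril_recombination,
    haldane_r,
    simulate_descent,
    simulate_panel,
    simulate_phenotypes,
    simulate_ril_population,
    soybean_skeleton_map,
    uniform_map,
)
from protqtl.popsim import five_locus_protein_model


# ---------------------------------------------------------------------------
# diversity panel


class TestSimulatePanel:
    def test_panel_dimensions_match_full_gbs_scale(self):
        # 300 varieties x 155,616 SNPs, GBS-panel scale, on 20 chromosomes
        gmap = uniform_map(20, 5, 100.0)
        densities = [7781] * 16 + [7780] * 4
        assert sum(densities) == 155616
        panel = simulate_panel(
            300, gmap, snp_density=densities, donor_rare_config=(0, 0.0), seed=5
        )
        assert panel.calls.shape == (300, 155616)

    def test_no_injection_leaves_no_designated_rare_snps(self, small_map):
        panel = simulate_panel(
            60, small_map, snp_density=200, donor_rare_config=(0, 0.0), seed=1
        )
        assert panel.meta["rare_snp_ids"] == []
        # alt frequencies follow the maf distribution, mean ~ (0.01+0.5)/2
        assert abs(np.nanmean(panel.alt_frequency()) - 0.255) < 0.02

    def test_rare_allele_carrier_count_matches_binomial_expectation(self, small_map):
        # E[#carrier lines] = 1 (donor) + (n-1) q with q = (f n - 1)/(n - 1)
        n, f = 300, 2 / 300
        panel = simulate_panel(
            n, small_map, snp_density=400, donor_rare_config=(150, f), seed=7,
            het_rate=0.0, missing_rate=0.0,
        )
        cols = panel.snps["snp"].isin(panel.meta["rare_snp_ids"]).to_numpy()
        carriers = (panel.calls[:, cols] == 2).sum(axis=0)
        expected = f * n
        q = (f * n - 1) / (n - 1)
        se = np.sqrt((n - 1) * q * (1 - q) / 150)
        assert abs(carriers.mean() - expected) < 3 * se + 1e-9
        # donor itself is always a carrier
        assert (panel.calls[0, cols] == 2).all()

    def test_impossible_rare_frequency_rejected(self, small_map):
        with pytest.raises(ValueError, match="less than one line"):
            simulate_panel(60, small_map, snp_density=50,
                           donor_rare_config=(10, 1 / 100), seed=1)

    def test_deterministic_given_seed(self, small_map):
        a = simulate_panel(30, small_map, snp_density=50, donor_rare_config=(5, 1 / 30), seed=3)
        b = simulate_panel(30, small_map, snp_density=50, donor_rare_config=(5, 1 / 30), seed=3)
        c = simulate_panel(30, small_map, snp_density=50, donor_rare_config=(5, 1 / 30), seed=4)
        assert a == b
        assert not (a == c)


# ---------------------------------------------------------------------------
# pedigree descent


@pytest.fixture(scope="module")
def panel(small_map):
    return simulate_panel(
        100, small_map, snp_density=200, donor_rare_config=(40, 1 / 100),
        seed=21, line_names=None, donor="donor",
    )


class TestSimulateDescent:
    def test_seven_derivatives_appended(self, panel):
        ped = demo_pedigree(7)
        # recurrent/low lines must exist in the panel under those names
        panel2 = _with_roles(panel, ped)
        out = simulate_descent(panel2, ped, [("Gm01", 1, 2_000_000)], 0.2, seed=2)
        assert out.n_lines == panel2.n_lines + 7
        assert out.lines[-7:] == ped.derivatives

    def test_whole_genome_blocks_reproduce_donor(self, panel):
        ped = demo_pedigree(3)
        panel2 = _with_roles(panel, ped)
        blocks = [(c, 1, 10**9) for c in panel2.snps["chrom"].unique()]
        out = simulate_descent(panel2, ped, blocks, 0.0, seed=3)
        donor = out.line_calls("donor")
        for d in ped.derivatives:
            assert np.array_equal(out.line_calls(d), donor)

    def test_outside_block_retention_matches_probability(self, panel):
        # Monte-Carlo oracle: donor-origin fraction at SNPs that distinguish
        # donor from recurrent approximates the retention probability
        ped = demo_pedigree(7)
        panel2 = _with_roles(panel, ped)
        donor = panel2.line_calls("donor")
        recurrent = panel2.line_calls("recurrent")
        informative = (donor != recurrent) & (donor != -1) & (recurrent != -1)
        fracs = []
        rng = np.random.default_rng(0)
        for _ in range(150):  # 150 x 7 = 1050 derivative draws
            out = simulate_descent(panel2, ped, [], 0.5, seed=int(rng.integers(2**31)))
            for d in ped.derivatives:
                calls = out.line_calls(d)[informative]
                fracs.append((calls == donor[informative]).mean())
        assert abs(np.mean(fracs) - 0.5) < 0.03

    def test_block_off_chromosome_rejected(self, panel):
        ped = demo_pedigree(2)
        panel2 = _with_roles(panel, ped)
        with pytest.raises(ValueError, match="unknown chromosome"):
            simulate_descent(panel2, ped, [("GmXX", 1, 100)], 0.1, seed=1)


def _with_roles(panel, ped):
    """Rename panel lines so the pedigree's roles exist in the panel."""
    names = list(panel.lines)
    names[1] = ped.recurrent_parent
    for k, low in enumerate(ped.low_protein_contrast_lines):
        names[2 + k] = low
    out = type(panel)(calls=panel.calls.copy(), lines=names, snps=panel.snps.copy())
    out.meta = dict(panel.meta)
    return out


# ---------------------------------------------------------------------------
# RIL populations


class TestSimulateRIL:
    def test_dimensions_on_skeleton_map(self):
        gmap = soybean_skeleton_map()
        ril = simulate_ril_population(gmap, 100, 5, seed=1)
        assert ril.codes.shape == (100, gmap.n_markers)

    def test_cosited_markers_are_identical_columns(self):
        t = pd.DataFrame(
            {"marker": ["m1", "m2", "m3"], "chrom": "c1", "cm": [0.0, 10.0, 10.0]}
        )
        from protqtl import GeneticMap

        ril = simulate_ril_population(GeneticMap(t), 500, 5, seed=2)
        assert np.array_equal(ril.codes[:, 1], ril.codes[:, 2])

    def test_residual_heterozygosity_matches_generation(self):
        gmap = uniform_map(2, 5, 100.0)
        for gen, h in [(2, 0.5), (5, 0.0625), (6, 0.03125)]:
            ril = simulate_ril_population(gmap, 3000, gen, seed=gen)
            obs = (ril.codes == 1).mean()
            se = np.sqrt(h * (1 - h) / ril.codes.size)
            # markers within a line are correlated; allow a generous multiple
            assert abs(obs - h) < 6 * se + 0.005

    @pytest.mark.parametrize("d_cm", [1.0, 5.0, 10.0, 20.0, 50.0])
    def test_recombination_matches_ssd_enumeration(self, d_cm):
        """Observed 2-marker recombinant fraction vs the exact SSD oracle
        and the closed form R = 2r/(1+2r) at fixation."""
        t = pd.DataFrame({"marker": ["a", "b"], "chrom": "c1", "cm": [0.0, d_cm]})
        from protqtl import GeneticMap

        gen = 6
        ril = simulate_ril_population(GeneticMap(t), 8000, gen, seed=int(d_cm))
        hom = (ril.codes != 1).all(axis=1)
        rec_obs = (ril.codes[hom, 0] != ril.codes[hom, 1]).mean()

        r = oracles.haldane(d_cm)
        dist = oracles.genotype_distribution((r,), gen)
        p_hom = sum(p for c, p in dist.items() if 1 not in c)
        p_rec = sum(p for c, p in dist.items() if 1 not in c and c[0] != c[1])
        rec_oracle = p_rec / p_hom
        se = np.sqrt(rec_oracle * (1 - rec_oracle) / hom.sum())
        assert abs(rec_obs - rec_oracle) < 4 * se
        # at (near) fixation the enumeration converges to R = 2r/(1+2r)
        dist_fix = oracles.genotype_distribution((r,), 16)
        p_hom = sum(p for c, p in dist_fix.items() if 1 not in c)
        p_rec = sum(p for c, p in dist_fix.items() if 1 not in c and c[0] != c[1])
        assert abs(p_rec / p_hom - ril_recombination(r)) < 2e-3

    def test_rejects_degenerate_sizes(self, small_map):
        with pytest.raises(ValueError):
            simulate_ril_population(small_map, 1, 5, seed=1)
        with pytest.raises(ValueError):
            simulate_ril_population(small_map, 10, 1, seed=1)

    def test_bit_reproducible_and_seed_sensitive(self, small_map):
        a = simulate_ril_population(small_map, 50, 5, seed=9)
        b = simulate_ril_population(small_map, 50, 5, seed=9)
        c = simulate_ril_population(small_map, 50, 5, seed=10)
        assert np.array_equal(a.codes, b.codes)
        assert not np.array_equal(a.codes, c.codes)


# ---------------------------------------------------------------------------
# phenotypes


class TestSimulatePhenotypes:
    def test_null_model_variance_is_noise_only(self, ril_small):
        model = QTLModel(loci=[], residual_sd=2.0, trial_effect_sd=1.0)
        reps = [
            simulate_phenotypes(ril_small, model, n_trials=4, seed=s)
            .line_means().var(ddof=1)
            for s in range(30)
        ]
        # balanced trials: trial effects shift all lines equally, so the
        # between-line variance is residual^2 / n_trials
        assert abs(np.mean(reps) - 4.0 / 4) < 0.1

    def test_single_locus_closed_form_r2(self, small_map):
        # R^2 -> a^2 var(x) / (a^2 var(x) + sigma^2) = target fraction
        ril = simulate_ril_population(small_map, 4000, 5, seed=31)
        cm = float(small_map.chrom_table("Gm02")["cm"].iloc[4])
        model = QTLModel(
            loci=[QTLLocus("Gm02", cm)], target_variance_fractions=[0.5]
        )
        ph = simulate_phenotypes(ril, model, n_trials=3, seed=32)
        y = ph.line_means().to_numpy()
        x = ril.marker_dosage(ph.meta["causal_markers"][0])
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert abs(r2 - 0.5) < 0.03

    def test_realized_marginal_fractions_hit_targets(self, small_map):
        targets = [0.4, 0.2]
        loci = [
            QTLLocus("Gm01", float(small_map.chrom_table("Gm01")["cm"].iloc[4])),
            QTLLocus("Gm03", float(small_map.chrom_table("Gm03")["cm"].iloc[4])),
        ]
        model = QTLModel(loci=loci, target_variance_fractions=targets)
        rng = np.random.default_rng(5)
        est = np.zeros(2)
        n_reps = 60
        for _ in range(n_reps):
            ril = simulate_ril_population(small_map, 100, 5, seed=int(rng.integers(2**31)))
            ph = simulate_phenotypes(ril, model, n_trials=3, seed=int(rng.integers(2**31)))
            y = ph.line_means().to_numpy()
            for k, m in enumerate(ph.meta["causal_markers"]):
                est[k] += np.corrcoef(ril.marker_dosage(m), y)[0, 1] ** 2
        est /= n_reps
        assert np.allclose(est, targets, atol=0.03)

    def test_overcommitted_variance_rejected(self):
        # the printed five single-locus fractions (0.60/0.23/0.14/0.13/0.01)
        # cannot coexist as simultaneous truths: they sum beyond 1
        with pytest.raises(ValueError, match="sum"):
            QTLModel(
                loci=[QTLLocus("Gm01", 0.0)] * 5,
                target_variance_fractions=[0.60, 0.23, 0.14, 0.13, 0.01],
            )

    def test_five_locus_model_is_feasible_and_scaled(self, small_map):
        gmap = uniform_map(20, 9, 80.0)
        model = five_locus_protein_model(gmap)
        assert model.total_target_fraction() == pytest.approx(0.70)
        # relative weights preserved: chr20 : chr15 = 60 : 23
        f = model.target_variance_fractions
        assert f[0] / f[1] == pytest.approx(60 / 23)

    def test_epistatic_variance_target(self, small_map):
        cm1 = float(small_map.chrom_table("Gm01")["cm"].iloc[4])
        cm2 = float(small_map.chrom_table("Gm04")["cm"].iloc[4])
        model = QTLModel(
            loci=[QTLLocus("Gm01", cm1), QTLLocus("Gm04", cm2)],
            epistatic_pairs=[EpistaticPair(0, 1, variance_fraction=0.3)],
            target_variance_fractions=[0.0, 0.0],
        )
        ril = simulate_ril_population(small_map, 3000, 5, seed=41)
        ph = simulate_phenotypes(ril, model, n_trials=3, seed=42)
        y = ph.line_means().to_numpy()
        x = ril.marker_dosage(ph.meta["causal_markers"][0]) * ril.marker_dosage(
            ph.meta["causal_markers"][1]
        )
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert abs(r2 - 0.3) < 0.03
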