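"""SNV density windows, allele of residence, spectra, lost CpGs, profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asmtrio import variant_context as vc
from asmtrio import simulate as sim


def sites(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions})


class TestWindowDensity:
    def test_single_window_arithmetic(self):
        asm_sites = sites([10_000])
        controls = sites([50_000, 60_000])
        variants = pd.DataFrame(
            {"chrom": "chr1", "pos": [9_800, 10_300, 50_100],
             "ref": "A", "alt": "G"}
        )
        res = vc.window_snv_density(asm_sites, controls, variants, window_bp=500,
                                    n_bootstrap=100, n_permutations=100, seed=0)
        assert res.density_asm == pytest.approx(2 / 1.001, rel=1e-9)
        assert res.density_control == pytest.approx(1 / 2.002, rel=1e-9)
        assert res.fold == pytest.approx(4.0, rel=1e-9)

    def test_null_fold_ci_contains_one(self):
        cfg = sim.SimConfig(
            genome_length=500_000, n_chromosomes=2, n_asm_sites=100, n_bulk_sites=300,
            snv_enrichment_fold=1.0, het_snv_rate=2.0, seed=8,
        )
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        res = vc.window_snv_density(
            truth.asm_sites[["chrom", "pos"]], truth.bulk_sites[["chrom", "pos"]],
            truth.variants, seed=1,
        )
        assert res.ci_low <= 1.0 <= res.ci_high
        assert res.empirical_p > 0.05

    def test_empty_controls_flagged(self):
        res = vc.window_snv_density(
            sites([1000]), sites([]), pd.DataFrame({"chrom": [], "pos": []}),
            n_bootstrap=10, n_permutations=10,
        )
        assert np.isnan(res.fold)


class TestMatchControls:
    def test_controls_match_coverage_distribution(self):
        rng = np.random.default_rng(0)
        asm_sites = sites(np.arange(100) * 1000 + 500)
        bulk = sites(np.arange(2000) * 400 + 37)
        coverage = {("chr1", int(p)): float(rng.poisson(30)) for p in asm_sites["pos"]}
        coverage.update(
            {("chr1", int(p)): float(rng.poisson(30)) for p in bulk["pos"]}
        )
        controls = vc.match_controls(
            asm_sites, bulk, k_per_site=2, coverage=coverage, seed=1
        )
        assert len(controls) == 200
        a_cov = [coverage[("chr1", int(p))] for p in asm_sites["pos"]]
        c_cov = [coverage[("chr1", int(p))] for p in controls["pos"]]
        assert stats.ks_2samp(a_cov, c_cov).pvalue > 0.05

    def test_singleton_strata_deterministic(self):
        asm_sites = sites([100])
        bulk = sites([500])
        out = vc.match_controls(asm_sites, bulk, k_per_site=1, seed=5)
        assert out["pos"].tolist() == [500]


class TestAlleleResidence:
    def test_bias_recovered_from_generator(self):
        cfg = sim.SimConfig(
            genome_length=1_000_000, n_chromosomes=3, n_asm_sites=300, n_bulk_sites=50,
            hypo_allele_bias=0.9, het_snv_rate=2.0, seed=9,
        )
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        calls = truth.asm_sites[["chrom", "pos", "hypo_hap"]]
        out = vc.allele_of_residence(calls, truth.variants, window_bp=500)
        assert out["hypo_share"] == pytest.approx(0.9, abs=0.04)

    def test_no_variants_gives_undefined_ratio(self):
        calls = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "hypo_hap": ["H1"]})
        variants = pd.DataFrame({"chrom": [], "pos": [], "hap_of_alt": []})
        out = vc.allele_of_residence(calls, variants)
        assert out["hypo_allele_snvs"] == 0 and np.isnan(out["hypo_share"])


class TestSpectrum:
    def test_single_variant(self):
        s = vc.substitution_spectrum(pd.DataFrame({"ref": ["C"], "alt": ["T"]}))
        assert s["C>T"] == 1.0 and s.drop("C>T").sum() == 0.0

    def test_uniform_mutation_matrix_flat(self):
        rng = np.random.default_rng(1)
        refs = rng.choice(list("ACGT"), 12_000)
        alts = [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
        s = vc.substitution_spectrum(pd.DataFrame({"ref": refs, "alt": alts}))
        assert np.allclose(s.values, 1 / 12, atol=0.02)

    def test_normalization_and_empty(self, demo_truth):
        s = vc.substitution_spectrum(demo_truth.variants)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        empty = vc.substitution_spectrum(demo_truth.variants.iloc[:0])
        assert empty.sum() == 0.0 and empty.attrs["n"] == 0


def build_reference(seq: str):
    arr = np.array(list(seq), dtype="U1")
    cg = np.flatnonzero((arr[:-1] == "C") & (arr[1:] == "G"))
    return sim.Reference(chroms={"chr1": arr}, cpg_sites={"chr1": cg})


class TestLostCpg:
    def test_het_substitution_at_c_loses_one_allele(self):
        ref = build_reference("AACGTT")
        out = vc.detect_lost_cpg(ref, pd.DataFrame(
            {"chrom": ["chr1"], "pos": [2], "ref": ["C"], "alt": ["T"]}))
        assert out.iloc[0].tolist() == ["chr1", 2, "one_allele"]

    def test_g_side_substitution_also_loses(self):
        ref = build_reference("AACGTT")
        out = vc.detect_lost_cpg(ref, pd.DataFrame(
            {"chrom": ["chr1"], "pos": [3], "ref": ["G"], "alt": ["A"],
             "gt": ["1/1"]}))
        assert out.iloc[0].tolist() == ["chr1", 2, "both_alleles"]

    def test_cg_creating_variant_is_not_a_loss(self):
        ref = build_reference("AACATT")
        out = vc.detect_lost_cpg(ref, pd.DataFrame(
            {"chrom": ["chr1"], "pos": [3], "ref": ["A"], "alt": ["G"]}))
        assert len(out) == 0

    def test_ref_mismatch_rejected(self):
        ref = build_reference("AACGTT")
        with pytest.raises(ValueError):
            vc.detect_lost_cpg(ref, pd.DataFrame(
                {"chrom": ["chr1"], "pos": [2], "ref": ["A"], "alt": ["T"]}))

    def test_agrees_with_haplotype_reconstruction_oracle(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            seq = bases[rng.integers(0, 4, 2000)]
            ref = build_reference("".join(seq))
            n_var = rng.integers(1, 15)
            pos = np.sort(rng.choice(2000, size=n_var, replace=False))
            alts = [str(rng.choice([b for b in "ACGT" if b != seq[p]])) for p in pos]
            variants = pd.DataFrame(
                {"chrom": "chr1", "pos": pos, "ref": [str(seq[p]) for p in pos],
                 "alt": alts}
            )
            out = vc.detect_lost_cpg(ref, variants)
            # oracle: apply all variants to one haplotype, compare CG presence
            hap = seq.copy()
            hap[pos] = alts
            lost_oracle = sorted(
                int(p) for p in ref.cpg_sites["chr1"]
                if not (hap[p] == "C" and hap[p + 1] == "G")
            )
            assert sorted(out["pos"].tolist()) == lost_oracle


class TestCpgSnpFraction:
    def test_generator_cpg_snv_rate_recovered(self):
        cfg = sim.SimConfig(
            genome_length=500_000, n_chromosomes=2, n_asm_sites=400, n_bulk_sites=50,
            cpg_snv_rate=0.14, seed=19,
        )
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        out = vc.cpg_snp_fraction(truth.asm_sites, truth.variants)
        # injected rate plus a small background hit probability
        assert 0.10 <= out["fraction"] <= 0.20

    def test_no_overlap(self):
        out = vc.cpg_snp_fraction(sites([100]), pd.DataFrame({"chrom": ["chr1"], "pos": [500]}))
        assert out["fraction"] == 0.0

    def test_full_overlap_counts_both_bases(self):
        calls = sites([100, 200])
        variants = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 201]})
        out = vc.cpg_snp_fraction(calls, variants)
        assert out["fraction"] == 1.0


class TestDistance:
    def test_nearest_distance_arithmetic(self):
        out = vc.distance_distribution(
            sites([100]), sites([90, 300]), {"chr1": 1000}, seed=0
        )
        assert out["observed_distances"].tolist() == [10]

    def test_uniform_lost_sites_non_significant(self):
        rng = np.random.default_rng(4)
        out = vc.distance_distribution(
            sites(np.sort(rng.integers(0, 500_000, 200))),
            sites(np.sort(rng.integers(0, 500_000, 200))),
            {"chr1": 500_000}, seed=1,
        )
        assert out["p_value"] > 0.01

    def test_adjacent_lost_sites_shift_distribution(self):
        rng = np.random.default_rng(5)
        asm_pos = np.sort(rng.integers(1000, 499_000, 200))
        out = vc.distance_distribution(
            sites(asm_pos), sites(asm_pos + 3), {"chr1": 500_000}, seed=1
        )
        assert out["p_value"] < 0.01
        assert out["median_observed"] < out["median_random"]

    def test_empty_lost_set_rejected(self):
        with pytest.raises(ValueError):
            vc.distance_distribution(sites([1]), sites([]), {"chr1": 100})


class TestAggregation:
    def test_features_at_center_spike(self):
        centers = sites([10_000, 20_000, 30_000])
        features = sites([10_000, 20_000, 30_000])
        prof = vc.aggregation_profile(centers, features, {"chr1": 50_000},
                                      window_bp=500, bin_bp=100, n_permutations=20, seed=0)
        spike = np.flatnonzero(prof.observed)
        assert len(spike) == 1 and prof.bin_offsets[spike[0]] == 0

    def test_uniform_features_flat_profile(self):
        rng = np.random.default_rng(6)
        centers = sites(np.sort(rng.integers(1000, 999_000, 100)))
        features = sites(np.sort(rng.integers(0, 1_000_000, 5000)))
        prof = vc.aggregation_profile(centers, features, {"chr1": 1_000_000},
                                      window_bp=500, bin_bp=50, n_permutations=100, seed=1)
        # per-bin expectation ~ 0.25; allow 4 binomial sd over 100 centers
        sd = np.sqrt(prof.baseline / prof.n_centers + 1e-9)
        assert np.all(np.abs(prof.observed - prof.baseline) < 4 * sd + 0.05)

    def test_baseline_deterministic_for_seed(self):
        centers, features = sites([5000]), sites([4800, 5200])
        a = vc.aggregation_profile(centers, features, {"chr1": 10_000},
                                   n_permutations=50, seed=9)
        b = vc.aggregation_profile(centers, features, {"chr1": 10_000},
                                   n_permutations=50, seed=9)
        assert np.array_equal(a.baseline, b.baseline)

    def test_bin_width_must_divide_window(self):
        with pytest.raises(ValueError):
            vc.aggregation_profile(sites([1]), sites([2]), {"chr1": 100},
                                   window_bp=500, bin_bp=300)


def test_global_h1_h2_relabel_leaves_window_stats_unchanged(demo_truth):
    """Polarity invariance: flipping every haplotype label globally leaves the
    hypo/hyper tallies unchanged because hypo_hap flips with it."""
    calls = demo_truth.asm_sites[["chrom", "pos", "hypo_hap"]]
    base = vc.allele_of_residence(calls, demo_truth.variants)
    flip = {"H1": "H2", "H2": "H1"}
    flipped_calls = calls.assign(hypo_hap=calls["hypo_hap"].map(flip))
    flipped_vars = demo_truth.variants.assign(
        hap_of_alt=demo_truth.variants["hap_of_alt"].map(flip)
    )
    out = vc.allele_of_residence(flipped_calls, flipped_vars)
    assert out == base
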