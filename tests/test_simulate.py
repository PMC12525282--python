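"""Generator correctness: sequence composition, truth invariants, determinism."""

import numpy as np
import pandas as pd
import pytest

from asmtrio import simulate as sim


def count_cg(seq: np.ndarray) -> int:
    return int(((seq[:-1] == "C") & (seq[1:] == "G")).sum())


class TestReference:
    def test_cpg_count_near_rate_and_matches_sequence(self):
        cfg = sim.SimConfig(genome_length=10_000, n_chromosomes=1, cpg_rate=10.0, seed=1)
        ref = sim.simulate_reference(cfg)
        seq = ref.chroms["chr1"]
        n = len(ref.cpg_sites["chr1"])
        # Poisson(100): +/- 4 sd
        assert 60 <= n <= 140
        # the CpG list is exactly the set of CG dinucleotides in the sequence
        assert count_cg(seq) == n
        assert all(seq[p] == "C" and seq[p + 1] == "G" for p in ref.cpg_sites["chr1"])

    def test_zero_rate_rejects_all_cg(self):
        cfg = sim.SimConfig(genome_length=20_000, n_chromosomes=1, cpg_rate=0.0, seed=2)
        ref = sim.simulate_reference(cfg)
        assert count_cg(ref.chroms["chr1"]) == 0
        assert len(ref.cpg_sites["chr1"]) == 0

    def test_deterministic_for_fixed_seed(self):
        cfg = sim.SimConfig(seed=7)
        a = sim.simulate_reference(cfg)
        b = sim.simulate_reference(cfg)
        for chrom in a.chroms:
            assert np.array_equal(a.chroms[chrom], b.chroms[chrom])
            assert np.array_equal(a.cpg_sites[chrom], b.cpg_sites[chrom])

    def test_too_short_genome_rejected(self):
        with pytest.raises(sim.ConfigError):
            sim.simulate_reference(sim.SimConfig(genome_length=500))


class TestDiploid:
    def test_snv_density_fold_recovered(self):
        cfg = sim.SimConfig(
            genome_length=400_000, n_chromosomes=2, n_asm_sites=100, n_bulk_sites=100,
            snv_enrichment_fold=4.0, het_snv_rate=2.0, seed=3,
        )
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        v = truth.variants
        w = cfg.window_bp
        window_bases = 0
        for chrom, seq in truth.reference.chroms.items():
            mask = np.zeros(len(seq), bool)
            for p in truth.asm_sites.loc[truth.asm_sites["chrom"] == chrom, "pos"]:
                mask[max(0, p - w): p + w + 1] = True
            window_bases += int(mask.sum())
        total = sum(truth.reference.chrom_lengths.values())
        dens_in = v["in_asm_window"].sum() / window_bases
        dens_out = (~v["in_asm_window"]).sum() / (total - window_bases)
        fold = dens_in / dens_out
        assert 3.0 < fold < 5.2  # binomial tolerance around injected 4

    def test_extreme_delta_gives_binary_probabilities(self):
        cfg = sim.SimConfig(asm_delta=1.0, seed=4)
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        a = truth.asm_sites
        assert np.allclose(np.minimum(a["prob_h1"], a["prob_h2"]), 0.0)
        assert np.allclose(np.maximum(a["prob_h1"], a["prob_h2"]), 1.0)

    def test_bulk_sites_symmetric_and_asm_delta_floor(self, demo_truth, demo_config):
        b = demo_truth.bulk_sites
        assert np.allclose(b["prob_h1"], b["prob_h2"])
        a = demo_truth.asm_sites
        assert ((a["prob_h1"] - a["prob_h2"]).abs() >= demo_config.asm_delta - 1e-12).all()

    def test_symmetric_bias_splits_alleles_evenly(self):
        cfg = sim.SimConfig(
            genome_length=400_000, n_chromosomes=2, n_asm_sites=150, n_bulk_sites=50,
            hypo_allele_bias=0.5, seed=5,
        )
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        enriched = truth.variants[truth.variants["in_asm_window"]]
        share = (enriched["hap_of_alt"] == "H1").mean()
        assert abs(share - 0.5) < 4 * np.sqrt(0.25 / len(enriched))

    def test_fold_below_one_rejected(self, demo_truth):
        cfg = sim.SimConfig(snv_enrichment_fold=0.5)
        with pytest.raises(sim.ConfigError):
            cfg.validate()

    def test_lost_cpgs_backed_by_destroying_variant(self, demo_truth):
        vkeys = set(zip(demo_truth.variants["chrom"], demo_truth.variants["pos"]))
        for chrom, pos in zip(demo_truth.lost_cpgs["chrom"], demo_truth.lost_cpgs["pos"]):
            assert (chrom, pos) in vkeys or (chrom, pos + 1) in vkeys
            seq = demo_truth.reference.chroms[chrom]
            assert seq[pos] == "C" and seq[pos + 1] == "G"


class TestParents:
    def test_full_information_all_informative_and_mendelian(self, demo_truth):
        p = demo_truth.parents
        assert p["informative"].all()
        merged = demo_truth.variants.merge(p, on=["chrom", "pos"])
        for _, row in merged.iterrows():
            fa = row["father_gt"].count("1")
            ma = row["mother_gt"].count("1")
            # child is 0/1: one parent must be able to give alt, other ref
            assert (fa >= 1 and ma <= 1) or (ma >= 1 and fa <= 1)
            # H1 = maternal: alt on H1 implies mother carries it
            if row["hap_of_alt"] == "H1":
                assert ma >= 1 and fa == 0
            else:
                assert fa >= 1 and ma == 0

    def test_zero_information_leaves_all_uninformative(self, demo_truth):
        p = sim.simulate_parents(demo_truth, informative_fraction=0.0, seed=9)
        assert not p["informative"].any()
        assert (p["father_gt"] == "0/1").all() and (p["mother_gt"] == "0/1").all()
        # restore the session fixture's fully informative table
        sim.simulate_parents(demo_truth, informative_fraction=1.0)


class TestReads:
    def test_realized_coverage_near_target(self, demo_reads, demo_config):
        span = sum(r.end - r.start for r in demo_reads)
        total = demo_config.genome_length * demo_config.n_chromosomes
        assert 25 <= span / total <= 35

    def test_noise_free_reads_report_truth(self):
        cfg = sim.SimConfig(
            meth_call_error=0.0, allele_read_error=0.0, asm_delta=1.0, seed=6,
        )
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        reads = sim.simulate_reads(truth)
        probs = {
            (c, p): {"H1": p1, "H2": p2}
            for c, p, p1, p2 in zip(truth.meth["chrom"], truth.meth["pos"],
                                    truth.meth["prob_h1"], truth.meth["prob_h2"])
        }
        for r in reads:
            h1, h2 = truth.haplotypes[r.chrom]
            hseq = h1 if r.truth_hap == "H1" else h2
            for pos, base in r.allele_obs.items():
                assert base == hseq[pos]
            for pos, state in r.meth_obs.items():
                p = probs[(r.chrom, pos)][r.truth_hap]
                if p in (0.0, 1.0):
                    assert state == int(p)

    def test_positions_within_read_interval(self, demo_reads):
        for r in demo_reads[:200]:
            assert all(r.start <= p < r.end for p in r.allele_obs)
            assert all(r.start <= p < r.end for p in r.meth_obs)


class TestErrorInjection:
    def test_no_injection_keeps_truth(self, demo_reads, demo_truth):
        out, labels = sim.inject_phasing_errors(
            demo_reads, 0.0, 0.0, 0.3, seed=1,
            chrom_lengths=demo_truth.reference.chrom_lengths,
        )
        assert all(r.assigned_hap == r.truth_hap for r in out)
        assert (labels["klass"] == "correct").all()

    def test_partial_flip_fraction_recovered(self, demo_reads, demo_truth):
        out, labels = sim.inject_phasing_errors(
            demo_reads, 0.0, 1.0, 0.3, region_size_bp=10_000, seed=2,
            chrom_lengths=demo_truth.reference.chrom_lengths,
        )
        flipped = sum(r.assigned_hap != r.truth_hap for r in out)
        assert abs(flipped / len(out) - 0.3) < 0.03
        assert (labels["klass"] == "partial").all()

    def test_rates_over_one_rejected(self, demo_reads):
        with pytest.raises(sim.ConfigError):
            sim.inject_phasing_errors(demo_reads, 0.7, 0.5, 0.3)


class TestTracks:
    def test_effect_shifts_category_means(self, demo_truth):
        cons, _ = sim.simulate_tracks(demo_truth, conservation_effect=0.3, seed=3)
        asm_scores = [
            cons[c][p] for c, p in zip(demo_truth.asm_sites["chrom"],
                                       demo_truth.asm_sites["pos"])
        ]
        lost_scores = [
            cons[c][p] for c, p in zip(demo_truth.lost_cpgs["chrom"],
                                       demo_truth.lost_cpgs["pos"])
        ]
        gap = np.mean(asm_scores) - np.mean(lost_scores)
        assert abs(gap - 0.6) < 0.06

    def test_null_effect_leaves_categories_identical(self, demo_truth):
        cons, _ = sim.simulate_tracks(demo_truth, conservation_effect=0.0, seed=3)
        asm_scores = [
            cons[c][p] for c, p in zip(demo_truth.asm_sites["chrom"],
                                       demo_truth.asm_sites["pos"])
        ]
        assert abs(np.mean(asm_scores) - 0.4) < 0.05

    def test_states_tile_genome(self, demo_truth):
        _, states = sim.simulate_tracks(demo_truth, seed=3)
        for chrom, grp in states.groupby("chrom"):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert grp["end"].iloc[-1] == demo_truth.reference.chrom_lengths[chrom]
            assert (grp["start"].iloc[1:].to_numpy() == grp["end"].iloc[:-1].to_numpy()).all()


class TestAlleleCounts:
    def test_null_genes_centered_and_flags_emitted(self):
        counts = sim.simulate_allele_counts(
            n_genes=100, ase_gene_fraction=0.0, seed=4
        )
        assert not counts["is_ase"].any()
        share = counts["h1"].sum() / (counts["h1"] + counts["h2"]).sum()
        assert abs(share - 0.5) < 0.01

    def test_effect_shifts_ase_gene_shares(self):
        counts = sim.simulate_allele_counts(
            n_genes=200, ase_gene_fraction=0.5, ase_log2_effect=2.0, seed=5
        )
        g = counts.groupby("gene_id").agg(h1=("h1", "sum"), h2=("h2", "sum"),
                                          is_ase=("is_ase", "first"))
        share = g["h1"] / (g["h1"] + g["h2"])
        imbalance = (share - 0.5).abs()
        assert imbalance[g["is_ase"]].median() > 0.25
        assert imbalance[~g["is_ase"]].median() < 0.05


def test_generator_is_deterministic_end_to_end(tmp_path):
    from asmtrio import io

    def build(outdir):
        cfg = sim.SimConfig(seed=11)
        truth = sim.simulate_diploid(sim.simulate_reference(cfg), cfg)
        sim.simulate_parents(truth, 1.0)
        reads = sim.simulate_reads(truth)
        io.write_fasta(truth.reference, outdir / "ref.fa")
        io.write_read_table(reads, outdir / "reads.tsv")
        vdf = truth.variants.assign(phase_set=truth.variants["chrom"])
        io.write_phased_vcf(vdf, truth.reference.chrom_lengths, outdir / "child.vcf")
        return outdir

    (tmp_path / "a").mkdir()
    (tmp_path / "b").mkdir()
    a = build(tmp_path / "a")
    b = build(tmp_path / "b")
    for name in ("ref.fa", "reads.tsv", "child.vcf"):
        assert (a / name).read_bytes() == (b / name).read_bytes()
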