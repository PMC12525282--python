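"""End-to-end runner: simulate -> phase -> asm -> varcontext -> enrich -> ase.

One structured YAML config drives every stage; outputs land in per-stage
subdirectories and a run manifest (config snapshot, seed, per-stage output
paths and wall times, tool version) is written last, so a run can be audited
and replayed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotation, asm, expression, io, phasing, variant_context
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def default_config() -> dict:
    return {
        "seed": 0,
        "simulate": {
            **sim.SimConfig().to_dict(),
            "informative_fraction": 1.0,
            "complete_region_rate": 0.02,
            "partial_region_rate": 0.02,
            "partial_flip_fraction": 0.3,
            "region_size_bp": 10_000,
            "conservation_effect": 0.3,
            "n_states": 5,
            "asm_state_odds": 3.0,
            "n_genes": 20,
            "expression": {
                "n_genes": 200,
                "n_replicates": 3,
                "mean_depth": 500.0,
                "dispersion": 1e-4,
                "ase_gene_fraction": 0.12,
                "ase_log2_effect": 2.0,
            },
        },
        "phase": {"min_link": 2, "min_votes": 1,
                  "region_size_bp": 10_000, "complete_threshold": 0.9},
        "asm": {"min_cov_per_hap": 5, "delta_min": 0.25, "alpha": 0.05},
        "varcontext": {"window_bp": 500, "bin_bp": 50,
                       "n_bootstrap": 1000, "n_permutations": 200},
        "enrich": {"n_permutations": 1000,
                   "promoter_upstream_bp": 2000, "promoter_downstream_bp": 500},
        "ase": {"alpha": 0.05},
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if "seed" not in user:
        raise PipelineError("config validation: missing required key 'seed'")
    cfg = default_config()

    def merge(base: dict, over: dict) -> dict:
        for k, v in over.items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v
        return base

    return merge(cfg, user)


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> dict:
    """Run every stage in order and return the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"asmtrio {__version__}",
        "seed": config["seed"],
        "config": config,
        "stages": {},
    }
    state: dict = {}
    for name, fn in [
        ("simulate", _stage_simulate),
        ("phase", _stage_phase),
        ("asm", _stage_asm),
        ("varcontext", _stage_varcontext),
        ("enrich", _stage_enrich),
        ("ase", _stage_ase),
    ]:
        t0 = time.perf_counter()
        stage_dir = outdir / name
        stage_dir.mkdir(exist_ok=True)
        try:
            outputs = fn(config, state, stage_dir)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage label
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "wall_seconds": round(time.perf_counter() - t0, 3),
        }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(path)
    return manifest


def _stage_simulate(config: dict, state: dict, outdir: Path) -> dict:
    c = dict(config["simulate"])
    expr_cfg = c.pop("expression")
    extras = {
        k: c.pop(k)
        for k in ["informative_fraction", "complete_region_rate", "partial_region_rate",
                  "partial_flip_fraction", "region_size_bp", "conservation_effect",
                  "n_states", "asm_state_odds", "n_genes"]
    }
    sc = sim.SimConfig.from_dict({**c, "seed": config["seed"]})
    reference = sim.simulate_reference(sc)
    truth = sim.simulate_diploid(reference, sc)
    sim.simulate_parents(truth, extras["informative_fraction"])
    reads = sim.simulate_reads(truth)
    reads, error_regions = sim.inject_phasing_errors(
        reads,
        extras["complete_region_rate"], extras["partial_region_rate"],
        extras["partial_flip_fraction"], extras["region_size_bp"],
        seed=sc.seed, chrom_lengths=reference.chrom_lengths,
    )
    cons, states = sim.simulate_tracks(
        truth, extras["conservation_effect"], extras["n_states"],
        asm_state_odds=extras["asm_state_odds"],
    )
    genes = sim.simulate_gene_models(truth, n_genes=extras["n_genes"], seed=sc.seed)
    counts = sim.simulate_allele_counts(seed=sc.seed, **expr_cfg)

    out = {}
    out["reference_fasta"] = outdir / "reference.fa"
    io.write_fasta(reference, out["reference_fasta"])
    out["child_vcf"] = outdir / "child.vcf"
    vdf = truth.variants.assign(phase_set=truth.variants["chrom"])
    io.write_phased_vcf(vdf, reference.chrom_lengths, out["child_vcf"])
    out["father_vcf"] = outdir / "father.vcf"
    out["mother_vcf"] = outdir / "mother.vcf"
    io.write_parent_vcfs(
        truth.variants, truth.parents, reference.chrom_lengths,
        out["father_vcf"], out["mother_vcf"],
    )
    out["read_table"] = outdir / "reads.tsv"
    io.write_read_table(reads, out["read_table"])
    out["asm_truth_bed"] = outdir / "asm_sites.truth.bed"
    a = truth.asm_sites
    io.write_bed(pd.DataFrame({"chrom": a["chrom"], "start": a["pos"], "end": a["pos"] + 2}),
                 out["asm_truth_bed"])
    out["lost_cpg_bed"] = outdir / "lost_cpgs.truth.bed"
    l = truth.lost_cpgs
    io.write_bed(pd.DataFrame({"chrom": l["chrom"], "start": l["pos"], "end": l["pos"] + 2}),
                 out["lost_cpg_bed"])
    out["error_regions_bed"] = outdir / "error_regions.truth.bed"
    io.write_bed(error_regions, out["error_regions_bed"],
                 cols=("chrom", "start", "end", "klass"))
    out["conservation_bedgraph"] = outdir / "conservation.bedgraph"
    io.write_bedgraph(cons, out["conservation_bedgraph"])
    out["states_bed"] = outdir / "chromatin_states.bed"
    io.write_bed(states, out["states_bed"], cols=("chrom", "start", "end", "state"))
    out["genes_bed12"] = outdir / "genes.bed12"
    io.write_gene_bed12(genes, out["genes_bed12"])
    out["allele_counts_tsv"] = outdir / "allele_counts.tsv"
    counts.to_csv(out["allele_counts_tsv"], sep="\t", index=False)

    state.update(
        truth=truth, reads=reads, error_regions=error_regions,
        conservation=cons, chrom_states=states, genes=genes, allele_counts=counts,
    )
    return out


def _stage_phase(config: dict, state: dict, outdir: Path) -> dict:
    pc = config["phase"]
    truth = state["truth"]
    trio = phasing.trio_bin(truth.variants, truth.parents)
    tagged = phasing.tag_reads(state["reads"], trio, min_votes=pc["min_votes"])
    blocks_trio = phasing.trio_blocks(trio)
    readbased, blocks_rb = phasing.phase_readbased(
        state["reads"], truth.variants, min_link=pc["min_link"]
    )
    truth_phase = {
        (c, p): h for c, p, h in zip(
            truth.variants["chrom"], truth.variants["pos"], truth.variants["hap_of_alt"]
        )
    }
    report = phasing.evaluate_phasing(
        tagged, region_size_bp=pc["region_size_bp"],
        complete_threshold=pc["complete_threshold"],
        blocks=blocks_trio, phased_variants=trio, truth_phase=truth_phase,
        chrom_lengths=truth.reference.chrom_lengths,
    )
    out = {}
    out["phased_vcf"] = outdir / "child.trio_phased.vcf"
    io.write_phased_vcf(trio, truth.reference.chrom_lengths, out["phased_vcf"])
    out["tagged_reads"] = outdir / "reads.haplotagged.tsv"
    io.write_read_table(tagged, out["tagged_reads"])
    out["region_calls"] = outdir / "region_calls.tsv"
    report.region_calls.to_csv(out["region_calls"], sep="\t", index=False)
    summary = {
        "n50_trio": report.n50,
        "n50_readbased": phasing.compute_n50(blocks_rb),
        "read_accuracy": report.read_accuracy,
        "switch_error_rate": report.switch_error_rate,
    }
    out["summary"] = outdir / "phasing_summary.json"
    Path(out["summary"]).write_text(json.dumps(summary, indent=2))
    state.update(trio=trio, tagged_reads=tagged, phasing_summary=summary,
                 phasing_report=report)
    return out


def _stage_asm(config: dict, state: dict, outdir: Path) -> dict:
    ac = config["asm"]
    counts = asm.pileup_cpg(state["tagged_reads"])
    calls = asm.call_asm(counts, ac["min_cov_per_hap"], ac["delta_min"], ac["alpha"])
    summary = asm.summarize_asm(max(len(counts), 1), int(calls["significant"].sum()))
    out = {}
    for hap in ("H1", "H2"):
        out[f"bedmethyl_{hap.lower()}"] = outdir / f"methylation.{hap}.bed"
        io.write_bedmethyl(counts, hap, out[f"bedmethyl_{hap.lower()}"])
    out["asm_calls"] = outdir / "asm_calls.tsv"
    calls.to_csv(out["asm_calls"], sep="\t", index=False)
    out["summary"] = outdir / "asm_summary.json"
    Path(out["summary"]).write_text(json.dumps(summary, indent=2))
    state.update(cpg_counts=counts, asm_calls=calls, asm_summary=summary)
    return out


def _stage_varcontext(config: dict, state: dict, outdir: Path) -> dict:
    vc = config["varcontext"]
    truth = state["truth"]
    calls = state["asm_calls"]
    sig = calls[calls["significant"]]
    coverage = {
        (c, p): m1 + u1 + m2 + u2
        for c, p, m1, u1, m2, u2 in zip(
            state["cpg_counts"]["chrom"], state["cpg_counts"]["pos"],
            state["cpg_counts"]["n_meth_h1"], state["cpg_counts"]["n_unmeth_h1"],
            state["cpg_counts"]["n_meth_h2"], state["cpg_counts"]["n_unmeth_h2"],
        )
    }
    nonsig = calls[~calls["significant"]][["chrom", "pos"]]
    controls = variant_context.match_controls(
        sig[["chrom", "pos"]], nonsig, k_per_site=1,
        coverage=coverage, cpg_positions=truth.reference.cpg_sites,
        seed=config["seed"],
    )
    enr = variant_context.window_snv_density(
        sig[["chrom", "pos"]], controls, truth.variants,
        window_bp=vc["window_bp"], n_bootstrap=vc["n_bootstrap"],
        n_permutations=vc["n_permutations"], seed=config["seed"],
    )
    residence = variant_context.allele_of_residence(sig, truth.variants, vc["window_bp"])
    if len(sig):
        mask = variant_context.variants_in_windows(
            truth.variants, sig[["chrom", "pos"]], vc["window_bp"]
        )
        in_windows = truth.variants[mask]
    else:
        in_windows = truth.variants.iloc[:0]
    spectrum = variant_context.substitution_spectrum(in_windows)
    lost = variant_context.detect_lost_cpg(truth.reference, truth.variants)
    frac = variant_context.cpg_snp_fraction(sig, truth.variants)
    profile = variant_context.aggregation_profile(
        sig[["chrom", "pos"]], truth.variants[["chrom", "pos"]],
        truth.reference.chrom_lengths, window_bp=vc["window_bp"],
        bin_bp=vc["bin_bp"], n_permutations=vc["n_permutations"], seed=config["seed"],
    )
    out = {}
    out["enrichment"] = outdir / "snv_enrichment.tsv"
    pd.DataFrame([vars(enr)]).to_csv(out["enrichment"], sep="\t", index=False)
    out["allele_residence"] = outdir / "allele_residence.json"
    Path(out["allele_residence"]).write_text(json.dumps(residence, indent=2))
    out["spectrum"] = outdir / "substitution_spectrum.tsv"
    spectrum.to_csv(out["spectrum"], sep="\t")
    out["lost_cpgs"] = outdir / "lost_cpgs.detected.bed"
    io.write_bed(
        pd.DataFrame({"chrom": lost["chrom"], "start": lost["pos"],
                      "end": lost["pos"] + 2, "klass": lost["klass"]}),
        out["lost_cpgs"], cols=("chrom", "start", "end", "klass"),
    )
    out["cpg_snp_fraction"] = outdir / "cpg_snp_fraction.json"
    Path(out["cpg_snp_fraction"]).write_text(json.dumps(frac, indent=2))
    out["profile"] = outdir / "aggregation_profile.tsv"
    pd.DataFrame(
        {"offset": profile.bin_offsets, "observed": profile.observed,
         "baseline": profile.baseline}
    ).to_csv(out["profile"], sep="\t", index=False)
    state.update(enrichment=enr, residence=residence, detected_lost=lost,
                 cpg_snp=frac, controls=controls)
    return out


def _stage_enrich(config: dict, state: dict, outdir: Path) -> dict:
    ec = config["enrich"]
    truth = state["truth"]
    calls = state["asm_calls"]
    sig = calls[calls["significant"]]
    annotated = annotation.annotate_sites(
        sig[["chrom", "pos"]], state["genes"],
        ec["promoter_upstream_bp"], ec["promoter_downstream_bp"],
    )
    states = state["chrom_states"]
    ann = {name: grp[["chrom", "start", "end"]] for name, grp in states.groupby("state")}
    workspace = pd.DataFrame(
        [(c, 0, n) for c, n in truth.reference.chrom_lengths.items()],
        columns=["chrom", "start", "end"],
    )
    enrich = annotation.interval_enrichment(
        sig[["chrom", "pos"]], ann, workspace,
        n_permutations=ec["n_permutations"], seed=config["seed"],
    )
    flank = truth.variants[truth.variants["in_asm_window"]][["chrom", "pos"]]
    categories = {
        "asm_site": sig[["chrom", "pos"]],
        "flanking_snv": flank,
        "lost_cpg": state["detected_lost"][["chrom", "pos"]],
    }
    cons_summary, cons_pairwise = annotation.conservation_strata(
        categories, state["conservation"]
    )
    out = {}
    out["annotation"] = outdir / "site_annotation.tsv"
    annotated.to_csv(out["annotation"], sep="\t", index=False)
    out["state_enrichment"] = outdir / "state_enrichment.tsv"
    enrich.to_csv(out["state_enrichment"], sep="\t", index=False)
    out["conservation_summary"] = outdir / "conservation_summary.tsv"
    cons_summary.to_csv(out["conservation_summary"], sep="\t", index=False)
    out["conservation_pairwise"] = outdir / "conservation_pairwise.tsv"
    cons_pairwise.to_csv(out["conservation_pairwise"], sep="\t", index=False)
    state.update(annotated=annotated, state_enrichment=enrich,
                 conservation_summary=cons_summary)
    return out


def _stage_ase(config: dict, state: dict, outdir: Path) -> dict:
    records = expression.test_ase(state["allele_counts"], alpha=config["ase"]["alpha"])
    truth_flags = state["allele_counts"].groupby("gene_id")["is_ase"].first()
    merged = records.merge(truth_flags.rename("is_ase"), on="gene_id")
    called = merged[merged["significant"]]
    summary = {
        "n_genes": int(len(records)),
        "n_significant": int(records["significant"].sum()),
        "n_true_ase": int(truth_flags.sum()),
        "sensitivity": float(
            called["is_ase"].sum() / max(int(truth_flags.sum()), 1)
        ),
    }
    out = {}
    out["ase_calls"] = outdir / "ase_calls.tsv"
    records.to_csv(out["ase_calls"], sep="\t", index=False)
    out["summary"] = outdir / "ase_summary.json"
    Path(out["summary"]).write_text(json.dumps(summary, indent=2))
    state.update(ase_records=records, ase_summary=summary)
    return out
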