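"""Readers and writers for the pipeline's on-disk formats.

Coordinates are 0-based half-open internally and in BED-family outputs;
VCF is 1-based with the conversion done at this boundary.  FASTA goes
through Biopython, VCF through pysam; the haplotagged read table is a plain
TSV with delimited per-position observation columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import Reference, TaggedRead

__all__ = [
    "write_fasta", "read_fasta",
    "write_phased_vcf", "write_parent_vcfs", "read_vcf",
    "write_read_table", "read_read_table",
    "write_bedmethyl", "write_bed", "write_bedgraph",
    "write_gene_bed12", "read_gene_bed12",
]


def write_fasta(reference: Reference, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(reference.sequence(c)), id=c, description="")
        for c in reference.chroms
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> Reference:
    chroms = {}
    cpgs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = np.array(list(str(rec.seq).upper()), dtype="U1")
        chroms[rec.id] = seq
        is_cg = (seq[:-1] == "C") & (seq[1:] == "G")
        cpgs[rec.id] = np.flatnonzero(is_cg)
    return Reference(chroms=chroms, cpg_sites=cpgs)


def _vcf_header(chrom_lengths: dict[str, int], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set")
    header.add_sample(sample)
    return header


def write_phased_vcf(
    variants: pd.DataFrame,
    chrom_lengths: dict[str, int],
    path: str | Path,
    sample: str = "child",
) -> None:
    """Phased child VCF: het GT written with `|` (alt-first when on H1), PS tag.

    Input positions are 0-based; VCF positions are 1-based.  Unphased rows
    are written `0/1` without PS.
    """
    header = _vcf_header(chrom_lengths, sample)
    ordered = variants.sort_values(["chrom", "pos"])
    # PS is conventionally the 1-based position of the first variant in the set
    ps_anchor: dict = {}
    if "phase_set" in ordered.columns:
        for _, v in ordered.iterrows():
            ps = v["phase_set"]
            if ps is not None and not pd.isna(ps):
                ps_anchor.setdefault(ps, int(v["pos"]) + 1)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, v in ordered.iterrows():
            rec = vcf.new_record(
                contig=v["chrom"], start=int(v["pos"]), stop=int(v["pos"]) + 1,
                alleles=(v["ref"], v["alt"]),
            )
            hap = v.get("hap_of_alt", "unphased")
            if hap == "H1":
                rec.samples[sample]["GT"] = (1, 0)
                rec.samples[sample].phased = True
            elif hap == "H2":
                rec.samples[sample]["GT"] = (0, 1)
                rec.samples[sample].phased = True
            else:
                rec.samples[sample]["GT"] = (0, 1)
                rec.samples[sample].phased = False
            ps = v.get("phase_set")
            if hap in ("H1", "H2") and ps is not None and not pd.isna(ps):
                rec.samples[sample]["PS"] = ps_anchor[ps]
            vcf.write(rec)


def write_parent_vcfs(
    variants: pd.DataFrame,
    parents: pd.DataFrame,
    chrom_lengths: dict[str, int],
    father_path: str | Path,
    mother_path: str | Path,
) -> None:
    merged = variants.merge(parents, on=["chrom", "pos"])
    for col, path, sample in (
        ("father_gt", father_path, "father"), ("mother_gt", mother_path, "mother")
    ):
        header = _vcf_header(chrom_lengths, sample)
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for _, v in merged.sort_values(["chrom", "pos"]).iterrows():
                rec = vcf.new_record(
                    contig=v["chrom"], start=int(v["pos"]), stop=int(v["pos"]) + 1,
                    alleles=(v["ref"], v["alt"]),
                )
                gt = tuple(int(x) for x in str(v[col]).replace("|", "/").split("/"))
                rec.samples[sample]["GT"] = gt
                vcf.write(rec)


def read_vcf(path: str | Path) -> pd.DataFrame:
    """VCF -> 0-based variant table with hap_of_alt decoded from phased GT."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            call = rec.samples[sample]
            gt = call["GT"]
            if call.phased and gt == (1, 0):
                hap = "H1"
            elif call.phased and gt == (0, 1):
                hap = "H2"
            else:
                hap = "unphased"
            ps = call.get("PS") if "PS" in call else None
            rows.append(
                (rec.contig, rec.start, rec.ref, rec.alts[0], hap, ps,
                 "/".join(str(a) for a in sorted(gt)))
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "hap_of_alt", "phase_set", "gt"]
    )


def _encode_obs(obs: dict, fmt) -> str:
    return ";".join(f"{p}:{fmt(v)}" for p, v in sorted(obs.items())) or "."


def write_read_table(reads: list[TaggedRead], path: str | Path) -> None:
    rows = []
    for r in reads:
        rows.append(
            (r.read_id, r.chrom, r.start, r.end, r.assigned_hap,
             r.truth_hap or ".",
             _encode_obs(r.allele_obs, str),
             _encode_obs(r.meth_obs, lambda v: "M" if v else "U"))
        )
    pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "end", "assigned_hap",
                 "truth_hap", "allele_obs", "meth_obs"],
    ).to_csv(path, sep="\t", index=False)


def read_read_table(path: str | Path) -> list[TaggedRead]:
    df = pd.read_csv(path, sep="\t", dtype={"allele_obs": str, "meth_obs": str})
    reads = []
    for _, row in df.iterrows():
        allele_obs = {}
        if row["allele_obs"] != ".":
            for tok in row["allele_obs"].split(";"):
                p, b = tok.split(":")
                allele_obs[int(p)] = b
        meth_obs = {}
        if row["meth_obs"] != ".":
            for tok in row["meth_obs"].split(";"):
                p, s = tok.split(":")
                meth_obs[int(p)] = 1 if s == "M" else 0
        reads.append(
            TaggedRead(
                read_id=row["read_id"], chrom=row["chrom"],
                start=int(row["start"]), end=int(row["end"]),
                allele_obs=allele_obs, meth_obs=meth_obs,
                assigned_hap=row["assigned_hap"],
                truth_hap=None if row["truth_hap"] == "." else row["truth_hap"],
            )
        )
    return reads


def write_bedmethyl(counts: pd.DataFrame, hap: str, path: str | Path) -> None:
    """bedMethyl-style track for one haplotype: chrom, start, end, cov, %meth."""
    h = hap.lower()
    cov = counts[f"n_meth_{h}"] + counts[f"n_unmeth_{h}"]
    with np.errstate(invalid="ignore"):
        pct = np.where(cov > 0, 100.0 * counts[f"n_meth_{h}"] / cov, np.nan)
    pd.DataFrame(
        {"chrom": counts["chrom"], "start": counts["pos"], "end": counts["pos"] + 2,
         "coverage": cov, "percent_methylated": np.round(pct, 2)}
    ).to_csv(path, sep="\t", index=False, header=False)


def write_bed(df: pd.DataFrame, path: str | Path, cols=("chrom", "start", "end")) -> None:
    df.loc[:, list(cols)].to_csv(path, sep="\t", index=False, header=False)


def write_bedgraph(track: dict[str, np.ndarray], path: str | Path) -> None:
    """Per-base scores as a run-length-merged bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            vals = np.round(track[chrom], 4)
            breaks = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(vals)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]}\n")


def read_bedgraph(path: str | Path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "score"])
    for _, row in df.iterrows():
        track[row["chrom"]][int(row["start"]): int(row["end"])] = row["score"]
    return track


def write_gene_bed12(genes: pd.DataFrame, path: str | Path) -> None:
    rows = []
    for _, g in genes.iterrows():
        sizes = [e - s for s, e in zip(g["exon_starts"], g["exon_ends"])]
        starts = [s - g["start"] for s in g["exon_starts"]]
        rows.append(
            (g["chrom"], g["start"], g["end"], g["gene_id"], 0, g["strand"],
             g["thick_start"], g["thick_end"], "0,0,0", len(sizes),
             ",".join(map(str, sizes)) + ",", ",".join(map(str, starts)) + ",")
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_gene_bed12(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand",
               "thick_start", "thick_end", "rgb", "n_blocks", "sizes", "offsets"],
    )
    rows = []
    for _, g in df.iterrows():
        sizes = [int(x) for x in str(g["sizes"]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(g["offsets"]).rstrip(",").split(",")]
        exon_starts = [g["start"] + o for o in offsets]
        exon_ends = [s + z for s, z in zip(exon_starts, sizes)]
        rows.append(
            {"gene_id": g["gene_id"], "chrom": g["chrom"], "start": g["start"],
             "end": g["end"], "strand": g["strand"],
             "thick_start": g["thick_start"], "thick_end": g["thick_end"],
             "exon_starts": exon_starts, "exon_ends": exon_ends}
        )
    return pd.DataFrame(rows)
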