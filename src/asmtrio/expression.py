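"""Allele-specific expression and its coupling with promoter methylation.

Haplotagged transcript reads are counted per gene and replicate; allele
imbalance is tested with an exact binomial test on pooled H1/H2 counts
against 0.5, BH-corrected across genes, with significance additionally
requiring a consistent direction across replicates.  Per-gene promoter
methylation asymmetry (mean ASM delta over promoter CpGs) is then correlated
with the pooled allelic expression log-ratio by Spearman rank correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["count_allele_reads", "test_ase", "couple_expression_methylation"]


def count_allele_reads(
    tagged_transcript_reads: pd.DataFrame, gene_model: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene per-replicate (H1, H2) read counts.

    Reads need columns ``chrom, start, end, hap, replicate``; untagged reads
    are excluded.  A read counts once for the gene with the largest span
    overlap; exact ties are dropped.  Reads overlapping no gene are dropped
    and logged.
    """
    genes_by_chrom = {c: g.reset_index(drop=True) for c, g in gene_model.groupby("chrom")}
    rows = []
    n_orphan = n_tie = 0
    tagged = tagged_transcript_reads[
        tagged_transcript_reads["hap"].isin(["H1", "H2"])
    ]
    for _, read in tagged.iterrows():
        genes = genes_by_chrom.get(read["chrom"])
        if genes is None:
            n_orphan += 1
            continue
        ov = np.minimum(genes["end"], read["end"]) - np.maximum(genes["start"], read["start"])
        ov = ov.to_numpy()
        if ov.max(initial=0) <= 0:
            n_orphan += 1
            continue
        best = ov.max()
        winners = np.flatnonzero(ov == best)
        if len(winners) > 1:
            n_tie += 1
            continue
        rows.append((genes["gene_id"].iat[winners[0]], read["replicate"], read["hap"]))
    if n_orphan or n_tie:
        logger.info("dropped %d reads overlapping no gene, %d overlap ties", n_orphan, n_tie)
    df = pd.DataFrame(rows, columns=["gene_id", "replicate", "hap"])
    counts = (
        df.groupby(["gene_id", "replicate", "hap"]).size().unstack(fill_value=0)
        .reindex(columns=["H1", "H2"], fill_value=0)
        .rename(columns={"H1": "h1", "H2": "h2"})
        .reset_index()
    )
    counts.columns.name = None
    return counts


def test_ase(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Exact binomial ASE test on pooled counts with direction consistency.

    ``counts`` holds one row per gene and replicate (``gene_id, replicate,
    h1, h2``).  The pooled log2 ratio uses a 0.5 pseudocount.  Genes with
    zero total reads are untestable and excluded from the BH correction.
    Significance requires q < alpha and the per-replicate ratio sign to agree
    in every replicate with reads.
    """
    rows = []
    for gene_id, grp in counts.groupby("gene_id"):
        h1, h2 = int(grp["h1"].sum()), int(grp["h2"].sum())
        total = h1 + h2
        ratio = float(np.log2((h1 + 0.5) / (h2 + 0.5)))
        rep_signs = [
            np.sign(np.log2((a + 0.5) / (b + 0.5)))
            for a, b in zip(grp["h1"], grp["h2"]) if a + b > 0
        ]
        consistent = len(rep_signs) > 0 and all(s == rep_signs[0] and s != 0 for s in rep_signs)
        p = stats.binomtest(h1, total, 0.5).pvalue if total > 0 else np.nan
        rows.append((gene_id, h1, h2, ratio, consistent, p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "h1", "h2", "pooled_log2_ratio",
                       "direction_consistent", "p"]
    )
    testable = out["p"].notna()
    out["q"] = np.nan
    if testable.any():
        out.loc[testable, "q"] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
    out["significant"] = (out["q"] < alpha) & out["direction_consistent"]
    return out


def couple_expression_methylation(
    ase_records: pd.DataFrame,
    asm_calls: pd.DataFrame,
    gene_model: pd.DataFrame,
    promoter_upstream_bp: int = 2000,
    promoter_downstream_bp: int = 500,
) -> tuple[pd.DataFrame, float, float]:
    """Spearman correlation of allelic expression with promoter ASM delta.

    ``promoter_delta`` is the mean delta (freq H1 - freq H2) over testable
    promoter CpGs of each gene; genes with no covered promoter CpG are
    excluded and counted.  Both tables must share the H1/H2 frame (e.g. the
    trio frame).  Raises ValueError with fewer than 2 genes to correlate.
    """
    calls_by_chrom = {c: g.sort_values("pos") for c, g in asm_calls.groupby("chrom")}
    rows = []
    n_uncovered = 0
    gm = gene_model.set_index("gene_id")
    for _, rec in ase_records.iterrows():
        gene = gm.loc[rec["gene_id"]]
        fwd = gene["strand"] == "+"
        tss = gene["start"] if fwd else gene["end"] - 1
        if fwd:
            lo, hi = tss - promoter_upstream_bp, tss + promoter_downstream_bp
        else:
            lo, hi = tss - promoter_downstream_bp + 1, tss + promoter_upstream_bp + 1
        sub = calls_by_chrom.get(gene["chrom"])
        if sub is not None:
            arr = sub["pos"].to_numpy()
            i, j = np.searchsorted(arr, [lo, hi])
            deltas = sub["delta"].to_numpy()[i:j]
        else:
            deltas = np.empty(0)
        if deltas.size == 0:
            n_uncovered += 1
            continue
        rows.append((rec["gene_id"], rec["pooled_log2_ratio"], float(deltas.mean())))
    if n_uncovered:
        logger.info("%d genes without covered promoter CpGs excluded", n_uncovered)
    table = pd.DataFrame(rows, columns=["gene_id", "pooled_log2_ratio", "promoter_delta"])
    if len(table) < 2:
        raise ValueError("need at least 2 genes with promoter methylation to correlate")
    rho, p = stats.spearmanr(table["pooled_log2_ratio"], table["promoter_delta"])
    return table, float(rho), float(p)
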