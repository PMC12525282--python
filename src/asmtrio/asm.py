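"""Per-CpG allele-specific methylation calling.

Read-level methylation calls are aggregated into per-CpG, per-haplotype
methylated/unmethylated counts; each site covered on both haplotypes is
tested with a two-sided Fisher exact test on the 2x2 count table, with
Benjamini-Hochberg correction across tested sites.  A site is called ASM when
q < alpha and the methylation-frequency difference |freq(H1) - freq(H2)|
reaches ``delta_min``.  Coverage subsampling and cross-coverage frequency
correlation support coverage-titration analyses.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import TaggedRead, stream_rng

__all__ = [
    "pileup_cpg",
    "call_asm",
    "subsample_reads",
    "methylation_correlation",
    "site_frequencies",
    "summarize_asm",
    "bin_deltas",
]


def pileup_cpg(tagged_reads: list[TaggedRead]) -> pd.DataFrame:
    """Per-CpG per-haplotype methylation counts from haplotagged reads.

    Untagged reads are excluded.  Returns one row per covered site with
    columns ``n_meth_h1, n_unmeth_h1, n_meth_h2, n_unmeth_h2`` and the
    per-haplotype frequencies (NaN where a haplotype has no coverage).
    """
    counts: dict[tuple[str, int], list[int]] = {}
    for read in tagged_reads:
        if read.assigned_hap not in ("H1", "H2"):
            continue
        k = 0 if read.assigned_hap == "H1" else 2
        for pos, state in read.meth_obs.items():
            row = counts.setdefault((read.chrom, pos), [0, 0, 0, 0])
            row[k + (0 if state else 1)] += 1
    if not counts:
        return pd.DataFrame(
            columns=["chrom", "pos", "n_meth_h1", "n_unmeth_h1",
                     "n_meth_h2", "n_unmeth_h2", "freq_h1", "freq_h2"]
        )
    rows = [
        (chrom, pos, m1, u1, m2, u2)
        for (chrom, pos), (m1, u1, m2, u2) in counts.items()
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "n_meth_h1", "n_unmeth_h1", "n_meth_h2", "n_unmeth_h2"]
    ).sort_values(["chrom", "pos"], ignore_index=True)
    with np.errstate(invalid="ignore"):
        df["freq_h1"] = df["n_meth_h1"] / (df["n_meth_h1"] + df["n_unmeth_h1"])
        df["freq_h2"] = df["n_meth_h2"] / (df["n_meth_h2"] + df["n_unmeth_h2"])
    return df


def call_asm(
    counts: pd.DataFrame,
    min_cov_per_hap: int = 5,
    delta_min: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher exact test per CpG with BH correction across tested sites.

    Sites with fewer than ``min_cov_per_hap`` reads on either haplotype are
    untestable and omitted.  ``delta`` is freq(H1) - freq(H2); ``hypo_hap``
    names the haplotype with the lower frequency (``none`` on a tie).
    """
    if len(counts) == 0:
        return pd.DataFrame(
            columns=list(counts.columns) + ["delta", "p", "q", "significant", "hypo_hap"]
        )
    cov1 = counts["n_meth_h1"] + counts["n_unmeth_h1"]
    cov2 = counts["n_meth_h2"] + counts["n_unmeth_h2"]
    testable = counts[(cov1 >= min_cov_per_hap) & (cov2 >= min_cov_per_hap)].copy()
    if len(testable) == 0:
        return testable.assign(delta=[], p=[], q=[], significant=[], hypo_hap=[])
    pvals = [
        stats.fisher_exact([[m1, u1], [m2, u2]], alternative="two-sided")[1]
        for m1, u1, m2, u2 in zip(
            testable["n_meth_h1"], testable["n_unmeth_h1"],
            testable["n_meth_h2"], testable["n_unmeth_h2"],
        )
    ]
    testable["delta"] = testable["freq_h1"] - testable["freq_h2"]
    testable["p"] = pvals
    testable["q"] = multipletests(pvals, method="fdr_bh")[1]
    testable["significant"] = (testable["q"] < alpha) & (testable["delta"].abs() >= delta_min)
    testable["hypo_hap"] = np.select(
        [testable["delta"] > 0, testable["delta"] < 0], ["H2", "H1"], default="none"
    )
    return testable.reset_index(drop=True)


def subsample_reads(
    reads: list[TaggedRead],
    target_coverage: float,
    current_coverage: float,
    seed: int = 0,
) -> list[TaggedRead]:
    """Thin reads to a target mean coverage by independent retention."""
    if target_coverage > current_coverage:
        raise ValueError("target coverage exceeds current coverage")
    if target_coverage == current_coverage:
        return list(reads)
    p = target_coverage / current_coverage
    rng = stream_rng(seed, "subsample")
    keep = rng.random(len(reads)) < p
    return [r for r, k in zip(reads, keep) if k]


def site_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Pooled (both-haplotype) per-site methylation frequency and coverage."""
    n_meth = counts["n_meth_h1"] + counts["n_meth_h2"]
    cov = n_meth + counts["n_unmeth_h1"] + counts["n_unmeth_h2"]
    return pd.DataFrame(
        {"chrom": counts["chrom"], "pos": counts["pos"],
         "freq": n_meth / cov, "cov": cov}
    )


def methylation_correlation(
    freqs_a: pd.DataFrame, freqs_b: pd.DataFrame, min_cov: int = 5
) -> tuple[float, int]:
    """Pearson r between two per-site frequency tables over shared sites.

    Tables need columns ``chrom, pos, freq, cov``; only sites meeting
    ``min_cov`` in both are used.  Raises ValueError below 3 shared sites.
    """
    merged = freqs_a.merge(freqs_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    merged = merged[(merged["cov_a"] >= min_cov) & (merged["cov_b"] >= min_cov)]
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared sites meet the coverage threshold")
    r, _ = stats.pearsonr(merged["freq_a"], merged["freq_b"])
    return float(r), int(len(merged))


def summarize_asm(n_total_sites: int, n_asm_sites: int) -> dict:
    """Headline summary: ASM share of all methylation sites, one decimal.

    The percentage is rounded half-up to one decimal place, matching how
    such fractions are conventionally reported.
    """
    if n_total_sites <= 0:
        raise ValueError("n_total_sites must be positive")
    if not 0 <= n_asm_sites <= n_total_sites:
        raise ValueError("n_asm_sites must lie in [0, n_total_sites]")
    pct = Decimal(100 * n_asm_sites) / Decimal(n_total_sites)
    pct = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return {
        "n_total_sites": int(n_total_sites),
        "n_asm_sites": int(n_asm_sites),
        "asm_percent": pct,
    }


def bin_deltas(asm_calls: pd.DataFrame, bin_edges=None) -> dict:
    """Histogram of methylation asymmetry and a maternal/paternal symmetry stat.

    The symmetry statistic |#(delta>0) - #(delta<0)| / n is near 0 when
    hypo/hypermethylation is balanced between haplotypes.
    """
    if bin_edges is None:
        bin_edges = np.linspace(-1.0, 1.0, 9)
    deltas = asm_calls["delta"].to_numpy() if len(asm_calls) else np.empty(0)
    hist, edges = np.histogram(deltas, bins=bin_edges)
    n = deltas.size
    sym = abs(int((deltas > 0).sum()) - int((deltas < 0).sum())) / n if n else 0.0
    return {"bin_edges": edges, "counts": hist, "symmetry_stat": float(sym), "n": int(n)}
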