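"""Genomic-segment annotation, randomization enrichment, conservation strata.

Sites are labelled by a strand-aware precedence over gene models
(promoter > 5'UTR > exon > intron > 3'UTR > downstream > distal intergenic).
Enrichment across chromatin-state or other segment annotations uses a
randomization test in the spirit of the Genomic Association Test: point sites
are re-placed uniformly within a workspace, and the observed overlap is
compared with the permuted distribution (log2 fold with a +0.5 continuity
offset; two-sided empirical p as the doubled min tail).  Conservation scores
are stratified by site category and compared pairwise with Mann-Whitney U.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SEGMENT_LABELS",
    "annotate_sites",
    "interval_enrichment",
    "conservation_strata",
]

SEGMENT_LABELS = [
    "promoter",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "downstream",
    "distal_intergenic",
]
_PRECEDENCE = {lbl: i for i, lbl in enumerate(SEGMENT_LABELS)}


def _gene_feature(pos: int, gene: pd.Series,
                  promoter_upstream_bp: int, promoter_downstream_bp: int,
                  downstream_bp: int) -> str | None:
    """Label of one position relative to one gene, or None if unrelated."""
    fwd = gene["strand"] == "+"
    tss = gene["start"] if fwd else gene["end"] - 1
    if fwd:
        prom_lo, prom_hi = tss - promoter_upstream_bp, tss + promoter_downstream_bp
        down_lo, down_hi = gene["end"], gene["end"] + downstream_bp
    else:
        prom_lo, prom_hi = tss - promoter_downstream_bp + 1, tss + promoter_upstream_bp + 1
        down_lo, down_hi = gene["start"] - downstream_bp, gene["start"]
    if prom_lo <= pos < prom_hi:
        return "promoter"
    if gene["start"] <= pos < gene["end"]:
        in_exon = any(
            s <= pos < e for s, e in zip(gene["exon_starts"], gene["exon_ends"])
        )
        if not in_exon:
            return "intron"
        ts, te = gene["thick_start"], gene["thick_end"]
        if pos < ts:
            return "five_prime_utr" if fwd else "three_prime_utr"
        if pos >= te:
            return "three_prime_utr" if fwd else "five_prime_utr"
        return "exon"
    if down_lo <= pos < down_hi:
        return "downstream"
    return None


def annotate_sites(
    sites: pd.DataFrame,
    gene_model: pd.DataFrame,
    promoter_upstream_bp: int = 2000,
    promoter_downstream_bp: int = 500,
    downstream_bp: int = 2000,
) -> pd.DataFrame:
    """One segment label per site under the fixed precedence.

    The promoter is [TSS - upstream, TSS + downstream) in the transcribed
    orientation.  When several genes assign different labels, the highest-
    precedence one wins; ties go to the gene with the nearest TSS.  Returns
    ``sites`` plus ``label``, ``gene_id`` and signed ``distance_to_tss``
    (positive downstream of the TSS).
    """
    required = {"gene_id", "chrom", "start", "end", "strand",
                "exon_starts", "exon_ends", "thick_start", "thick_end"}
    missing = required - set(gene_model.columns)
    if missing:
        raise ValueError(f"malformed gene model; missing columns {sorted(missing)}")
    genes_by_chrom = {c: g for c, g in gene_model.groupby("chrom")}
    labels, gene_ids, dists = [], [], []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        best = ("distal_intergenic", None, None)
        for _, gene in genes_by_chrom.get(chrom, pd.DataFrame()).iterrows():
            lbl = _gene_feature(
                pos, gene, promoter_upstream_bp, promoter_downstream_bp, downstream_bp
            )
            if lbl is None:
                continue
            tss = gene["start"] if gene["strand"] == "+" else gene["end"] - 1
            d = (pos - tss) if gene["strand"] == "+" else (tss - pos)
            if (
                best[1] is None
                or _PRECEDENCE[lbl] < _PRECEDENCE[best[0]]
                or (_PRECEDENCE[lbl] == _PRECEDENCE[best[0]] and abs(d) < abs(best[2]))
            ):
                best = (lbl, gene["gene_id"], d)
        labels.append(best[0])
        gene_ids.append(best[1])
        dists.append(best[2])
    out = sites.copy()
    out["label"] = labels
    out["gene_id"] = gene_ids
    out["distance_to_tss"] = dists
    return out


def _linearize(workspace: pd.DataFrame):
    """Map workspace intervals onto a concatenated coordinate line."""
    ws = workspace.sort_values(["chrom", "start"]).reset_index(drop=True)
    offsets = np.concatenate([[0], np.cumsum((ws["end"] - ws["start"]).to_numpy())])
    return ws, offsets

def _to_linear(ws: pd.DataFrame, offsets: np.ndarray, chroms, positions) -> np.ndarray:
    out = np.full(len(chroms), -1, dtype=np.int64)
    for i, (c, p) in enumerate(zip(chroms, positions)):
        hit = ws[(ws["chrom"] == c) & (ws["start"] <= p) & (p < ws["end"])]
        if len(hit):
            j = hit.index[0]
            out[i] = offsets[j] + (p - ws["start"].iloc[j])
    return out


def interval_enrichment(
    sites: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    workspace: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomization enrichment of point sites across segment annotations.

    Sites are re-placed uniformly within the workspace ``n_permutations``
    times; per annotation, log2_fold = log2((obs + 0.5) / (mean_perm + 0.5))
    and the empirical p is the doubled smaller tail,
    (1 + #permutations at-or-beyond observed) / (n + 1), capped at 1.
    Annotation segments outside the workspace are clipped with a warning.
    """
    ws, offsets = _linearize(workspace)
    total = int(offsets[-1])
    lin_sites = _to_linear(ws, offsets, sites["chrom"], sites["pos"])
    if np.any(lin_sites < 0):
        raise ValueError("workspace does not cover all sites")
    rng = np.random.default_rng(seed)
    perms = rng.integers(0, total, size=(n_permutations, len(lin_sites)))

    rows = []
    for name, ann in annotations.items():
        # clip annotation segments into workspace linear coordinates
        segs = []
        clipped = False
        for _, seg in ann.iterrows():
            for j, w in ws.iterrows():
                if seg["chrom"] != w["chrom"]:
                    continue
                s = max(seg["start"], w["start"])
                e = min(seg["end"], w["end"])
                if s < e:
                    segs.append((offsets[j] + s - w["start"], offsets[j] + e - w["start"]))
                if seg["start"] < w["start"] or seg["end"] > w["end"]:
                    clipped = True
        if clipped:
            logger.warning("annotation %r extends outside workspace; clipped", name)
        if not segs:
            rows.append((name, 0, np.nan, np.nan, np.nan, n_permutations))
            continue
        segs.sort()
        starts = np.array([s for s, _ in segs])
        ends = np.array([e for _, e in segs])

        def count_in(points: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(starts, points, side="right") - 1
            ok = (idx >= 0) & (points < ends[np.clip(idx, 0, len(ends) - 1)])
            return ok

        observed = int(count_in(lin_sites).sum())
        perm_counts = count_in(perms.ravel()).reshape(n_permutations, -1).sum(axis=1)
        mean_perm = float(perm_counts.mean())
        log2_fold = float(np.log2((observed + 0.5) / (mean_perm + 0.5)))
        upper = int((perm_counts >= observed).sum())
        lower = int((perm_counts <= observed).sum())
        p = min(1.0, 2.0 * (1 + min(upper, lower)) / (n_permutations + 1))
        rows.append((name, observed, mean_perm, log2_fold, p, n_permutations))
    return pd.DataFrame(
        rows,
        columns=["annotation", "observed", "mean_permuted", "log2_fold",
                 "empirical_p", "n_permutations"],
    )


def conservation_strata(
    categories: dict[str, pd.DataFrame],
    score_track: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category conservation summaries and BH-corrected pairwise tests.

    ``categories`` maps a category name (e.g. ASM site, flanking SNV,
    lost CpG) to a chrom/pos table; scores are looked up per base, and bases
    without a score are excluded (counted in ``n_missing``).  Pairwise
    two-sided Mann-Whitney U tests (tie-corrected normal approximation) are
    BH-adjusted; a category pair of identical constants yields p = 1.
    """
    samples: dict[str, np.ndarray] = {}
    rows = []
    for name, sites in categories.items():
        vals, missing = [], 0
        for c, p in zip(sites["chrom"], sites["pos"]):
            track = score_track.get(c)
            if track is None or not 0 <= p < len(track):
                missing += 1
                continue
            vals.append(track[p])
        arr = np.asarray(vals, dtype=float)
        samples[name] = arr
        rows.append(
            (name, arr.size, missing,
             float(arr.mean()) if arr.size else np.nan,
             float(np.median(arr)) if arr.size else np.nan)
        )
    summary = pd.DataFrame(rows, columns=["category", "n", "n_missing", "mean", "median"])

    names = list(samples)
    pair_rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = samples[names[i]], samples[names[j]]
            if a.size == 0 or b.size == 0:
                pair_rows.append((names[i], names[j], np.nan, np.nan))
                continue
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                pair_rows.append((names[i], names[j], np.nan, 1.0))
                continue
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            pair_rows.append((names[i], names[j], float(u), float(p)))
    pairwise = pd.DataFrame(pair_rows, columns=["category_a", "category_b", "u", "p"])
    mask = pairwise["p"].notna()
    pairwise["q"] = np.nan
    if mask.any():
        pairwise.loc[mask, "q"] = multipletests(pairwise.loc[mask, "p"], method="fdr_bh")[1]
    return summary, pairwise
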