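"""Genetic-variant context of allele-specific methylation sites.

Quantifies how heterozygous SNVs distribute around ASM versus matched bulk
(control) methylation sites: windowed SNV density with a bootstrap CI and a
label-permutation p-value, the allele of residence of flanking variants
(hypo- vs hypermethylated haplotype), the 12-type substitution spectrum,
CpG-disrupting ("lost CpG") variants, nearest-neighbour distances, and
center-anchored aggregation profiles against a randomized baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import Reference

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "AggregationProfile",
    "variants_in_windows",
    "window_snv_density",
    "match_controls",
    "allele_of_residence",
    "substitution_spectrum",
    "detect_lost_cpg",
    "cpg_snp_fraction",
    "distance_distribution",
    "aggregation_profile",
]

SUBSTITUTION_TYPES = [
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
]


@dataclass
class EnrichmentResult:
    density_asm: float          # SNVs per kb in ASM windows
    density_control: float      # SNVs per kb in control windows
    fold: float
    ci_low: float
    ci_high: float
    empirical_p: float
    n_asm_windows: int
    n_control_windows: int
    hypo_allele_snvs: int | None = None
    hyper_allele_snvs: int | None = None


@dataclass
class AggregationProfile:
    bin_offsets: np.ndarray     # left edge of each offset bin
    observed: np.ndarray        # mean feature count per bin per center
    baseline: np.ndarray        # same under uniform re-placement
    n_centers: int
    n_permutations: int


def _window_counts(sites: pd.DataFrame, variants: pd.DataFrame, window_bp: int) -> np.ndarray:
    """Number of variants within +/- window_bp of each site (inclusive)."""
    vpos = {c: np.sort(g["pos"].to_numpy()) for c, g in variants.groupby("chrom")}
    out = np.zeros(len(sites), dtype=int)
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        vp = vpos.get(chrom)
        if vp is None:
            continue
        lo, hi = np.searchsorted(vp, [pos - window_bp, pos + window_bp + 1])
        out[i] = hi - lo
    return out


def variants_in_windows(
    variants: pd.DataFrame, sites: pd.DataFrame, window_bp: int = 500
) -> np.ndarray:
    """Boolean mask: variant lies within +/- window_bp of any site."""
    spos = {c: np.sort(g["pos"].to_numpy()) for c, g in sites.groupby("chrom")}
    mask = np.zeros(len(variants), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(variants["chrom"], variants["pos"])):
        sp = spos.get(chrom)
        if sp is None or sp.size == 0:
            continue
        j = np.searchsorted(sp, pos)
        near = min(abs(int(sp[k]) - int(pos)) for k in (j - 1, j) if 0 <= k < sp.size)
        mask[i] = near <= window_bp
    return mask


def window_snv_density(
    asm_sites: pd.DataFrame,
    control_sites: pd.DataFrame,
    variants: pd.DataFrame,
    window_bp: int = 500,
    n_bootstrap: int = 1000,
    n_permutations: int = 1000,
    seed: int = 0,
    exclude_overlapping_controls: bool = True,
) -> EnrichmentResult:
    """SNV density fold change in ASM vs control windows.

    Density per class = total SNVs inside the +/- ``window_bp`` windows
    divided by total window length.  The fold CI is a percentile bootstrap
    (``n_bootstrap`` resamples over windows); the two-sided empirical p comes
    from permuting ASM/control labels across the pooled windows.  Control
    windows intersecting any ASM window are dropped by default so the control
    class measures the background rate.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rng = np.random.default_rng(seed)
    if exclude_overlapping_controls and len(asm_sites):
        apos = {c: np.sort(g["pos"].to_numpy()) for c, g in asm_sites.groupby("chrom")}
        keep = []
        for chrom, pos in zip(control_sites["chrom"], control_sites["pos"]):
            ap = apos.get(chrom)
            if ap is None or ap.size == 0:
                keep.append(True)
                continue
            j = np.searchsorted(ap, pos)
            near = min(
                abs(int(ap[k]) - int(pos)) for k in (j - 1, j) if 0 <= k < ap.size
            )
            keep.append(near > 2 * window_bp)
        control_sites = control_sites[np.asarray(keep, dtype=bool)]

    ca = _window_counts(asm_sites, variants, window_bp).astype(float)
    cc = _window_counts(control_sites, variants, window_bp).astype(float)
    wlen = 2 * window_bp + 1
    density_asm = ca.sum() / (len(ca) * wlen) * 1000.0 if len(ca) else np.nan
    density_control = cc.sum() / (len(cc) * wlen) * 1000.0 if len(cc) else np.nan
    if not len(cc) or cc.sum() == 0:
        logger.warning("control windows carry no SNVs; fold undefined")
        return EnrichmentResult(
            density_asm, density_control, np.nan, np.nan, np.nan, np.nan,
            len(ca), len(cc),
        )
    fold = density_asm / density_control

    boot_a = ca[rng.integers(0, len(ca), size=(n_bootstrap, len(ca)))].mean(axis=1)
    boot_c = cc[rng.integers(0, len(cc), size=(n_bootstrap, len(cc)))].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot_fold = boot_a / boot_c
    boot_fold = boot_fold[np.isfinite(boot_fold)]
    ci_low, ci_high = np.percentile(boot_fold, [2.5, 97.5])

    pooled = np.concatenate([ca, cc])
    na = len(ca)
    obs_stat = abs(np.log(fold))
    perm_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        pa, pc = perm[:na].mean(), perm[na:].mean()
        if pa > 0 and pc > 0:
            stat = abs(np.log(pa / pc))
        else:
            stat = np.inf
        if stat >= obs_stat:
            perm_ge += 1
    empirical_p = (1 + perm_ge) / (n_permutations + 1)

    return EnrichmentResult(
        density_asm=float(density_asm),
        density_control=float(density_control),
        fold=float(fold),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        empirical_p=float(empirical_p),
        n_asm_windows=len(ca),
        n_control_windows=len(cc),
    )


def match_controls(
    asm_sites: pd.DataFrame,
    bulk_sites: pd.DataFrame,
    k_per_site: int = 1,
    coverage: dict[tuple[str, int], float] | None = None,
    cpg_positions: dict[str, np.ndarray] | None = None,
    density_window_bp: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample bulk control sites matched on coverage and CpG-density deciles.

    Strata are (coverage decile, CpG-density decile) over the pooled sites;
    when either covariate is absent the corresponding stratum collapses.
    Controls are drawn without replacement; an exhausted stratum falls back
    to the nearest stratum with a logged warning.
    """
    rng = np.random.default_rng(seed)

    def covariates(df: pd.DataFrame) -> pd.DataFrame:
        out = df[["chrom", "pos"]].copy()
        if coverage is not None:
            out["cov"] = [coverage.get((c, p), 0.0) for c, p in zip(df["chrom"], df["pos"])]
        else:
            out["cov"] = 0.0
        if cpg_positions is not None:
            dens = []
            for c, p in zip(df["chrom"], df["pos"]):
                cp = cpg_positions.get(c, np.empty(0))
                lo, hi = np.searchsorted(cp, [p - density_window_bp, p + density_window_bp + 1])
                dens.append(hi - lo)
            out["cpg_density"] = dens
        else:
            out["cpg_density"] = 0.0
        return out

    a = covariates(asm_sites)
    b = covariates(bulk_sites)
    pooled = pd.concat([a, b], ignore_index=True)

    def decile(series: pd.Series, ref: pd.Series) -> np.ndarray:
        if ref.nunique() <= 1:
            return np.zeros(len(series), dtype=int)
        edges = np.unique(np.quantile(ref, np.linspace(0, 1, 11)))
        return np.clip(np.searchsorted(edges, series, side="right") - 1, 0, len(edges) - 2)

    a_strat = list(zip(decile(a["cov"], pooled["cov"]), decile(a["cpg_density"], pooled["cpg_density"])))
    b_strat = list(zip(decile(b["cov"], pooled["cov"]), decile(b["cpg_density"], pooled["cpg_density"])))

    available: dict[tuple[int, int], list[int]] = {}
    for i, s in enumerate(b_strat):
        available.setdefault(s, []).append(i)
    for pool in available.values():
        rng.shuffle(pool)

    chosen: list[int] = []
    n_fallback = 0
    for s in a_strat:
        for _ in range(k_per_site):
            pool = available.get(s)
            if pool:
                chosen.append(pool.pop())
                continue
            n_fallback += 1
            # nearest non-empty stratum by L1 distance in decile space
            best, best_d = None, None
            for key, p in available.items():
                if not p:
                    continue
                d = abs(key[0] - s[0]) + abs(key[1] - s[1])
                if best_d is None or d < best_d:
                    best, best_d = key, d
            if best is None:
                raise ValueError("bulk pool exhausted; cannot match controls")
            chosen.append(available[best].pop())
    if n_fallback:
        logger.warning("%d control draws fell back to a neighbouring stratum", n_fallback)
    return bulk_sites.iloc[sorted(chosen)].reset_index(drop=True)


def allele_of_residence(
    asm_calls: pd.DataFrame,
    phased_variants: pd.DataFrame,
    window_bp: int = 500,
) -> dict:
    """Tally flanking phased SNVs by hypo- vs hypermethylated allele.

    Each phased variant within +/- ``window_bp`` of an ASM call is attributed
    to the haplotype carrying its alternate allele and counted as hypo- or
    hyper-allele relative to that call's ``hypo_hap``.  Unphased variants are
    counted separately and excluded from the ratio.
    """
    phased = phased_variants[phased_variants["hap_of_alt"].isin(["H1", "H2"])]
    unphased_in_windows = 0
    vpos = {c: g.sort_values("pos") for c, g in phased.groupby("chrom")}
    upos = {
        c: np.sort(g["pos"].to_numpy())
        for c, g in phased_variants[~phased_variants["hap_of_alt"].isin(["H1", "H2"])].groupby("chrom")
    }
    hypo = hyper = 0
    calls = asm_calls[asm_calls["hypo_hap"].isin(["H1", "H2"])]
    for chrom, pos, hypo_hap in zip(calls["chrom"], calls["pos"], calls["hypo_hap"]):
        sub = vpos.get(chrom)
        if sub is not None:
            arr = sub["pos"].to_numpy()
            lo, hi = np.searchsorted(arr, [pos - window_bp, pos + window_bp + 1])
            haps = sub["hap_of_alt"].to_numpy()[lo:hi]
            hypo += int((haps == hypo_hap).sum())
            hyper += int((haps != hypo_hap).sum())
        up = upos.get(chrom)
        if up is not None:
            lo, hi = np.searchsorted(up, [pos - window_bp, pos + window_bp + 1])
            unphased_in_windows += hi - lo
    total = hypo + hyper
    return {
        "hypo_allele_snvs": hypo,
        "hyper_allele_snvs": hyper,
        "unphased_snvs": int(unphased_in_windows),
        "hypo_share": (hypo / total) if total else np.nan,
    }


def substitution_spectrum(variants: pd.DataFrame) -> pd.Series:
    """Fractions over the 12 ordered ref>alt substitution types.

    Types are kept un-collapsed on the reference strand (C>T distinct from
    G>A).  Empty input yields an all-zero spectrum.
    """
    spectrum = pd.Series(0.0, index=SUBSTITUTION_TYPES, name="fraction")
    if len(variants) == 0:
        spectrum.attrs["n"] = 0
        return spectrum
    labels = variants["ref"].str.cat(variants["alt"], sep=">")
    counts = labels.value_counts()
    for t in SUBSTITUTION_TYPES:
        spectrum[t] = counts.get(t, 0) / len(variants)
    spectrum.attrs["n"] = int(len(variants))
    return spectrum


def detect_lost_cpg(reference: Reference, variants: pd.DataFrame) -> pd.DataFrame:
    """Reference CG dinucleotides destroyed by a substitution.

    A CG at forward-C position p is lost on a haplotype iff that haplotype
    carries a substitution at p (the C) or p+1 (the G); heterozygous variants
    lose it on one allele, homozygous on both.  The variant's ``ref`` must
    match the reference sequence.  Variants creating a new CG are not losses.
    ``gt`` column, when present, holds '0/1' (het, default) or '1/1' (hom).
    """
    rows = []
    for chrom, grp in variants.groupby("chrom"):
        seq = reference.chroms[chrom]
        cpgs = reference.cpg_sites[chrom]
        for _, v in grp.iterrows():
            pos = int(v["pos"])
            if str(seq[pos]) != v["ref"]:
                raise ValueError(
                    f"variant ref mismatch at {chrom}:{pos}: "
                    f"reference {seq[pos]!s}, VCF {v['ref']}"
                )
            gt = str(v.get("gt", "0/1")).replace("|", "/")
            klass = "both_alleles" if gt == "1/1" else "one_allele"
            j = np.searchsorted(cpgs, pos)
            if j < len(cpgs) and cpgs[j] == pos and v["alt"] != "C":
                rows.append((chrom, pos, klass))
            elif j > 0 and cpgs[j - 1] == pos - 1 and v["alt"] != "G":
                rows.append((chrom, pos - 1, klass))
    return pd.DataFrame(rows, columns=["chrom", "pos", "klass"]).drop_duplicates(
        subset=["chrom", "pos"], ignore_index=True
    )


def cpg_snp_fraction(asm_calls: pd.DataFrame, variants: pd.DataFrame) -> dict:
    """Fraction of ASM sites with an SNV on either base of the CpG dinucleotide."""
    vkeys = set(zip(variants["chrom"], variants["pos"]))
    n = len(asm_calls)
    hit = sum(
        (c, p) in vkeys or (c, p + 1) in vkeys
        for c, p in zip(asm_calls["chrom"], asm_calls["pos"])
    )
    return {"n_asm": int(n), "n_with_cpg_snv": int(hit),
            "fraction": (hit / n) if n else np.nan}


def distance_distribution(
    asm_sites: pd.DataFrame,
    lost_cpgs: pd.DataFrame,
    chrom_lengths: dict[str, int],
    seed: int = 0,
) -> dict:
    """Nearest lost-CpG distance per ASM site vs randomly placed pseudo-sites.

    The comparison set keeps the per-chromosome ASM site counts but draws
    positions uniformly; the two distance samples are compared with a
    two-sided Mann-Whitney U test.
    """
    if len(asm_sites) == 0 or len(lost_cpgs) == 0:
        raise ValueError("both site sets must be non-empty")
    rng = np.random.default_rng(seed)
    lpos = {c: np.sort(g["pos"].to_numpy()) for c, g in lost_cpgs.groupby("chrom")}

    def nearest(chroms, positions) -> np.ndarray:
        out = []
        for c, p in zip(chroms, positions):
            lp = lpos.get(c)
            if lp is None or lp.size == 0:
                continue
            j = np.searchsorted(lp, p)
            out.append(min(abs(int(lp[k]) - int(p)) for k in (j - 1, j) if 0 <= k < lp.size))
        return np.asarray(out)

    observed = nearest(asm_sites["chrom"], asm_sites["pos"])
    rand_chroms, rand_pos = [], []
    for c, grp in asm_sites.groupby("chrom"):
        n = len(grp)
        rand_chroms.extend([c] * n)
        rand_pos.extend(rng.integers(0, chrom_lengths[c], size=n).tolist())
    random_d = nearest(rand_chroms, rand_pos)
    u, p = stats.mannwhitneyu(observed, random_d, alternative="two-sided")
    return {
        "observed_distances": observed,
        "random_distances": random_d,
        "median_observed": float(np.median(observed)),
        "median_random": float(np.median(random_d)),
        "mannwhitney_u": float(u),
        "p_value": float(p),
    }


def aggregation_profile(
    centers: pd.DataFrame,
    features: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 500,
    bin_bp: int = 50,
    n_permutations: int = 200,
    seed: int = 0,
) -> AggregationProfile:
    """Mean feature count per offset bin around centers, with random baseline.

    The baseline re-places features uniformly within their chromosome and
    averages the same statistic over ``n_permutations`` draws, emulating a
    random-distribution null for spatial colocalization.
    """
    if (2 * window_bp) % bin_bp != 0:
        raise ValueError("bin_bp must divide 2 * window_bp")
    rng = np.random.default_rng(seed)
    edges = np.arange(-window_bp, window_bp + 1, bin_bp)
    cpos = {c: g["pos"].to_numpy() for c, g in centers.groupby("chrom")}
    fpos = {c: np.sort(g["pos"].to_numpy()) for c, g in features.groupby("chrom")}
    n_centers = int(len(centers))

    def profile(fp: dict[str, np.ndarray]) -> np.ndarray:
        hist = np.zeros(len(edges) - 1)
        for chrom, cps in cpos.items():
            fa = fp.get(chrom)
            if fa is None or fa.size == 0:
                continue
            for c in cps:
                lo, hi = np.searchsorted(fa, [c - window_bp, c + window_bp])
                if hi > lo:
                    hist += np.histogram(fa[lo:hi] - c, bins=edges)[0]
        return hist / max(n_centers, 1)

    observed = profile(fpos)
    baseline = np.zeros(len(edges) - 1)
    for _ in range(n_permutations):
        shuffled = {
            c: np.sort(rng.integers(0, chrom_lengths[c], size=arr.size))
            for c, arr in fpos.items()
        }
        baseline += profile(shuffled)
    baseline /= max(n_permutations, 1)
    return AggregationProfile(
        bin_offsets=edges[:-1],
        observed=observed,
        baseline=baseline,
        n_centers=n_centers,
        n_permutations=n_permutations,
    )
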