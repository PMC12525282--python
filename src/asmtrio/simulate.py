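"""Synthetic diploid genome, read, and track generator.

Emulates the data structure of a haplotype-resolved methylation study of a
single individual: a diploid genome with heterozygous SNVs, per-haplotype CpG
methylation states, long reads carrying both allele observations and per-CpG
methylation calls, Mendelian parental genotypes, annotation tracks
(conservation, chromatin states, gene models) and per-gene allele-assigned
expression counts.  Every stochastic feature the downstream analyses measure
(SNV enrichment around allele-specific methylation sites, allele-of-residence
bias toward the hypomethylated haplotype, conservation strata, phasing-error
regions) is injected with a known parameter and recorded in a machine-readable
truth object, so estimators can be validated by parameter recovery.

Randomness is split into independent named streams derived from the master
seed, so changing one knob (e.g. coverage) never perturbs unrelated draws
(e.g. variant placement).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Reference",
    "SimTruth",
    "TaggedRead",
    "simulate_reference",
    "simulate_diploid",
    "simulate_parents",
    "simulate_reads",
    "inject_phasing_errors",
    "simulate_tracks",
    "simulate_gene_models",
    "simulate_allele_counts",
]

_BASES = np.array(["A", "C", "G", "T"])

# Transition partner of each base; remaining two alternates are transversions.
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# Named substreams off the master seed.
_STREAMS = {
    "sequence": 1,
    "variants": 2,
    "parents": 3,
    "reads": 4,
    "errors": 5,
    "tracks": 6,
    "genes": 7,
    "expression": 8,
    "subsample": 9,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named component of the simulation."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its stated ranges."""


@dataclass
class SimConfig:
    """Parameters of one simulated diploid dataset.

    Rates are per kilobase; probabilities are in [0, 1]; lengths in bases.
    ``genome_length`` is the length of each simulated chromosome.
    """

    genome_length: int = 50_000
    n_chromosomes: int = 2
    cpg_rate: float = 10.0            # expected CpGs / kb
    het_snv_rate: float = 1.0         # background heterozygous SNVs / kb
    n_asm_sites: int = 50
    n_bulk_sites: int = 300
    asm_delta: float = 0.5            # methylation difference at ASM sites
    snv_enrichment_fold: float = 4.0  # SNV rate multiplier inside ASM windows
    hypo_allele_bias: float = 0.7     # P(enriched alt allele on hypomethylated hap)
    window_bp: int = 500              # half-window around an ASM site
    coverage: float = 30.0            # mean total read depth (both haplotypes)
    read_length_mean: float = 3000.0
    read_length_sd: float = 1000.0
    meth_call_error: float = 0.05     # per-CpG read-level flip probability
    allele_read_error: float = 0.01   # per-site allele misread probability
    cpg_snv_rate: float = 0.0         # P(an ASM site carries an SNV in its CpG)
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.genome_length < 10_000:
            raise ConfigError("genome_length must be >= 10 kb per chromosome")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be positive")
        if self.cpg_rate < 0 or self.het_snv_rate < 0:
            raise ConfigError("rates must be non-negative")
        if not 0.0 <= self.asm_delta <= 1.0:
            raise ConfigError("asm_delta must lie in [0, 1]")
        if self.snv_enrichment_fold < 1.0:
            raise ConfigError("snv_enrichment_fold must be >= 1")
        if not 0.5 <= self.hypo_allele_bias <= 1.0:
            raise ConfigError("hypo_allele_bias must lie in [0.5, 1]")
        if not 0.0 <= self.meth_call_error < 0.5:
            raise ConfigError("meth_call_error must lie in [0, 0.5)")
        if not 0.0 <= self.allele_read_error <= 1.0:
            raise ConfigError("allele_read_error must lie in [0, 1]")
        if not 0.0 <= self.cpg_snv_rate <= 1.0:
            raise ConfigError("cpg_snv_rate must lie in [0, 1]")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known}).validate()


@dataclass
class Reference:
    """Haploid reference: per-chromosome sequence and CpG site list.

    A CpG site is identified by the 0-based position of the forward-strand C.
    """

    chroms: dict[str, np.ndarray]       # chrom -> array of 'U1' bases
    cpg_sites: dict[str, np.ndarray]    # chrom -> sorted 0-based C positions

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def sequence(self, chrom: str) -> str:
        return "".join(self.chroms[chrom])


@dataclass
class TaggedRead:
    """One simulated long read.

    ``allele_obs`` maps het-site position -> observed base; ``meth_obs`` maps
    CpG position -> 1 (methylated) / 0 (unmethylated).  Coordinates are
    0-based and fall inside ``[start, end)``.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    allele_obs: dict[int, str]
    meth_obs: dict[int, int]
    assigned_hap: str = "untagged"      # H1 | H2 | untagged
    truth_hap: str | None = None        # simulation only

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class SimTruth:
    """Ground truth of one simulated diploid dataset."""

    config: SimConfig
    reference: Reference
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (H1, H2)
    variants: pd.DataFrame   # chrom,pos,ref,alt,hap_of_alt,in_asm_window
    meth: pd.DataFrame       # chrom,pos,prob_h1,prob_h2,kind,hypo_hap
    lost_cpgs: pd.DataFrame  # chrom,pos (forward C of destroyed CG),klass
    parents: pd.DataFrame | None = None  # chrom,pos,father_gt,mother_gt,informative

    @property
    def asm_sites(self) -> pd.DataFrame:
        return self.meth[self.meth["kind"] == "asm"]

    @property
    def bulk_sites(self) -> pd.DataFrame:
        return self.meth[self.meth["kind"] == "bulk"]


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _background_without_cg(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random sequence with every CG dinucleotide rejected."""
    seq = _BASES[rng.integers(0, 4, size=length)]
    # Replacing the G of each CG can create a new CG one base right; iterate.
    while True:
        is_cg = (seq[:-1] == "C") & (seq[1:] == "G")
        hits = np.flatnonzero(is_cg)
        if hits.size == 0:
            return seq
        seq[hits + 1] = np.array(["A", "C", "T"])[rng.integers(0, 3, size=hits.size)]


def simulate_reference(config: SimConfig) -> Reference:
    """Generate a CG-free background and seed CpG dinucleotides into it.

    The number of CpGs per chromosome is Poisson(cpg_rate * length / 1000);
    positions are uniform with a minimum spacing of two bases so each seeded
    site contributes exactly one CG dinucleotide.
    """
    config.validate()
    rng = stream_rng(config.seed, "sequence")
    chroms: dict[str, np.ndarray] = {}
    cpgs: dict[str, np.ndarray] = {}
    for chrom in _chrom_names(config.n_chromosomes):
        length = int(config.genome_length)
        seq = _background_without_cg(rng, length)
        n_cpg = rng.poisson(config.cpg_rate * length / 1000.0)
        if n_cpg > 0:
            cand = np.unique(rng.integers(1, length - 2, size=int(n_cpg * 1.2)))
            # enforce spacing >= 2 so seeded CGs never overlap
            keep = [cand[0]]
            for p in cand[1:]:
                if p - keep[-1] >= 2:
                    keep.append(p)
            pos = np.asarray(keep[: int(n_cpg)], dtype=int)
            seq[pos] = "C"
            seq[pos + 1] = "G"
        else:
            pos = np.empty(0, dtype=int)
        chroms[chrom] = seq
        cpgs[chrom] = np.sort(pos)
    return Reference(chroms=chroms, cpg_sites=cpgs)


def _draw_alt(rng: np.random.Generator, ref: str) -> str:
    """Alternate base under a transition:transversion = 2:1 model."""
    if rng.random() < 2.0 / 3.0:
        return _TRANSITION[ref]
    others = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
    return others[rng.integers(0, 2)]


def simulate_diploid(reference: Reference, config: SimConfig) -> SimTruth:
    """Place ASM/bulk methylation states and heterozygous SNVs on a diploid.

    SNVs follow a two-rate inhomogeneous Bernoulli-per-base model: background
    rate genome-wide and background x ``snv_enrichment_fold`` inside
    +/- ``window_bp`` of each designated ASM site, so the expected window/
    background density ratio equals the configured fold exactly.  Enriched
    variants put the alternate allele on the hypomethylated haplotype of the
    nearest ASM site with probability ``hypo_allele_bias``.
    """
    config.validate()
    rng = stream_rng(config.seed, "variants")
    total_cpg = sum(len(v) for v in reference.cpg_sites.values())
    n_sites = config.n_asm_sites + config.n_bulk_sites
    if n_sites > total_cpg:
        raise ConfigError(
            f"cannot place {n_sites} methylation sites on {total_cpg} CpGs"
        )

    # --- designate ASM / bulk sites over the pooled CpG list ---
    pool = [(c, p) for c, ps in reference.cpg_sites.items() for p in ps]
    idx = rng.choice(len(pool), size=n_sites, replace=False)
    asm_idx = set(idx[: config.n_asm_sites].tolist())
    meth_rows = []
    for i in idx:
        chrom, pos = pool[i]
        if i in asm_idx:
            # per-site asymmetry at least asm_delta; observed ASM asymmetry
            # is strongly skewed toward complete (imprinted-like) imbalance,
            # emulated by a Beta(2,1)-weighted draw on [asm_delta, 1]
            d = config.asm_delta + (1.0 - config.asm_delta) * rng.beta(2.0, 1.0)
            low = rng.uniform(0.0, 1.0 - d)
            high = low + d
            hypo = "H1" if rng.random() < 0.5 else "H2"
            p1, p2 = (low, high) if hypo == "H1" else (high, low)
            meth_rows.append((chrom, int(pos), p1, p2, "asm", hypo))
        else:
            p = rng.beta(0.5, 0.5)
            meth_rows.append((chrom, int(pos), p, p, "bulk", "none"))
    meth = pd.DataFrame(
        meth_rows, columns=["chrom", "pos", "prob_h1", "prob_h2", "kind", "hypo_hap"]
    ).sort_values(["chrom", "pos"], ignore_index=True)

    # --- two-rate SNV placement ---
    var_rows = []
    lost_rows = []
    bg_rate = config.het_snv_rate / 1000.0
    asm_by_chrom = {
        c: g["pos"].to_numpy()
        for c, g in meth[meth["kind"] == "asm"].groupby("chrom")
    }
    hypo_by_chrom = {
        c: g["hypo_hap"].to_numpy()
        for c, g in meth[meth["kind"] == "asm"].groupby("chrom")
    }
    for chrom, seq in reference.chroms.items():
        length = len(seq)
        in_window = np.zeros(length, dtype=bool)
        for p in asm_by_chrom.get(chrom, ()):
            in_window[max(0, p - config.window_bp): p + config.window_bp + 1] = True
        rate = np.where(in_window, bg_rate * config.snv_enrichment_fold, bg_rate)
        hit = rng.random(length) < rate
        cpg_set = reference.cpg_sites[chrom]
        for pos in np.flatnonzero(hit):
            ref_base = str(seq[pos])
            alt = _draw_alt(rng, ref_base)
            if in_window[pos]:
                sites = asm_by_chrom[chrom]
                nearest = int(np.argmin(np.abs(sites - pos)))
                hypo = hypo_by_chrom[chrom][nearest]
                on_hypo = rng.random() < config.hypo_allele_bias
                hap = hypo if on_hypo else ("H2" if hypo == "H1" else "H1")
            else:
                hap = "H1" if rng.random() < 0.5 else "H2"
            var_rows.append(
                (chrom, int(pos), ref_base, alt, hap, bool(in_window[pos]))
            )
            # does the substitution destroy a reference CG dinucleotide?
            j = np.searchsorted(cpg_set, pos)
            if j < len(cpg_set) and cpg_set[j] == pos:      # hit the C
                lost_rows.append((chrom, int(pos), "one_allele"))
            elif j > 0 and cpg_set[j - 1] == pos - 1:       # hit the G
                lost_rows.append((chrom, int(pos - 1), "one_allele"))
    # optionally seed CpG-disrupting SNVs directly at ASM sites: the variant
    # destroys the CpG on the hypomethylated allele, the mechanism by which a
    # genotype difference manifests as apparent allele-specific methylation
    if config.cpg_snv_rate > 0:
        occupied = {(c, p) for c, p, *_ in var_rows}
        for chrom, grp in meth[meth["kind"] == "asm"].groupby("chrom"):
            seq = reference.chroms[chrom]
            for pos, hypo in zip(grp["pos"], grp["hypo_hap"]):
                if rng.random() >= config.cpg_snv_rate:
                    continue
                hit = int(pos) + int(rng.integers(0, 2))  # C or G base
                if (chrom, hit) in occupied or (chrom, hit - 1) in occupied \
                        or (chrom, hit + 1) in occupied:
                    continue
                ref_base = str(seq[hit])
                var_rows.append((chrom, hit, ref_base, _draw_alt(rng, ref_base),
                                 hypo, True))
                occupied.add((chrom, hit))
                lost_rows.append((chrom, int(pos), "one_allele"))
    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "ref", "alt", "hap_of_alt", "in_asm_window"]
    ).sort_values(["chrom", "pos"], ignore_index=True)
    lost = pd.DataFrame(lost_rows, columns=["chrom", "pos", "klass"]).drop_duplicates(
        subset=["chrom", "pos"], ignore_index=True
    )

    # --- haplotype sequences ---
    haplotypes = {}
    for chrom, seq in reference.chroms.items():
        h1, h2 = seq.copy(), seq.copy()
        sub = variants[variants["chrom"] == chrom]
        for pos, alt, hap in zip(sub["pos"], sub["alt"], sub["hap_of_alt"]):
            (h1 if hap == "H1" else h2)[pos] = alt
        haplotypes[chrom] = (h1, h2)

    return SimTruth(
        config=config,
        reference=reference,
        haplotypes=haplotypes,
        variants=variants,
        meth=meth,
        lost_cpgs=lost,
    )


def simulate_parents(
    truth: SimTruth, informative_fraction: float = 1.0, seed: int | None = None
) -> pd.DataFrame:
    """Mendelian-consistent parental genotypes for every child het site.

    For an informative site one parent is homozygous, which makes the child's
    parental origin of the alternate allele unambiguous.  By convention H1 is
    the maternal haplotype: if the alternate resides on H1 the mother carries
    it and the father is homozygous reference, and vice versa.  Uninformative
    sites get both parents heterozygous.
    """
    if not 0.0 <= informative_fraction <= 1.0:
        raise ConfigError("informative_fraction must lie in [0, 1]")
    rng = stream_rng(truth.config.seed if seed is None else seed, "parents")
    rows = []
    for chrom, pos, hap in zip(
        truth.variants["chrom"], truth.variants["pos"], truth.variants["hap_of_alt"]
    ):
        informative = rng.random() < informative_fraction
        if informative:
            carrier = "1/1" if rng.random() < 0.5 else "0/1"
            if hap == "H1":  # maternal alternate
                father, mother = "0/0", carrier
            else:
                father, mother = carrier, "0/0"
        else:
            father = mother = "0/1"
        rows.append((chrom, pos, father, mother, informative))
    parents = pd.DataFrame(
        rows, columns=["chrom", "pos", "father_gt", "mother_gt", "informative"]
    )
    truth.parents = parents
    return parents


def _truncated_normal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: int, hi: int
) -> np.ndarray:
    lengths = rng.normal(mean, sd, size=n)
    return np.clip(np.round(lengths), lo, hi).astype(int)


def simulate_reads(truth: SimTruth, config: SimConfig | None = None) -> list[TaggedRead]:
    """Sample long reads per haplotype at half the total coverage each.

    Allele observations reflect the read's haplotype sequence with
    ``allele_read_error`` flips; methylation calls are Bernoulli draws from the
    site's per-haplotype probability, flipped with ``meth_call_error``.  Read
    lengths are Normal(mean, sd) truncated below at 200 bp.
    """
    config = (config or truth.config).validate()
    if config.coverage <= 0:
        raise ConfigError("coverage must be positive")
    rng = stream_rng(config.seed, "reads")
    var_by_chrom = {
        c: g.reset_index(drop=True) for c, g in truth.variants.groupby("chrom")
    }
    meth_by_chrom = {
        c: g.reset_index(drop=True) for c, g in truth.meth.groupby("chrom")
    }
    reads: list[TaggedRead] = []
    rid = 0
    for chrom, (h1, h2) in truth.haplotypes.items():
        length = len(h1)
        vsub = var_by_chrom.get(chrom)
        msub = meth_by_chrom.get(chrom)
        vpos = vsub["pos"].to_numpy() if vsub is not None else np.empty(0, int)
        mpos = msub["pos"].to_numpy() if msub is not None else np.empty(0, int)
        for hap, hseq in (("H1", h1), ("H2", h2)):
            n_reads = int(np.ceil((config.coverage / 2.0) * length / config.read_length_mean))
            lens = _truncated_normal_lengths(
                rng, n_reads, config.read_length_mean, config.read_length_sd, 200, length
            )
            starts = rng.integers(0, np.maximum(1, length - lens + 1))
            probs = (
                msub["prob_h1"] if hap == "H1" else msub["prob_h2"]
            ).to_numpy() if msub is not None else np.empty(0)
            for s, ln in zip(starts, lens):
                e = int(s + ln)
                allele_obs: dict[int, str] = {}
                lo, hi = np.searchsorted(vpos, [s, e])
                for k in range(lo, hi):
                    p = int(vpos[k])
                    base = str(hseq[p])
                    if rng.random() < config.allele_read_error:
                        ref, alt = vsub["ref"].iat[k], vsub["alt"].iat[k]
                        base = alt if base == ref else ref
                    allele_obs[p] = base
                meth_obs: dict[int, int] = {}
                lo, hi = np.searchsorted(mpos, [s, e])
                for k in range(lo, hi):
                    state = int(rng.random() < probs[k])
                    if rng.random() < config.meth_call_error:
                        state = 1 - state
                    meth_obs[int(mpos[k])] = state
                reads.append(
                    TaggedRead(
                        read_id=f"read{rid:06d}",
                        chrom=chrom,
                        start=int(s),
                        end=e,
                        allele_obs=allele_obs,
                        meth_obs=meth_obs,
                        assigned_hap="untagged",
                        truth_hap=hap,
                    )
                )
                rid += 1
    return reads


def inject_phasing_errors(
    reads: list[TaggedRead],
    complete_region_rate: float,
    partial_region_rate: float,
    partial_flip_fraction: float,
    region_size_bp: int = 10_000,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[TaggedRead], pd.DataFrame]:
    """Corrupt haplotype tags region-wise and return region truth labels.

    The genome is tiled into ``region_size_bp`` windows; a read belongs to the
    region containing its midpoint.  In a *complete* region every read's tag
    is flipped to the opposite haplotype; in a *partial* region a random
    ``partial_flip_fraction`` subset is flipped; elsewhere tags equal truth.
    """
    if complete_region_rate + partial_region_rate > 1.0:
        raise ConfigError("region rates must sum to <= 1")
    rng = stream_rng(seed, "errors")
    if chrom_lengths is None:
        chrom_lengths = {}
        for r in reads:
            chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0), r.end)
    labels = []
    region_class: dict[tuple[str, int], str] = {}
    for chrom, length in sorted(chrom_lengths.items()):
        n_regions = int(np.ceil(length / region_size_bp))
        u = rng.random(n_regions)
        for i in range(n_regions):
            if u[i] < complete_region_rate:
                klass = "complete"
            elif u[i] < complete_region_rate + partial_region_rate:
                klass = "partial"
            else:
                klass = "correct"
            region_class[(chrom, i)] = klass
            labels.append(
                (chrom, i * region_size_bp, min((i + 1) * region_size_bp, length), klass)
            )
    out = []
    flip = {"H1": "H2", "H2": "H1"}
    by_region: dict[tuple[str, int], list[int]] = {}
    for i, r in enumerate(reads):
        by_region.setdefault((r.chrom, r.midpoint // region_size_bp), []).append(i)
    assigned = [r.truth_hap for r in reads]
    for key, members in by_region.items():
        klass = region_class.get(key, "correct")
        if klass == "complete":
            for i in members:
                assigned[i] = flip[reads[i].truth_hap]
        elif klass == "partial":
            n_flip = int(round(partial_flip_fraction * len(members)))
            for i in rng.choice(members, size=n_flip, replace=False):
                assigned[i] = flip[reads[i].truth_hap]
    for r, a in zip(reads, assigned):
        out.append(dataclasses.replace(r, assigned_hap=a))
    label_df = pd.DataFrame(labels, columns=["chrom", "start", "end", "klass"])
    return out, label_df


def simulate_tracks(
    truth: SimTruth,
    conservation_effect: float = 0.3,
    n_states: int = 5,
    seed: int | None = None,
    asm_state_odds: float = 3.0,
    tile_bp: int = 2000,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-base conservation scores and a tiled chromatin-state segmentation.

    Conservation: baseline Uniform(0.3, 0.5) per base, ASM-site bases shifted
    up and lost-CpG bases shifted down by ``conservation_effect`` (clipped to
    [0, 1]), emulating purifying selection at functional methylation sites and
    relaxed constraint at dispensable CpGs.  States: fixed ``tile_bp`` tiles
    labelled E1..En; tiles overlapping an ASM site receive state E1 with its
    odds multiplied by ``asm_state_odds``.
    """
    rng = stream_rng(truth.config.seed if seed is None else seed, "tracks")
    cons: dict[str, np.ndarray] = {}
    asm = truth.asm_sites
    lost = truth.lost_cpgs
    for chrom, seq in truth.reference.chroms.items():
        score = rng.uniform(0.3, 0.5, size=len(seq))
        a = asm.loc[asm["chrom"] == chrom, "pos"].to_numpy()
        l = lost.loc[lost["chrom"] == chrom, "pos"].to_numpy()
        score[a] += conservation_effect
        score[l] -= conservation_effect
        cons[chrom] = np.clip(score, 0.0, 1.0)

    base_p = 1.0 / n_states
    odds = base_p / (1 - base_p) * asm_state_odds
    p_asm_tile = odds / (1 + odds)
    rows = []
    for chrom, seq in truth.reference.chroms.items():
        length = len(seq)
        a = asm.loc[asm["chrom"] == chrom, "pos"].to_numpy()
        for start in range(0, length, tile_bp):
            end = min(start + tile_bp, length)
            has_asm = np.any((a >= start) & (a < end))
            p1 = p_asm_tile if has_asm else base_p
            if rng.random() < p1:
                state = "E1"
            else:
                state = f"E{rng.integers(2, n_states + 1)}"
            rows.append((chrom, start, end, state))
    states = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return cons, states


def simulate_gene_models(
    truth_or_lengths,
    n_genes: int = 20,
    seed: int = 0,
    gene_length: int = 5000,
    n_exons: int = 3,
) -> pd.DataFrame:
    """Non-overlapping multi-exon gene models with UTRs, as a BED12-like table.

    Accepts a :class:`SimTruth` or a ``{chrom: length}`` mapping.  Exon blocks
    split the gene span evenly; the thick (CDS) region trims one sixth of the
    span at each end so both UTRs are exonic.
    """
    if isinstance(truth_or_lengths, SimTruth):
        lengths = truth_or_lengths.reference.chrom_lengths
    else:
        lengths = dict(truth_or_lengths)
    rng = stream_rng(seed, "genes")
    chroms = sorted(lengths)
    rows = []
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    gid = 0
    for chrom in chroms:
        length = lengths[chrom]
        slot = length // per_chrom
        # shrink genes so each fits its slot with breathing room on both sides
        gl = min(gene_length, slot // 2)
        if gl < 600:
            raise ConfigError("genome too small for requested gene models")
        margin = max(100, (slot - gl) // 4)
        for k in range(per_chrom):
            if gid >= n_genes:
                break
            start = k * slot + int(rng.integers(margin, slot - gl - margin + 1))
            end = start + gl
            strand = "+" if rng.random() < 0.5 else "-"
            span = end - start
            exon_len = span // (2 * n_exons - 1)
            exon_starts = [start + 2 * i * exon_len for i in range(n_exons)]
            exon_ends = [s + exon_len for s in exon_starts]
            exon_ends[-1] = end
            rows.append(
                {
                    "gene_id": f"gene{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "thick_start": start + span // 6,
                    "thick_end": end - span // 6,
                    "exon_starts": exon_starts,
                    "exon_ends": exon_ends,
                }
            )
            gid += 1
    return pd.DataFrame(rows)


def simulate_allele_counts(
    n_genes: int = 200,
    n_replicates: int = 3,
    mean_depth: float = 500.0,
    dispersion: float = 1e-4,
    ase_gene_fraction: float = 0.12,
    ase_log2_effect: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene per-replicate haplotype read counts with known ASE truth.

    Null genes draw their H1 share from a Beta centred at 0.5; ASE genes shift
    the mean log-odds by ``ase_log2_effect`` (in log2 units, random sign).
    ``dispersion`` is the beta-binomial overdispersion rho; counts per
    replicate are Binomial(Poisson(mean_depth), share).
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if not 0.0 < dispersion < 1.0:
        raise ConfigError("dispersion must lie in (0, 1)")
    rng = stream_rng(seed, "expression")
    conc = (1.0 - dispersion) / dispersion
    rows = []
    for g in range(n_genes):
        is_ase = rng.random() < ase_gene_fraction
        if is_ase:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            logit = sign * ase_log2_effect * np.log(2.0)
            mu = 1.0 / (1.0 + np.exp(-logit))
        else:
            mu = 0.5
        for rep in range(n_replicates):
            share = rng.beta(mu * conc, (1.0 - mu) * conc)
            depth = rng.poisson(mean_depth)
            h1 = rng.binomial(depth, share)
            rows.append(
                {
                    "gene_id": f"gene{g:04d}",
                    "replicate": rep + 1,
                    "h1": int(h1),
                    "h2": int(depth - h1),
                    "is_ase": bool(is_ase),
                    "true_mu_h1": float(mu),
                }
            )
    return pd.DataFrame(rows)
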