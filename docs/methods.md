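# Methods

## Phasing

**Trio binning.** A child heterozygous SNV is Mendelian-informative when at
least one parent is homozygous, which makes the parental origin of the
alternate allele unambiguous (e.g. child 0/1, father 0/0 ⇒ the alternate is
maternal). H1 is defined as the maternal haplotype throughout; this fixes a
global frame shared by methylation and expression analyses. Sites where the
parental genotypes cannot produce a heterozygous child are flagged as
Mendelian violations and excluded rather than guessed. Because trio phase is
absolute, all informative sites of a chromosome form one phase block;
uninformative sites are simply unphased and do not break blocks.

**Read-based phasing.** For every pair of het sites co-covered by a read,
the read supports *cis* (both alternate or both reference alleles observed)
or *trans*; the pair's edge weight is #cis − #trans. Edges are applied in
descending |weight| into a union–find structure that tracks relative
orientation (parity); edges with |weight| < `min_link` (default 2, avoiding
single-read linkage artifacts) are ignored, as are exact cis/trans ties.
Each component of ≥ 2 sites becomes a phase block whose polarity is fixed
deterministically: the lowest-position site's reference allele defines H1.
All downstream statistics are invariant to a global H1/H2 flip within a
block; switch errors are therefore scored on the *relative* orientation of
adjacent phased sites, strictly within blocks.

**Haplotagging and error taxonomy.** Each read votes once per covered phased
site for the haplotype carrying its observed allele; majority wins, ties or
fewer than `min_votes` (default 1) votes leave the read untagged. Tagging
quality against simulation truth is summarised per `region_size_bp` tile
(default 10 kb, reads assigned by midpoint) through the misassigned fraction
f of tagged reads: *complete misassignment* when f ≥ 0.9, *correct* when
f ≤ 0.1, *partial misassignment* between. The 0.9 threshold is a symmetric,
conservative cut for a qualitative two-class distinction; regions without
tagged reads are reported as unassessed and excluded from rates. N50 is the
block length at which the cumulative length of blocks sorted descending
first reaches half the total.

## ASM calling

Read-level CpG calls of tagged reads are piled into per-site, per-haplotype
methylated/unmethylated counts (reverse-strand observations collapse onto
the forward-strand C; a site is identified by that C's 0-based position).
Sites with ≥ `min_cov_per_hap` (default 5) reads on *both* haplotypes are
tested by a two-sided Fisher exact test on the 2×2 table; sites with a
haplotype at zero or low coverage are reported untestable, never imputed.
Benjamini–Hochberg correction runs over all tested sites, and significance
additionally requires |Δ| ≥ `delta_min` (default 0.25) with α = 0.05. An
exact count-based test was chosen because per-site haplotype counts at
desk-scale coverage are small and discrete; all thresholds are exposed in
the configuration. Reported percentages round half-up to one decimal.

Coverage titration uses binomial thinning (each read kept with probability
target/current), and agreement between coverage levels is the Pearson r of
pooled per-site methylation frequencies over sites covered in both.

## Variant context

SNV density is measured in ±`window_bp` (default 500 bp) windows. The
control class is coverage- and CpG-density-matched bulk (non-ASM) sites,
drawn without replacement from decile strata; control windows intersecting
any ASM window are excluded so the control estimates the background rate —
without this exclusion, controls sitting inside enriched neighbourhoods pull
the fold toward 1. The fold CI is a 1,000-resample percentile bootstrap over
windows; the two-sided empirical p permutes ASM/control labels across the
pooled windows using |log fold| as the statistic. Substitution types are
reported un-collapsed on the reference strand (12 types), since C>T and G>A
carry distinct information relative to the CpG. A reference CG is *lost* on
a haplotype when that haplotype carries any substitution at either base;
variants creating new CGs are not losses. Aggregation profiles bin feature
offsets around centers (50 bp bins by default) and compare against features
uniformly re-placed within their chromosome, averaged over permutations.

## Annotation enrichment and conservation

Sites are labelled by strand-aware precedence promoter > 5'UTR > exon >
intron > 3'UTR > downstream > distal intergenic, with the promoter spanning
[TSS − 2,000, TSS + 500) in the transcribed orientation (conventional
annotation-package defaults; configurable). Enrichment across segment
annotations uses randomization in the spirit of the Genomic Association
Test: since the queried sites are single CpGs, the null re-places them
uniformly in the workspace (no segment-length preservation is needed for
points; the default workspace is the union of provided segments or the whole
assembly). log2 fold uses the mean permuted count with a +0.5 continuity
offset; the empirical p is the doubled smaller tail, (1 + #at-or-beyond)/
(n + 1), capped at 1. Conservation scores are stratified by site category
and compared pairwise with tie-corrected asymptotic Mann–Whitney U tests
under BH correction; a constant track yields p = 1 by the ties policy.

## Allele-specific expression

Haplotagged transcript reads count once for their best-overlap gene (exact
ties dropped). ASE is tested per gene by an exact binomial test of pooled
H1 counts against 0.5 — chosen as a transparent, assumption-light test for
haplotype counts from the same library, in place of a negative-binomial
regression fit — with BH across genes, and significance additionally
requires the per-replicate log-ratio sign to agree in every replicate.
Log-ratios use a 0.5 pseudocount. Expression–methylation coupling is the
Spearman ρ between the pooled log2 allelic ratio and the mean ASM Δ over
promoter CpGs, over genes with both defined; expression and methylation must
share the trio (maternal = H1) frame.

## The synthetic diploid generator

The generator emulates the statistical structure the analyses measure, not
sequencing physics. Per chromosome it builds a CG-free background sequence,
seeds CpG dinucleotides at `cpg_rate` (default 10/kb), designates
`n_asm_sites` ASM and `n_bulk_sites` bulk CpGs, and places heterozygous SNVs
by a two-rate Bernoulli-per-base model: `het_snv_rate` (default 1/kb, a
typical human heterozygosity) genome-wide and `het_snv_rate ×
snv_enrichment_fold` (default 4) inside ±500 bp of ASM sites, so the
expected window/background density ratio equals the configured fold exactly
and fold recovery is analytically checkable. Enriched variants put their
alternate allele on the hypomethylated haplotype of the nearest ASM site
with probability `hypo_allele_bias` (default 0.7). Alternates follow a
transition:transversion = 2:1 model, the genome-average human ratio; with
roughly a quarter of variant positions being reference C this yields a C>T
share near 19% of flanking variants without a dedicated knob. An optional
`cpg_snv_rate` (default 0) plants an SNV directly in the CpG dinucleotide of
that fraction of ASM sites, on the hypomethylated haplotype — the mechanism
by which CpG destruction manifests as apparent ASM.

ASM sites receive per-haplotype methylation probabilities differing by
d = `asm_delta` + (1 − `asm_delta`)·Beta(2,1): the configured value is a
floor on the asymmetry, and the Beta(2,1) weighting skews site asymmetry
toward complete (imprinted-like) imbalance, which is how empirical ASM
asymmetry distributes; bulk sites get equal probabilities drawn from a
bimodal Beta(0.5, 0.5). Reads are sampled per haplotype at half the total
`coverage` (default 30×, past which phasing quality has been observed to
saturate without parental data), lengths Normal(3,000, 1,000) truncated at
200 bp; allele observations flip with `allele_read_error` (default 0.01)
and methylation calls with `meth_call_error` (default 0.05, a free choice —
read-level modified-base callers do not publish a single error rate).
Parental genotypes are generated Mendelian-consistent with the configured
fraction of informative sites. Phasing errors are injected region-wise
(complete regions flip every read's tag, partial regions flip a configured
fraction), with region truth labels emitted. Conservation tracks add/subtract
a configurable offset at ASM/lost-CpG bases over a Uniform(0.3, 0.5)
baseline; chromatin states tile the genome with a designated state whose
odds are multiplied over ASM-containing tiles. Expression counts are
beta-binomial: null genes centred at an H1 share of 0.5, ASE genes shifted
by `ase_log2_effect` in log-odds; the default dispersion is 10⁻⁴, i.e. mild
extra-binomial noise consistent with the pooled exact binomial test being
approximately calibrated. The defaults of 200 genes with 12% ASE at depth
500 over 3 replicates put ~24 true ASE genes in a run, the scale at which
such studies report findings.

All randomness derives from a master seed split into named per-component
streams (sequence, variants, parents, reads, errors, tracks, genes,
expression), so changing one knob never perturbs unrelated draws and a fixed
config reproduces outputs byte-identically.

**What the generator does not model** — and hence what passing tests do not
demonstrate about real data: alignment and mapping error, indels and
structural variants, strand-specific or non-CpG methylation, correlated
methylation of neighbouring CpGs, sequence-composition bias in coverage, and
raw-signal artifacts. Estimator validation here shows correctness of the
statistics under their stated sampling model, not robustness to every
real-data failure mode.

## Numerical choices and degenerate inputs

Fisher p-values come from exact hypergeometric enumeration (scipy); they are
validated against an independent enumeration oracle over all tables with
per-haplotype coverage ≤ 15. Percentile bootstrap CIs discard non-finite
resamples (zero control draws). Permutation p-values use the add-one rule so
p > 0 always. Empty inputs return empty outputs (ASM calling, spectra) or
raise (correlation below 3 shared sites, coupling below 2 genes, distance
analysis with an empty site set). Matching falls back to the nearest
stratum, with a warning, when a stratum is exhausted. The polarity of a
read-based phase block is arbitrary; all reported statistics are invariant
to it.

## Problem sizes

The bundled simulations are desk-scale by design: 2 × 50 kb chromosomes at
30× for the demo pipeline; 2 × 600 kb with 100 ASM sites for fold-recovery
sweeps; 4 × 1.25 Mb with 500 ASM sites for allele-bias recovery; 200 genes ×
3 replicates at depth 500 for ASE. These sizes give each estimator enough
events for its stated tolerance while keeping a full run in seconds on one
CPU.

## Known limitations

The read-based phaser is a greedy linkage algorithm, not MEC-optimal, and is
meant as a realistic baseline against which trio binning is compared rather
than as a competitor to production phasers. The ASM test is per-site; no
region-level smoothing or neighbouring-site borrowing is performed. ASE uses
pooled counts with a direction-consistency guard rather than a per-replicate
dispersion model, and is anti-conservative if between-replicate
overdispersion is large. Annotation precedence assigns exactly one label per
site, which undercounts overlapping features by construction.
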