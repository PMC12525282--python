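"""Haplotype assignment of reads and variants.

Two phasing routes are provided: *trio binning*, which resolves each child
heterozygous variant to its parental chromosome using Mendelian-informative
parental genotypes (H1 is the maternal haplotype by convention), and a
*read-based* linkage route that unites het sites into phase blocks from the
co-occurrence of alleles on individual long reads.  Quality is summarised by
phase-block N50, read-tagging accuracy against simulation truth, switch-error
rate, and a two-class regional error taxonomy distinguishing regions where
all reads are assigned to the wrong haplotype (complete misassignment) from
regions where only a fraction are (partial misassignment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import TaggedRead

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseBlock",
    "PhasingReport",
    "trio_bin",
    "phase_readbased",
    "tag_reads",
    "compute_n50",
    "evaluate_phasing",
    "trio_blocks",
]

_OTHER = {"H1": "H2", "H2": "H1"}


@dataclass
class PhaseBlock:
    """A maximal set of jointly phased heterozygous variants."""

    chrom: str
    variant_positions: list[int]
    block_id: str

    def __post_init__(self):
        self.variant_positions = sorted(self.variant_positions)

    @property
    def start(self) -> int:
        return self.variant_positions[0]

    @property
    def end(self) -> int:
        return self.variant_positions[-1]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PhasingReport:
    n50: int
    read_accuracy: float | None
    switch_error_rate: float | None
    region_calls: pd.DataFrame  # chrom,start,end,n_reads,misassigned_fraction,klass


def trio_bin(child_variants: pd.DataFrame, parental_genotypes: pd.DataFrame) -> pd.DataFrame:
    """Assign parental origin to child het variants from parental genotypes.

    A site is informative iff at least one parent is homozygous so that the
    transmission of the alternate allele is unambiguous.  Mendelian-
    inconsistent sites are flagged (``mendel_ok`` False) and left unassigned.
    Returns a copy of ``child_variants`` with ``parental_origin`` in
    {maternal, paternal, unknown}, ``hap_of_alt`` in {H1, H2, unphased}
    (H1 = maternal) and ``phase_set`` (the chromosome name for assigned sites).
    """
    out = child_variants.copy()
    gt = parental_genotypes.set_index(["chrom", "pos"])
    origins, haps, mendel, phase_sets = [], [], [], []
    n_missing = 0
    for chrom, pos in zip(out["chrom"], out["pos"]):
        try:
            row = gt.loc[(chrom, pos)]
        except KeyError:
            n_missing += 1
            origins.append("unknown")
            haps.append("unphased")
            mendel.append(True)
            phase_sets.append(None)
            continue
        f = str(row["father_gt"]).replace("|", "/")
        m = str(row["mother_gt"]).replace("|", "/")
        fa = f.count("1")
        ma = m.count("1")
        # child is 0/1: needs an alt from one parent and a ref from the other
        consistent = (fa >= 1 and ma <= 1) or (ma >= 1 and fa <= 1)
        origin = "unknown"
        if not consistent:
            mendel.append(False)
        else:
            mendel.append(True)
            if fa == 0 and ma >= 1:
                origin = "maternal"   # father can only give ref
            elif ma == 0 and fa >= 1:
                origin = "paternal"
            elif fa == 2 and ma <= 1:
                origin = "paternal"   # father must give alt
            elif ma == 2 and fa <= 1:
                origin = "maternal"
        origins.append(origin)
        if origin == "maternal":
            haps.append("H1")
            phase_sets.append(chrom)
        elif origin == "paternal":
            haps.append("H2")
            phase_sets.append(chrom)
        else:
            haps.append("unphased")
            phase_sets.append(None)
    if n_missing:
        logger.warning("%d child sites absent from parental tables; marked unknown", n_missing)
    out["parental_origin"] = origins
    out["hap_of_alt"] = haps
    out["phase_set"] = phase_sets
    out["mendel_ok"] = mendel
    return out


def trio_blocks(phased_variants: pd.DataFrame) -> list[PhaseBlock]:
    """Phase blocks of a trio-binned variant set.

    Trio binning places every informative site in the absolute parental
    frame, so all assigned sites of a chromosome form a single block.
    """
    blocks = []
    assigned = phased_variants[phased_variants["hap_of_alt"].isin(["H1", "H2"])]
    for chrom, grp in assigned.groupby("chrom"):
        if len(grp) >= 2:
            blocks.append(
                PhaseBlock(chrom=chrom, variant_positions=grp["pos"].tolist(),
                           block_id=f"trio_{chrom}")
            )
    return blocks


class _ParityUnionFind:
    """Union-find tracking relative haplotype orientation (parity) per site."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n
        self.parity = [0] * n  # orientation relative to parent

    def find(self, x: int) -> tuple[int, int]:
        if self.parent[x] == x:
            return x, 0
        root, par = self.find(self.parent[x])
        self.parent[x] = root
        self.parity[x] ^= par
        return root, self.parity[x]

    def union(self, a: int, b: int, rel: int) -> None:
        ra, pa = self.find(a)
        rb, pb = self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
            pa, pb = pb, pa
        self.parent[rb] = ra
        self.parity[rb] = pa ^ pb ^ rel
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def phase_readbased(
    reads: list[TaggedRead], het_variants: pd.DataFrame, min_link: int = 2
) -> tuple[pd.DataFrame, list[PhaseBlock]]:
    """Phase het sites from allele co-occurrence on long reads.

    For every pair of het sites covered by a read, the read supports *cis*
    (both alternate or both reference alleles) or *trans*; the edge weight is
    #cis - #trans.  Edges are applied in descending \\|weight\\|, skipping those
    with \\|weight\\| < ``min_link``.  Each resulting connected component of two
    or more sites becomes a phase block; polarity within a block is fixed
    deterministically by sending the lowest-position site's reference allele
    to H1 (its alternate to H2).
    """
    variants = het_variants.reset_index(drop=True)
    key_to_idx = {
        (c, p): i for i, (c, p) in enumerate(zip(variants["chrom"], variants["pos"]))
    }
    ref = variants["ref"].to_numpy()
    alt = variants["alt"].to_numpy()

    weights: dict[tuple[int, int], int] = {}
    for read in reads:
        covered = []
        for pos, base in read.allele_obs.items():
            i = key_to_idx.get((read.chrom, pos))
            if i is None:
                continue
            if base == alt[i]:
                covered.append((i, 1))
            elif base == ref[i]:
                covered.append((i, 0))
        covered.sort()
        for a in range(len(covered)):
            for b in range(a + 1, len(covered)):
                (i, ai), (j, aj) = covered[a], covered[b]
                edge = (i, j)
                weights[edge] = weights.get(edge, 0) + (1 if ai == aj else -1)

    uf = _ParityUnionFind(len(variants))
    for (i, j), w in sorted(weights.items(), key=lambda kv: -abs(kv[1])):
        if abs(w) < min_link:
            continue
        # w > 0: alternates in cis (same haplotype, parity 0); w < 0: trans
        uf.union(i, j, 0 if w > 0 else 1)

    comps: dict[int, list[int]] = {}
    for i in range(len(variants)):
        root, _ = uf.find(i)
        comps.setdefault(root, []).append(i)

    out = variants.copy()
    out["hap_of_alt"] = "unphased"
    out["phase_set"] = None
    out["parental_origin"] = "unknown"
    blocks: list[PhaseBlock] = []
    for members in comps.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda i: (variants["chrom"].iat[i], variants["pos"].iat[i]))
        anchor = members[0]
        _, anchor_par = uf.find(anchor)
        chrom = variants["chrom"].iat[anchor]
        block_id = f"{chrom}_{variants['pos'].iat[anchor]}"
        positions = []
        for i in members:
            _, par = uf.find(i)
            # anchor's alternate -> H2 (its reference defines H1)
            out.loc[i, "hap_of_alt"] = "H2" if par == anchor_par else "H1"
            out.loc[i, "phase_set"] = block_id
            positions.append(int(variants["pos"].iat[i]))
        blocks.append(PhaseBlock(chrom=chrom, variant_positions=positions, block_id=block_id))
    return out, blocks


def tag_reads(
    reads: list[TaggedRead], phased_variants: pd.DataFrame, min_votes: int = 1
) -> list[TaggedRead]:
    """Haplotag reads by majority vote over covered phased het sites."""
    phased = phased_variants[phased_variants["hap_of_alt"].isin(["H1", "H2"])]
    lookup = {
        (c, p): (r, a, h)
        for c, p, r, a, h in zip(
            phased["chrom"], phased["pos"], phased["ref"], phased["alt"], phased["hap_of_alt"]
        )
    }
    out = []
    for read in reads:
        votes = {"H1": 0, "H2": 0}
        for pos, base in read.allele_obs.items():
            entry = lookup.get((read.chrom, pos))
            if entry is None:
                continue
            ref, alt, hap_of_alt = entry
            if base == alt:
                votes[hap_of_alt] += 1
            elif base == ref:
                votes[_OTHER[hap_of_alt]] += 1
        if votes["H1"] == votes["H2"] or max(votes.values()) < min_votes:
            hap = "untagged"
        else:
            hap = "H1" if votes["H1"] > votes["H2"] else "H2"
        out.append(replace(read, assigned_hap=hap))
    return out


def compute_n50(blocks) -> int:
    """N50 of phase-block lengths.

    Accepts :class:`PhaseBlock` objects or plain integer lengths.  N50 is the
    length of the block at which the cumulative length of blocks, sorted in
    descending order, first reaches at least half the total length; an empty
    list yields 0.
    """
    lengths = sorted(
        (b.length if isinstance(b, PhaseBlock) else int(b)) for b in blocks
    )
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for ln in reversed(lengths):
        acc += ln
        if acc * 2 >= total:
            return ln
    return lengths[0]


def switch_error_rate(
    phased_variants: pd.DataFrame,
    truth_phase: dict[tuple[str, int], str],
    blocks: list[PhaseBlock] | None = None,
) -> float | None:
    """Fraction of adjacent phased-site pairs with inconsistent orientation.

    Computed strictly within blocks.  A pair is an error when the predicted
    relative orientation (same vs opposite haplotype of the alternates)
    disagrees with the true one, so the statistic is invariant to a global
    H1/H2 flip within each block.  Returns None with no assessable pair.
    """
    assigned = phased_variants[phased_variants["hap_of_alt"].isin(["H1", "H2"])]
    if blocks is None:
        blocks = trio_blocks(phased_variants)
    hap = {
        (c, p): h
        for c, p, h in zip(assigned["chrom"], assigned["pos"], assigned["hap_of_alt"])
    }
    n_pairs = n_err = 0
    for block in blocks:
        prev = None
        for pos in block.variant_positions:
            key = (block.chrom, pos)
            if key not in hap or key not in truth_phase:
                continue
            if prev is not None:
                pred_same = hap[prev] == hap[key]
                true_same = truth_phase[prev] == truth_phase[key]
                n_pairs += 1
                n_err += int(pred_same != true_same)
            prev = key
    return (n_err / n_pairs) if n_pairs else None


def evaluate_phasing(
    tagged_reads: list[TaggedRead],
    region_size_bp: int = 10_000,
    complete_threshold: float = 0.9,
    blocks: list[PhaseBlock] | None = None,
    phased_variants: pd.DataFrame | None = None,
    truth_phase: dict[tuple[str, int], str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> PhasingReport:
    """Score haplotagging against simulation truth with the error taxonomy.

    Per region (genome tiled at ``region_size_bp``; reads assigned by
    midpoint) the misassigned fraction f of tagged reads yields the class:
    ``complete_misassignment`` if f >= ``complete_threshold``, ``correct`` if
    f <= 1 - ``complete_threshold``, else ``partial_misassignment``.  Regions
    with no tagged read are ``unassessed`` and excluded from the rates.
    """
    if not 0.5 < complete_threshold <= 1.0:
        raise ValueError("complete_threshold must lie in (0.5, 1]")
    tagged = [
        r for r in tagged_reads
        if r.assigned_hap in ("H1", "H2") and r.truth_hap in ("H1", "H2")
    ]
    accuracy = (
        sum(r.assigned_hap == r.truth_hap for r in tagged) / len(tagged)
        if tagged else None
    )
    if chrom_lengths is None:
        chrom_lengths = {}
        for r in tagged_reads:
            chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0), r.end)
    stats: dict[tuple[str, int], list[int]] = {}
    for r in tagged:
        key = (r.chrom, r.midpoint // region_size_bp)
        n, bad = stats.get(key, (0, 0))
        stats[key] = (n + 1, bad + int(r.assigned_hap != r.truth_hap))
    rows = []
    for chrom, length in sorted(chrom_lengths.items()):
        for i in range(int(np.ceil(length / region_size_bp))):
            n, bad = stats.get((chrom, i), (0, 0))
            if n == 0:
                f, klass = np.nan, "unassessed"
            else:
                f = bad / n
                if f >= complete_threshold:
                    klass = "complete_misassignment"
                elif f <= 1.0 - complete_threshold:
                    klass = "correct"
                else:
                    klass = "partial_misassignment"
            rows.append(
                (chrom, i * region_size_bp, min((i + 1) * region_size_bp, length),
                 n, f, klass)
            )
    region_calls = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_reads", "misassigned_fraction", "klass"],
    )
    n50 = compute_n50(blocks) if blocks is not None else 0
    ser = None
    if phased_variants is not None and truth_phase is not None:
        ser = switch_error_rate(phased_variants, truth_phase, blocks)
    return PhasingReport(
        n50=n50, read_accuracy=accuracy, switch_error_rate=ser, region_calls=region_calls
    )
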