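"""Coding-effect classification and per-class heterozygosity.

Classifies biallelic SNVs falling inside annotated coding sequence into
synonymous / non-synonymous / nonsense (premature stop) / stop-loss classes,
flags transition pairs compatible with post-mortem deamination damage
(C->T / G->A and their complements), corrects heterozygote counts for a known
false-negative rate, and summarises per-class heterozygosity (Hn, Hs) with
binomial standard errors over Nei-Gojobori-style fractional site counts.

All coordinates are 0-based half-open internally; conversion to the 1-based
conventions of VCF/GFF3 happens only in the format readers/writers.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

_CODON_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_CODON_TABLE.stop_codons)  # TAA, TAG, TGA
_AA = dict(_CODON_TABLE.forward_table)  # codon -> amino acid, stops absent

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

BASES = ("A", "C", "G", "T")

#: severity order used when one site is covered by several transcripts
SEVERITY = {
    "nonsense": 4,
    "stop_loss": 3,
    "nonsynonymous": 2,
    "synonymous": 1,
    "noncoding": 0,
    "unknown": -1,
}


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A transcript: ordered exons (and CDS) on a genomic contig.

    ``exons`` and ``cds`` are tuples of 0-based half-open ``(start, end)``
    intervals sorted by genomic coordinate regardless of strand.  For minus
    strand models, transcript coordinates run from the 3'-most genomic edge,
    i.e. the first codon of translation lies at the highest genomic CDS
    coordinate.
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s, e), (s2, e2) in zip(ivs, ivs[1:]):
                if e > s2:
                    raise ValueError(f"{name} of {self.gene_id} overlap or are unsorted")
        if not self.cds:
            object.__setattr__(self, "cds", self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def junction_offsets(self) -> list[int]:
        """Transcript-space offsets of exon-exon junctions (5'->3')."""
        lengths = [e - s for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        offsets, acc = [], 0
        for ln in lengths[:-1]:
            acc += ln
            offsets.append(acc)
        return offsets

    def transcript_seq(self, genome: Mapping[str, str]) -> str:
        seq = "".join(genome[self.contig][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq.upper()

    def cds_seq(self, genome: Mapping[str, str]) -> str:
        seq = "".join(genome[self.contig][s:e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq.upper()

    def transcript_to_genomic(self, offset: int) -> int:
        """Genomic position of transcript base ``offset`` (0-based, 5'->3')."""
        if not 0 <= offset < self.transcript_length:
            raise IndexError(f"transcript offset {offset} out of range")
        if self.strand == "-":
            offset = self.transcript_length - 1 - offset
        acc = 0
        for s, e in self.exons:
            if offset < acc + (e - s):
                return s + (offset - acc)
            acc += e - s
        raise AssertionError("unreachable")

    def cds_to_genomic(self, offset: int) -> int:
        """Genomic position of CDS base ``offset`` (0-based, 5'->3')."""
        if not 0 <= offset < self.cds_length:
            raise IndexError(f"CDS offset {offset} out of range")
        if self.strand == "-":
            offset = self.cds_length - 1 - offset
        acc = 0
        for s, e in self.cds:
            if offset < acc + (e - s):
                return s + (offset - acc)
            acc += e - s
        raise AssertionError("unreachable")

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to its 0-based offset in the CDS, or None."""
        acc = 0
        offset = None
        for s, e in self.cds:
            if s <= pos < e:
                offset = acc + (pos - s)
                break
            acc += e - s
        if offset is None:
            return None
        if self.strand == "-":
            offset = self.cds_length - 1 - offset
        return offset


# ---------------------------------------------------------------------------
# Codon-level classification
# ---------------------------------------------------------------------------


def classify_codon_change(codon: str, offset: int, alt_base: str, strand: str = "+") -> str:
    """Effect of substituting ``alt_base`` at ``offset`` within a codon.

    ``codon`` is in transcript (coding-strand) space; ``alt_base`` is given on
    the genomic plus strand and is complemented first for minus-strand genes.
    Returns one of synonymous / nonsynonymous / nonsense / stop_loss /
    unknown (ambiguous bases).
    """
    codon = codon.upper()
    alt = alt_base.upper()
    if strand == "-":
        alt = complement(alt)
    if len(codon) != 3 or any(b not in BASES for b in codon) or alt not in BASES:
        return "unknown"
    if not 0 <= offset <= 2:
        raise ValueError(f"codon offset must be 0..2, got {offset}")
    ref_base = codon[offset]
    if alt == ref_base:
        raise ValueError("alt base equals ref base after strand adjustment")
    new = codon[:offset] + alt + codon[offset + 1 :]
    ref_stop, new_stop = codon in STOP_CODONS, new in STOP_CODONS
    if ref_stop and new_stop:
        return "synonymous"
    if new_stop:
        return "nonsense"
    if ref_stop:
        return "stop_loss"
    return "synonymous" if _AA[codon] == _AA[new] else "nonsynonymous"


def is_damage_pair(ref: str, alt: str) -> bool:
    """True iff the unordered allele pair is {A,G} or {C,T}.

    Post-mortem cytosine deamination manifests as C->T (and G->A on the
    opposite strand); excluding both transition pairs removes every SNV that
    could be a damage artefact.
    """
    pair = frozenset((ref.upper(), alt.upper()))
    return pair == frozenset("AG") or pair == frozenset("CT")


# ---------------------------------------------------------------------------
# Variant annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantEffect:
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    gene_id: str | None
    codon_index: int | None
    effect_class: str
    damage_flag: bool


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNV with its called genotype (0-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str


def annotate_variants(
    snps: Iterable[SnpRecord],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[VariantEffect]:
    """Annotate SNVs against gene models; one effect per variant x transcript.

    Variants outside every CDS yield a single ``noncoding`` record.  Records
    whose REF allele disagrees with the genome sequence are rejected and
    logged.
    """
    by_contig: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_contig[g.contig].append(g)

    effects: list[VariantEffect] = []
    n_rejected = 0
    for v in snps:
        ref, alt = v.ref.upper(), v.alt.upper()
        if len(ref) != 1 or len(alt) != 1:
            continue  # only SNVs are classified
        genome_base = genome[v.contig][v.pos].upper()
        if genome_base != ref:
            n_rejected += 1
            logger.warning(
                "REF mismatch at %s:%d (VCF %s, genome %s); record rejected",
                v.contig, v.pos + 1, ref, genome_base,
            )
            continue
        damage = is_damage_pair(ref, alt)
        hit = False
        for g in by_contig.get(v.contig, ()):
            if not (g.start <= v.pos < g.end):
                continue
            cds_off = g.genomic_to_cds(v.pos)
            if cds_off is None:
                continue
            hit = True
            codon_idx, codon_off = divmod(cds_off, 3)
            cds_seq = g.cds_seq(genome)
            codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            cls = classify_codon_change(codon, codon_off, alt, g.strand)
            effects.append(
                VariantEffect(v.contig, v.pos, ref, alt, v.genotype,
                              g.gene_id, codon_idx, cls, damage)
            )
        if not hit:
            effects.append(
                VariantEffect(v.contig, v.pos, ref, alt, v.genotype,
                              None, None, "noncoding", damage)
            )
    if n_rejected:
        logger.warning("%d variant records rejected for REF mismatch", n_rejected)
    return effects


def collapse_by_severity(effects: Iterable[VariantEffect]) -> list[VariantEffect]:
    """Keep one effect per (contig, pos, alt), the most severe across transcripts."""
    best: dict[tuple[str, int, str], VariantEffect] = {}
    for e in effects:
        key = (e.contig, e.pos, e.alt)
        if key not in best or SEVERITY[e.effect_class] > SEVERITY[best[key].effect_class]:
            best[key] = e
    return sorted(best.values(), key=lambda e: (e.contig, e.pos, e.alt))


# ---------------------------------------------------------------------------
# Site counting (NG86-style fractional sites)
# ---------------------------------------------------------------------------


def codon_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional site counts of one codon.

    Each of the three positions contributes the fraction of its three
    possible single-base changes that are synonymous; changes creating a stop
    count as nonsynonymous. The two fractions always sum to 3.
    """
    codon = codon.upper()
    syn = 0.0
    for off in range(3):
        for alt in BASES:
            if alt == codon[off]:
                continue
            if classify_codon_change(codon, off, alt) == "synonymous":
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def count_syn_nonsyn_sites(
    genes: Sequence[GeneModel], genome: Mapping[str, str]
) -> tuple[float, float]:
    """Total fractional synonymous / nonsynonymous site counts over all genes.

    The terminal stop codon is excluded.  A CDS with an internal stop codon
    is skipped and logged.
    """
    l_syn = l_nonsyn = 0.0
    for g in genes:
        seq = g.cds_seq(genome)
        codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if any(c in STOP_CODONS for c in codons):
            logger.warning("gene %s has an internal stop codon; skipped", g.gene_id)
            continue
        for c in codons:
            if any(b not in BASES for b in c):
                continue
            s, n = codon_site_fractions(c)
            l_syn += s
            l_nonsyn += n
    return l_syn, l_nonsyn


# ---------------------------------------------------------------------------
# Heterozygote false-negative correction and H summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrectionConfig:
    """Heterozygote false-negative rates applied to raw counts.

    ``het_fnr_snp`` is the fraction of true heterozygous SNVs missed by the
    genotyper (0.30 for the lower-coverage ancient libraries this models);
    ``het_fnr_del`` the analogous rate for deletion calls (0.005).
    """

    het_fnr_snp: float = 0.30
    het_fnr_del: float = 0.005

    def __post_init__(self):
        for v in (self.het_fnr_snp, self.het_fnr_del):
            if not 0.0 <= v < 1.0:
                raise ValueError(f"false-negative rate must be in [0, 1), got {v}")


def correct_het_undercall(het_count: float, hom_count: float, fnr: float) -> float:
    """Total count after inflating heterozygote calls by 1/(1-fnr)."""
    if not 0.0 <= fnr < 1.0:
        raise ValueError(f"fnr must be in [0, 1), got {fnr}")
    if het_count < 0 or hom_count < 0:
        raise ValueError("counts must be non-negative")
    return hom_count + het_count / (1.0 - fnr)


@dataclass(frozen=True)
class HetSummary:
    label: str
    het_count: float
    callable_sites: float
    H: float
    sigma: float


def heterozygosity_summary(
    effects: Iterable[VariantEffect],
    l_syn: float,
    l_nonsyn: float,
    damage_excluded: bool = False,
    het_fnr: float = 0.0,
) -> dict[str, HetSummary]:
    """Per-class heterozygosity Hs / Hn with binomial standard errors.

    H = (heterozygous sites of the class) / (fractional callable sites of the
    class); sigma = sqrt(H(1-H)/L).  Sites covered by several transcripts are
    counted once at their most severe effect; nonsense changes count toward
    the nonsynonymous class denominator-wise but are tallied separately, so
    Hn here is computed over nonsynonymous (amino-acid-changing, non-stop)
    sites only.  ``het_fnr`` inflates the heterozygote count by 1/(1-fnr).
    """
    if l_syn <= 0 or l_nonsyn <= 0:
        raise ValueError("callable site counts must be positive")
    collapsed = collapse_by_severity(effects)
    counts = {"syn": 0, "nonsyn": 0}
    for e in collapsed:
        if e.genotype != "het":
            continue
        if damage_excluded and e.damage_flag:
            continue
        if e.effect_class == "synonymous":
            counts["syn"] += 1
        elif e.effect_class == "nonsynonymous":
            counts["nonsyn"] += 1
    out: dict[str, HetSummary] = {}
    for label, L in (("syn", l_syn), ("nonsyn", l_nonsyn)):
        het = correct_het_undercall(counts[label], 0.0, het_fnr)
        H = het / L
        sigma = (H * (1.0 - H) / L) ** 0.5
        out[label] = HetSummary(label, het, L, H, sigma)
    return out


def hn_hs_ratio(summaries: Mapping[str, HetSummary]) -> float:
    hs = summaries["syn"].H
    if hs == 0:
        raise ZeroDivisionError("Hs is zero; Hn/Hs undefined")
    return summaries["nonsyn"].H / hs


# ---------------------------------------------------------------------------
# Premature-stop census
# ---------------------------------------------------------------------------


@dataclass
class StopCensus:
    per_sample_genes: dict[str, set[str]] = field(default_factory=dict)
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    shared_sites: int = 0
    shared_genes: int = 0


def stop_codon_census(
    effects_by_sample: Mapping[str, Iterable[VariantEffect]],
    damage_excluded: bool = False,
) -> StopCensus:
    """Genes carrying premature stop codons per sample, plus sharing counts.

    Sharing across samples is reported both at the site level (identical
    contig/position/alt in every sample) and the gene level (same gene hit,
    possibly at independent sites).
    """
    census = StopCensus()
    site_sets: list[set[tuple[str, int, str]]] = []
    for sample, effects in effects_by_sample.items():
        nonsense = [
            e
            for e in collapse_by_severity(effects)
            if e.effect_class == "nonsense" and not (damage_excluded and e.damage_flag)
        ]
        genes = {e.gene_id for e in nonsense if e.gene_id is not None}
        census.per_sample_genes[sample] = genes
        census.per_sample_counts[sample] = len(genes)
        site_sets.append({(e.contig, e.pos, e.alt) for e in nonsense})
    if len(site_sets) >= 2:
        census.shared_sites = len(set.intersection(*site_sets))
        census.shared_genes = len(set.intersection(*census.per_sample_genes.values()))
    return census
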