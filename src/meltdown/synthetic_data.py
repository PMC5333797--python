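"""Synthetic diploid-genome corpus with planted defects and a truth table.

Generates everything the census pipeline consumes, emulating the inputs of
an ancient-genome defect survey at shotgun coverage of roughly 11-17X:

* a random reference contig with non-overlapping multi-exon protein-coding
  genes on both strands (CDS starts with ATG, ends with a stop, no internal
  stops);
* planted SNVs of requested effect classes (synonymous / non-synonymous /
  nonsense, het or hom) plus intergenic background SNVs;
* planted deletions >= 1 kb, heterozygous or homozygous;
* retrocopies of multi-exon genes emitting exon-junction reads, with
  matched transcript-space and genome-space alignments carrying explicit
  alignment-score (AS) tags;
* a per-base depth track with negative-binomial noise, halved depth over
  heterozygous deletions and zero depth over homozygous ones;
* deamination-like damage (C->T / G->A) applied to reads only, never to the
  truth genotypes, so damage filtering can be tested as a confounder.

A fixed seed yields a byte-identical corpus.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import formats
from .coding_effects import (
    BASES,
    GeneModel,
    STOP_CODONS,
    classify_codon_change,
    complement,
    is_damage_pair,
)
from .deletion_caller import DepthTrack

logger = logging.getLogger(__name__)

CONTIG = "chr1"
_NON_STOP_CODONS = sorted(
    c for c in ("".join((a, b, d)) for a in BASES for b in BASES for d in BASES)
    if c not in STOP_CODONS
)
_MIN_GENE_GAP = 500
MISMATCH_PENALTY = 5  # alignment score = aligned bases - penalty * mismatches
MIN_OVERHANG = 10


class PlacementError(ValueError):
    """Requested features do not fit in the genome."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults emulate the ancient-genome study conditions.

    Coverage defaults to 15X with moderate negative-binomial overdispersion
    (the two ancient libraries modelled here were 11X and 17X); reads are
    short (60 bp) as expected for degraded ancient fragments; a quarter of
    planted deletions are homozygous, matching the ~23-24% observed
    homozygous fractions; the damage rate is a per-C/G-base probability of a
    deamination-like substitution in reads.
    """

    genome_length: int = 1_000_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (90, 300)
    intron_len: tuple[int, int] = (200, 1500)
    snp_rate: float = 5e-4
    het_fraction: float = 0.6
    n_syn_snps: int = 60
    n_nonsyn_snps: int = 60
    n_nonsense_snps: int = 12
    deletion_count: int = 20
    deletion_len_range: tuple[int, int] = (1000, 10_000)
    hom_del_fraction: float = 0.25
    retrocopy_count: int = 5
    reads_per_junction: int = 2
    background_read_count: int = 400
    mean_depth: float = 15.0
    depth_dispersion: float = 5.0
    read_len: int = 60
    damage_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for name in ("exons_per_gene", "exon_len", "intron_len", "deletion_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (min, max) range")
        for name in ("het_fraction", "hom_del_fraction", "snp_rate", "damage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.deletion_len_range[0] < 1000:
            raise ValueError("deletions below 1 kb are out of scope; min length >= 1000")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if self.read_len < 2 * MIN_OVERHANG + 1:
            raise ValueError(
                f"read_len must be >= {2 * MIN_OVERHANG + 1} to satisfy junction overhangs"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        raw = json.loads(text)
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


@dataclass(frozen=True)
class DeletionTruth:
    contig: str
    start: int
    end: int
    zygosity: str


@dataclass(frozen=True)
class SnpTruth:
    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str
    effect_class: str
    damage_flag: bool
    gene_id: str | None = None


@dataclass(frozen=True)
class RetrocopyTruth:
    gene_id: str
    introns_removed: int
    insertion_site: int


@dataclass
class TruthSet:
    deletions: list[DeletionTruth] = field(default_factory=list)
    snps: list[SnpTruth] = field(default_factory=list)
    retrocopies: list[RetrocopyTruth] = field(default_factory=list)


@dataclass
class ReadSet:
    """Simulated reads plus their two alignment record sets.

    Alignment records are (qname, reference, pos0, cigar, seq, AS score);
    ``transcript`` references gene ids, ``genome`` references contigs.
    """

    reads: list[tuple[str, str]] = field(default_factory=list)
    transcript: list[tuple[str, str, int, str, str, int]] = field(default_factory=list)
    genome: list[tuple[str, str, int, str, str, int]] = field(default_factory=list)


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Reference and annotation
# ---------------------------------------------------------------------------


def generate_reference_and_annotation(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random reference plus non-overlapping protein-coding gene models.

    Every CDS starts with ATG, ends with a stop codon, has length divisible
    by three and no internal stop; exon order is 5'->3' in transcript space
    on both strands.  Raises PlacementError when the genome cannot hold the
    requested genes.
    """
    rng = _rng(config, 1)
    seq = rng.choice(list("ACGT"), size=config.genome_length)

    # draw gene structures first so the space requirement is known
    structures = []
    for _ in range(config.n_genes):
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, size=k)
        exon_lens[-1] += (3 - exon_lens.sum() % 3) % 3
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, size=max(0, k - 1))
        structures.append((exon_lens, intron_lens))
    spans = [int(e.sum() + i.sum()) for e, i in structures]
    free = config.genome_length - sum(spans) - (config.n_genes + 1) * _MIN_GENE_GAP
    if config.n_genes and free < 0:
        raise PlacementError(
            f"genome of {config.genome_length} bp cannot hold {config.n_genes} genes "
            f"spanning {sum(spans)} bp plus minimum gaps"
        )
    if config.n_genes:
        extra = rng.multinomial(free, np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1)))
    else:
        extra = []

    genes: list[GeneModel] = []
    cursor = 0
    for i, (exon_lens, intron_lens) in enumerate(structures):
        cursor += _MIN_GENE_GAP + int(extra[i])
        exons = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        cursor = pos
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(exon_lens.sum()) // 3
        codons = ["ATG"] + list(rng.choice(_NON_STOP_CODONS, size=n_codons - 2)) + [
            str(rng.choice(sorted(STOP_CODONS)))
        ]
        cds_seq = "".join(codons)
        genomic = cds_seq if strand == "+" else _revcomp(cds_seq)
        for s, e in exons:
            off = _cum(exons, s)
            seq[s:e] = list(genomic[off : off + (e - s)])
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}", contig=CONTIG, strand=strand,
                exons=tuple(exons), cds=tuple(exons),
            )
        )
    genome = {CONTIG: "".join(seq)}
    return genome, genes


def _cum(exons: Sequence[tuple[int, int]], start: int) -> int:
    """Offset of exon starting at ``start`` within the concatenated exons."""
    acc = 0
    for s, e in exons:
        if s == start:
            return acc
        acc += e - s
    raise AssertionError("unreachable")


def _revcomp(s: str) -> str:
    return "".join(complement(b) for b in reversed(s))


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


def plant_variant_set(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    config: SyntheticConfig,
) -> TruthSet:
    """Plant deletions, classed coding SNVs, background SNVs and retrocopies.

    Raises PlacementError when a requested effect class cannot be satisfied
    from the available codons (the shortfall is reported in the message).
    """
    rng = _rng(config, 2)
    L = len(genome[CONTIG])
    truth = TruthSet()

    # --- deletions: non-overlapping, >= 1 kb, away from the contig ends
    margin = 1000
    tries = 0
    while len(truth.deletions) < config.deletion_count:
        tries += 1
        if tries > 200 * max(1, config.deletion_count):
            raise PlacementError(
                f"placed only {len(truth.deletions)}/{config.deletion_count} deletions"
            )
        dl = int(rng.integers(config.deletion_len_range[0], config.deletion_len_range[1] + 1))
        if L - margin - dl <= margin:
            raise PlacementError("genome too small for requested deletion lengths")
        start = int(rng.integers(margin, L - margin - dl))
        iv = (start, start + dl)
        if any(iv[0] < d.end + 1000 and d.start - 1000 < iv[1] for d in truth.deletions):
            continue
        zyg = "hom" if rng.random() < config.hom_del_fraction else "het"
        truth.deletions.append(DeletionTruth(CONTIG, iv[0], iv[1], zyg))
    deleted = [(d.start, d.end) for d in truth.deletions]

    def in_deleted(pos: int) -> bool:
        return any(s <= pos < e for s, e in deleted)

    # --- coding SNVs per effect class, verified against the classifier
    used_positions: set[int] = set()
    eligible = [g for g in genes if g.cds_length >= 9]
    requests = (
        ("synonymous", config.n_syn_snps),
        ("nonsynonymous", config.n_nonsyn_snps),
        ("nonsense", config.n_nonsense_snps),
    )
    for wanted, count in requests:
        placed = 0
        tries = 0
        while placed < count:
            tries += 1
            if tries > 5000 * max(1, count):
                raise PlacementError(
                    f"only {placed}/{count} {wanted} SNVs could be planted"
                )
            if not eligible:
                raise PlacementError(f"no genes available for {wanted} SNVs")
            g = eligible[int(rng.integers(len(eligible)))]
            cds_seq = g.cds_seq(genome)
            n_codons = len(cds_seq) // 3
            codon_idx = int(rng.integers(1, n_codons - 1))  # skip start and stop codons
            offset = int(rng.integers(3))
            codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            tx_ref = codon[offset]
            tx_alt = str(rng.choice([b for b in BASES if b != tx_ref]))
            if classify_codon_change(codon, offset, tx_alt) != wanted:
                continue
            gpos = g.cds_to_genomic(codon_idx * 3 + offset)
            if gpos in used_positions or in_deleted(gpos):
                continue
            if g.strand == "+":
                ref, alt = tx_ref, tx_alt
            else:
                ref, alt = complement(tx_ref), complement(tx_alt)
            assert genome[CONTIG][gpos] == ref
            genotype = "het" if rng.random() < config.het_fraction else "hom"
            used_positions.add(gpos)
            truth.snps.append(
                SnpTruth(CONTIG, gpos, ref, alt, genotype, wanted,
                         is_damage_pair(ref, alt), g.gene_id)
            )
            placed += 1

    # --- intergenic background SNVs at snp_rate
    gene_ivs = [(g.start, g.end) for g in genes]
    n_bg = rng.binomial(L, config.snp_rate)
    positions = rng.choice(L, size=min(n_bg, L), replace=False)
    for pos in sorted(int(p) for p in positions):
        if pos in used_positions or in_deleted(pos):
            continue
        if any(s <= pos < e for s, e in gene_ivs):
            continue
        ref = genome[CONTIG][pos]
        if ref not in BASES:
            continue
        alt = str(rng.choice([b for b in BASES if b != ref]))
        genotype = "het" if rng.random() < config.het_fraction else "hom"
        used_positions.add(pos)
        truth.snps.append(
            SnpTruth(CONTIG, pos, ref, alt, genotype, "noncoding",
                     is_damage_pair(ref, alt), None)
        )

    # --- retrocopies of multi-exon genes (need >= 2 introns)
    candidates = [g for g in genes if g.n_introns >= 2]
    if len(candidates) < config.retrocopy_count:
        raise PlacementError(
            f"only {len(candidates)} genes with >= 2 introns available for "
            f"{config.retrocopy_count} retrocopies"
        )
    chosen = rng.choice(len(candidates), size=config.retrocopy_count, replace=False)
    for ci in sorted(int(c) for c in chosen):
        g = candidates[ci]
        truth.retrocopies.append(
            RetrocopyTruth(g.gene_id, g.n_introns, int(rng.integers(0, L)))
        )
    truth.snps.sort(key=lambda s: (s.contig, s.pos))
    return truth


# ---------------------------------------------------------------------------
# Depth track
# ---------------------------------------------------------------------------


def render_depth_track(
    genome: Mapping[str, str],
    truth: TruthSet,
    config: SyntheticConfig,
) -> list[DepthTrack]:
    """Per-base coverage: NB(mean, dispersion) baseline, halved (binomially
    thinned) over heterozygous deletions, zero over homozygous ones."""
    rng = _rng(config, 3)
    tracks = []
    for contig, seq in genome.items():
        n = len(seq)
        k = config.depth_dispersion
        p = k / (k + config.mean_depth)
        depth = rng.negative_binomial(k, p, size=n).astype(np.int64)
        for d in truth.deletions:
            if d.contig != contig:
                continue
            if d.zygosity == "hom":
                depth[d.start:d.end] = 0
            else:
                depth[d.start:d.end] = rng.binomial(depth[d.start:d.end], 0.5)
        mask = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
        tracks.append(DepthTrack(contig, depth, mask))
    return tracks


# ---------------------------------------------------------------------------
# Junction and background reads
# ---------------------------------------------------------------------------


def _apply_damage(seq: str, rate: float, rng: np.random.Generator) -> str:
    """C->T / G->A substitutions at per-base probability ``rate``."""
    if rate <= 0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if b == "C" and rng.random() < rate:
            out[i] = "T"
        elif b == "G" and rng.random() < rate:
            out[i] = "A"
    return "".join(out)


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def render_junction_reads(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    truth: TruthSet,
    config: SyntheticConfig,
) -> ReadSet:
    """Reads supporting planted retrocopies, plus genomic background reads.

    Each retrocopy emits ``reads_per_junction`` reads per exon-exon junction,
    positioned with at least 12 bp on each side of the junction.  Junction
    reads receive a transcript-space alignment (full length) and a
    genome-space alignment of their longest single-exon piece (soft-clipped),
    so their transcript score exceeds their genomic score.  Background reads
    sampled from the intron-containing genome get a full-length genomic
    alignment and, when they lie inside one exon, an equally scoring
    transcript alignment.  Scores are aligned bases minus 5 per mismatch;
    mismatches arise only from damage substitutions.
    """
    rng = _rng(config, 4)
    by_id = {g.gene_id: g for g in genes}
    L = config.read_len
    pad = MIN_OVERHANG + 2
    rs = ReadSet()
    n_read = 0

    for rc in truth.retrocopies:
        g = by_id[rc.gene_id]
        tx = g.transcript_seq(genome)
        junctions = g.junction_offsets()
        for j_idx, j in enumerate(junctions):
            for _ in range(config.reads_per_junction):
                lo = max(0, j - L + pad)
                hi = min(len(tx) - L, j - pad)
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                source = tx[start : start + L]
                read = _apply_damage(source, config.damage_rate, rng)
                qname = f"read{n_read:06d}"
                n_read += 1
                rs.reads.append((qname, read))
                as_tx = L - MISMATCH_PENALTY * _mismatches(read, source)
                rs.transcript.append((qname, g.gene_id, start, f"{L}M", read, as_tx))
                # genomic best hit: the longest piece bounded by junctions
                cuts = [start] + [c for c in junctions if start < c < start + L] + [start + L]
                pieces = [(a - start, b - start) for a, b in zip(cuts, cuts[1:])]
                pa, pb = max(pieces, key=lambda p: p[1] - p[0])
                piece_src = source[pa:pb]
                piece_read = read[pa:pb]
                as_gen = (pb - pa) - MISMATCH_PENALTY * _mismatches(piece_read, piece_src)
                gpos = min(
                    g.transcript_to_genomic(start + pa),
                    g.transcript_to_genomic(start + pb - 1),
                )
                cigar = _clipped_cigar(pa, pb - pa, L)
                rs.genome.append((qname, g.contig, gpos, cigar, read, as_gen))

    # background reads from the intron-containing genome
    contig = CONTIG
    glen = len(genome[contig])
    exon_index = []
    for g in genes:
        acc = 0
        ordered = g.exons if g.strand == "+" else g.exons[::-1]
        for s, e in ordered:
            exon_index.append((s, e, g, acc))
            acc += e - s
    for _ in range(config.background_read_count):
        pos = int(rng.integers(0, glen - L))
        source = genome[contig][pos : pos + L]
        if "N" in source:
            continue
        read = _apply_damage(source, config.damage_rate, rng)
        qname = f"read{n_read:06d}"
        n_read += 1
        rs.reads.append((qname, read))
        as_gen = L - MISMATCH_PENALTY * _mismatches(read, source)
        rs.genome.append((qname, contig, pos, f"{L}M", read, as_gen))
        # transcript hit when the read lies inside one exon
        for s, e, g, acc in exon_index:
            if pos >= s and pos + L <= e:
                if g.strand == "+":
                    tx_start = acc + (pos - s)
                    tx_read, tx_src = read, source
                else:
                    tx_start = acc + (e - (pos + L))
                    tx_read, tx_src = _revcomp(read), _revcomp(source)
                as_tx = L - MISMATCH_PENALTY * _mismatches(tx_read, tx_src)
                rs.transcript.append((qname, g.gene_id, tx_start, f"{L}M", tx_read, as_tx))
                break
    return rs


def _clipped_cigar(clip_left: int, matched: int, read_len: int) -> str:
    clip_right = read_len - clip_left - matched
    parts = []
    if clip_left:
        parts.append(f"{clip_left}S")
    parts.append(f"{matched}M")
    if clip_right:
        parts.append(f"{clip_right}S")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Corpus assembly and emission
# ---------------------------------------------------------------------------


@dataclass
class Corpus:
    config: SyntheticConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: TruthSet
    tracks: list[DepthTrack]
    reads: ReadSet


def generate_corpus(config: SyntheticConfig) -> Corpus:
    """Run the whole generator pipeline in memory."""
    genome, genes = generate_reference_and_annotation(config)
    truth = plant_variant_set(genome, genes, config)
    tracks = render_depth_track(genome, truth, config)
    reads = render_junction_reads(genome, genes, truth, config)
    return Corpus(config, genome, genes, truth, tracks, reads)


def emit_truth_and_files(corpus: Corpus, outdir: str | Path) -> dict[str, str]:
    """Write the corpus in standard formats; returns the checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = corpus.genome, corpus.genes, corpus.truth
    contig_lengths = {c: len(s) for c, s in genome.items()}

    formats.write_fasta(genome, outdir / "reference.fa")
    formats.write_fasta(
        {g.gene_id: g.transcript_seq(genome) for g in genes}, outdir / "transcripts.fa"
    )
    formats.write_gff3(genes, outdir / "annotation.gff3")
    formats.write_vcf(truth.snps, contig_lengths, outdir / "variants.vcf")
    formats.write_bedgraph(corpus.tracks, outdir / "depth.bedGraph")
    formats.write_sam(
        corpus.reads.transcript,
        {g.gene_id: g.transcript_length for g in genes},
        outdir / "reads_transcripts.sam",
    )
    formats.write_sam(corpus.reads.genome, contig_lengths, outdir / "reads_genome.sam")
    formats.write_deletion_bed(truth.deletions, outdir / "truth_deletions.bed")
    with open(outdir / "truth_snps.tsv", "w") as fh:
        fh.write("contig\tpos\tref\talt\tgenotype\teffect_class\tdamage_flag\tgene_id\n")
        for s in truth.snps:
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.genotype}\t"
                f"{s.effect_class}\t{int(s.damage_flag)}\t{s.gene_id or '.'}\n"
            )
    with open(outdir / "truth_retrocopies.tsv", "w") as fh:
        fh.write("gene_id\tintrons_removed\tinsertion_site\n")
        for r in truth.retrocopies:
            fh.write(f"{r.gene_id}\t{r.introns_removed}\t{r.insertion_site}\n")
    with open(outdir / "config.json", "w") as fh:
        fh.write(corpus.config.to_json() + "\n")

    files = [p for p in outdir.iterdir() if p.name != "manifest.json"]
    return formats.write_manifest(files, outdir / "manifest.json")
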