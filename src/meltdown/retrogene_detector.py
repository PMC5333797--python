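"""Retrogene (processed-pseudogene) detection from exon-junction reads.

A retrocopy is an intron-less, reverse-transcribed gene copy reinserted into
the genome.  Genomic DNA reads derived from a retrocopy align contiguously
across exon-exon junctions of the parent transcript, whereas reads from the
intact intron-containing locus cannot.  The caller therefore:

1. collects reads aligned to transcript sequences whose aligned span crosses
   at least one exon-exon junction with >= 10 aligned bases on each side;
2. discards any junction read whose best genomic alignment scores at least
   as well as its transcript alignment (ties discard: the read is explained
   by the intact locus);
3. calls a gene a candidate retrogene when the surviving reads support loss
   of two or more introns (distinct junctions) with three or more distinct
   junction reads in total.

Overhang is measured in aligned (matched) bases; soft-clipped bases do not
count.  Alignment scores are taken from the standard ``AS`` tag, using the
maximum over multiple genomic alignments of the same read.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

from .coding_effects import GeneModel

logger = logging.getLogger(__name__)

MIN_OVERHANG = 10
MIN_READS = 3
MIN_INTRONS = 2


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    gene_id: str
    junction_index: int  # 0-based intron ordinal in transcript orientation
    left_overhang: int
    right_overhang: int
    transcript_score: int
    genomic_score: int | None = None


@dataclass(frozen=True)
class RetrogeneCall:
    gene_id: str
    junctions: tuple[int, ...]
    n_reads: int

    @property
    def introns_lost(self) -> int:
        return len(self.junctions)


def _aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference-coordinate blocks of aligned (M/=/X) bases."""
    return read.get_blocks()


def find_junction_reads(
    alignments: str | Iterable[pysam.AlignedSegment],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    min_overhang: int = MIN_OVERHANG,
) -> list[JunctionRead]:
    """Junction-spanning reads from transcript-space alignments.

    ``alignments`` is a SAM path or an iterable of aligned segments whose
    reference names are gene ids.  One JunctionRead is emitted per
    (read, junction) crossed with >= ``min_overhang`` aligned bases on each
    side; a read spanning two junctions yields two records.
    """
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}
    junction_map = {gid: g.junction_offsets() for gid, g in genes.items()}

    close = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments, "r", check_sq=False)
        close = True
    out: list[JunctionRead] = []
    n_unknown = n_noscore = 0
    try:
        for read in alignments:
            if read.is_unmapped:
                continue
            gid = read.reference_name
            if gid not in junction_map:
                n_unknown += 1
                continue
            try:
                score = read.get_tag("AS")
            except KeyError:
                n_noscore += 1
                continue
            blocks = _aligned_blocks(read)
            if not blocks:
                continue
            for j_idx, j_pos in enumerate(junction_map[gid]):
                left = sum(min(e, j_pos) - s for s, e in blocks if s < j_pos)
                right = sum(e - max(s, j_pos) for s, e in blocks if e > j_pos)
                if left >= min_overhang and right >= min_overhang:
                    out.append(
                        JunctionRead(
                            read_id=read.query_name,
                            gene_id=gid,
                            junction_index=j_idx,
                            left_overhang=left,
                            right_overhang=right,
                            transcript_score=int(score),
                        )
                    )
    finally:
        if close:
            alignments.close()
    if n_unknown:
        logger.warning("%d alignments to unknown transcripts skipped", n_unknown)
    if n_noscore:
        logger.warning("%d alignments without AS score tag rejected", n_noscore)
    return out


def best_genomic_scores(
    alignments: str | Iterable[pysam.AlignedSegment],
) -> dict[str, int]:
    """Best (maximum) AS alignment score per read id from a genomic SAM."""
    close = False
    if isinstance(alignments, str):
        alignments = pysam.AlignmentFile(alignments, "r", check_sq=False)
        close = True
    best: dict[str, int] = {}
    n_noscore = 0
    try:
        for read in alignments:
            if read.is_unmapped:
                continue
            try:
                score = int(read.get_tag("AS"))
            except KeyError:
                n_noscore += 1
                continue
            name = read.query_name
            if name not in best or score > best[name]:
                best[name] = score
    finally:
        if close:
            alignments.close()
    if n_noscore:
        logger.warning("%d genomic alignments without AS score tag ignored", n_noscore)
    return best


def filter_by_genomic_alignment(
    junction_reads: Iterable[JunctionRead],
    genomic_scores: Mapping[str, int],
) -> list[JunctionRead]:
    """Discard junction reads aligning equally or better to the genome.

    A read whose best genomic alignment score is >= its transcript score is
    explained by the intact intron-containing locus; ties discard.  Reads
    with no genomic alignment are retained.
    """
    kept = []
    for jr in junction_reads:
        g = genomic_scores.get(jr.read_id)
        if g is not None and g >= jr.transcript_score:
            continue
        kept.append(
            JunctionRead(
                jr.read_id, jr.gene_id, jr.junction_index,
                jr.left_overhang, jr.right_overhang, jr.transcript_score, g,
            )
        )
    return kept


def call_retrogenes(
    junction_reads: Iterable[JunctionRead],
    min_reads: int = MIN_READS,
    min_introns: int = MIN_INTRONS,
) -> list[RetrogeneCall]:
    """Genes with >= ``min_introns`` distinct junctions and >= ``min_reads``
    distinct supporting reads."""
    by_gene: dict[str, list[JunctionRead]] = defaultdict(list)
    for jr in junction_reads:
        by_gene[jr.gene_id].append(jr)
    calls = []
    for gid in sorted(by_gene):
        reads = by_gene[gid]
        junctions = sorted({jr.junction_index for jr in reads})
        n_reads = len({jr.read_id for jr in reads})
        if len(junctions) >= min_introns and n_reads >= min_reads:
            calls.append(RetrogeneCall(gid, tuple(junctions), n_reads))
    return calls


def detect_retrogenes(
    transcript_sam: str,
    genome_sam: str,
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
    min_overhang: int = MIN_OVERHANG,
    min_reads: int = MIN_READS,
    min_introns: int = MIN_INTRONS,
) -> list[RetrogeneCall]:
    """End-to-end: junction reads -> genomic-alignment filter -> calls."""
    jreads = find_junction_reads(transcript_sam, genes, min_overhang)
    scores = best_genomic_scores(genome_sam)
    kept = filter_by_genomic_alignment(jreads, scores)
    return call_retrogenes(kept, min_reads, min_introns)
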