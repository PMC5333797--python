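"""Readers and writers for the standard formats at the package boundary.

Internal coordinates are 0-based half-open everywhere; GFF3 and VCF are
1-based inclusive on disk, BED/bedGraph 0-based half-open.  Conversions
happen here and nowhere else.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coding_effects import GeneModel, SnpRecord
from .deletion_caller import DeletionCall, DepthTrack

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            cols = [g.contig, "meltdown", "gene", str(g.start + 1), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(cols + [f"ID={g.gene_id}"]) + "\n")
            mrna = f"{g.gene_id}.t1"
            cols[2] = "mRNA"
            fh.write("\t".join(cols + [f"ID={mrna};Parent={g.gene_id}"]) + "\n")
            for i, (s, e) in enumerate(g.exons):
                row = [g.contig, "meltdown", "exon", str(s + 1), str(e), ".", g.strand, ".",
                       f"ID={mrna}.exon{i};Parent={mrna}"]
                fh.write("\t".join(row) + "\n")
            # CDS phase: number of bases to skip to reach the next codon start
            phase = 0
            cds = g.cds if g.strand == "+" else g.cds[::-1]
            for i, (s, e) in enumerate(cds):
                row = [g.contig, "meltdown", "CDS", str(s + 1), str(e), ".", g.strand,
                       str(phase), f"ID={mrna}.cds;Parent={mrna}"]
                fh.write("\t".join(row) + "\n")
                phase = (3 - ((e - s) - phase) % 3) % 3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (one per mRNA) from a GFF3 file."""
    mrna_parent: dict[str, str] = {}
    mrna_meta: dict[str, tuple[str, str]] = {}  # mrna -> (contig, strand)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            contig, _, ftype, start, end, _, strand, _, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            iv = (int(start) - 1, int(end))
            if ftype == "mRNA":
                mid = attr["ID"]
                mrna_parent[mid] = attr.get("Parent", mid)
                mrna_meta[mid] = (contig, strand)
            elif ftype in ("exon", "CDS"):
                parent = attr.get("Parent")
                target = exons if ftype == "exon" else cds
                target.setdefault(parent, []).append(iv)
    genes = []
    for mid, (contig, strand) in mrna_meta.items():
        genes.append(
            GeneModel(
                gene_id=mrna_parent[mid],
                contig=contig,
                strand=strand,
                exons=tuple(sorted(exons.get(mid, []))),
                cds=tuple(sorted(cds.get(mid, []))),
            )
        )
    return sorted(genes, key=lambda g: (g.contig, g.start))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    snps: Iterable,
    contig_lengths: Mapping[str, int],
    path: str | Path,
    sample: str = "sample1",
) -> None:
    """Write biallelic SNVs with a GT field.  ``snps`` need contig, pos
    (0-based), ref, alt and genotype ('het'|'hom') attributes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in sorted(snps, key=lambda v: (v.contig, v.pos)):
            gt = "0/1" if v.genotype == "het" else "1/1"
            fh.write(f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}\n")


def read_vcf_snps(path: str | Path) -> list[SnpRecord]:
    """Read biallelic SNVs (multi-allelic records are split per ALT)."""
    out: list[SnpRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            sample = rec.samples[0] if rec.samples else None
            gt = sample["GT"] if sample is not None else None
            for ai, alt in enumerate(rec.alts, start=1):
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue
                if gt is not None and None not in gt:
                    n_alt = sum(1 for a in gt if a == ai)
                    if n_alt == 0:
                        continue
                    genotype = "hom" if n_alt == len(gt) else "het"
                else:
                    genotype = "het"
                out.append(SnpRecord(rec.contig, rec.pos - 1, rec.ref, alt, genotype))
    return out


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------


def write_bedgraph(tracks: Sequence[DepthTrack] | DepthTrack, path: str | Path) -> None:
    """Run-length encoded per-base depth, 0-based half-open."""
    if isinstance(tracks, DepthTrack):
        tracks = [tracks]
    with open(path, "w") as fh:
        for track in tracks:
            d = np.asarray(track.depth)
            if len(d) == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(d)]])
            for s, e in zip(starts, ends):
                fh.write(f"{track.contig}\t{s}\t{e}\t{int(d[s])}\n")


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-base depth arrays per contig (positions absent from the file get 0)."""
    depth = {name: np.zeros(length, dtype=np.int64) for name, length in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, value = line.split()[:4]
            depth[contig][int(start):int(end)] = int(float(value))
    return depth


def write_deletion_bed(calls: Sequence, path: str | Path) -> None:
    """BED6+ of deletion calls or truth intervals."""
    with open(path, "w") as fh:
        for i, c in enumerate(sorted(calls, key=lambda c: (c.contig, c.start))):
            lam = getattr(c, "lam", 0.0)
            zero = int(getattr(c, "zero_flag", False))
            p = getattr(c, "p_value", "")
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\tdel{i}\t{lam:.3f}\t"
                f"{c.zygosity}\t{zero}\t{p}\n"
            )


def read_deletion_bed(path: str | Path) -> list[DeletionCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(
                DeletionCall(
                    contig=f[0], start=int(f[1]), end=int(f[2]),
                    zygosity=f[5] if len(f) > 5 else "hom",
                    tract_depth=float("nan"), background=float("nan"),
                    zero_fraction=float("nan"),
                    zero_flag=bool(int(f[6])) if len(f) > 6 else False,
                    lam=float(f[4]) if len(f) > 4 else 0.0,
                    p_value=float(f[7]) if len(f) > 7 and f[7] else float("nan"),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def write_sam(
    records: Sequence[tuple[str, str, int, str, str, int]],
    references: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write alignments as (qname, ref, pos0, cigar, seq, alignment_score).

    Every record carries the standard ``AS`` alignment-score tag, the
    deterministic comparison key used by the retrogene filter.
    """
    names = list(references)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(references[n])} for n in names],
    }
    idx = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for qname, ref, pos, cigar, seq, score in records:
            a = pysam.AlignedSegment()
            a.query_name = qname
            a.reference_id = idx[ref]
            a.reference_start = pos
            a.cigarstring = cigar
            a.query_sequence = seq
            a.mapping_quality = 60
            a.flag = 0
            a.set_tag("AS", int(score))
            out.write(a)


# ---------------------------------------------------------------------------
# Checksums
# ---------------------------------------------------------------------------


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: Sequence[Path], out_path: str | Path) -> dict[str, str]:
    manifest = {p.name: file_sha256(p) for p in sorted(paths, key=lambda p: p.name)}
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
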