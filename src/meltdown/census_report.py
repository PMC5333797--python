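"""Per-sample defect census, excess tests and cross-sample sharing.

Assembles the deletion / retrogene / truncated-gene counts per sample
(raw, heterozygote-false-negative-corrected, and damage-excluded where
applicable), runs Pearson 2x2 chi-squared excess tests without continuity
correction, compares deletion size distributions with a tie-corrected
two-sided Wilcoxon rank-sum test (both the U and the R-style W statistic are
reported, since either convention appears in the literature), and counts
events shared across samples: deletions by >= 50% reciprocal overlap,
premature stops at both the site and the gene level, retrogenes at the gene
level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding_effects import (
    CorrectionConfig,
    StopCensus,
    VariantEffect,
    collapse_by_severity,
    correct_het_undercall,
    stop_codon_census,
)
from .deletion_caller import DeletionCall, gene_overlap, reciprocal_overlap
from .retrogene_detector import RetrogeneCall

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Census table
# ---------------------------------------------------------------------------


@dataclass
class SampleOutputs:
    """Upstream stage outputs for one sample; any stage may be missing."""

    deletions: Sequence[DeletionCall] | None = None
    retrogenes: Sequence[RetrogeneCall] | None = None
    effects: Sequence[VariantEffect] | None = None
    genes: Sequence | None = None  # gene models, for exon-overlap counting


def build_census_table(
    samples: Mapping[str, SampleOutputs],
    corrections: CorrectionConfig = CorrectionConfig(),
) -> pd.DataFrame:
    """One row per sample: defect counts, raw and corrected.

    Heterozygote false-negative corrections apply to heterozygous calls
    only; missing stage outputs yield NA cells, never zeros.
    """
    rows = {}
    for name, out in samples.items():
        row: dict[str, float] = {}
        if out.deletions is not None:
            het = sum(1 for c in out.deletions if c.zygosity == "het")
            hom = sum(1 for c in out.deletions if c.zygosity == "hom")
            row["deletions_raw"] = het + hom
            row["deletions_corrected"] = correct_het_undercall(
                het, hom, corrections.het_fnr_del
            )
            row["deletions_hom"] = hom
            row["deletions_zero_flagged"] = sum(1 for c in out.deletions if c.zero_flag)
            if out.genes is not None:
                hits = gene_overlap(out.deletions, out.genes)
                row["genes_exon_deleted_hom"] = len(hits["hom"])
                row["genes_exon_deleted_het"] = len(hits["het"])
                row["genes_exon_deleted"] = len(hits["hom"] | hits["het"])
        if out.retrogenes is not None:
            row["retrogenes"] = len(out.retrogenes)
        if out.effects is not None:
            collapsed = collapse_by_severity(out.effects)
            stops = [e for e in collapsed if e.effect_class == "nonsense"]
            het = sum(1 for e in stops if e.genotype == "het")
            hom = sum(1 for e in stops if e.genotype == "hom")
            row["stop_codons_raw"] = het + hom
            row["stop_codons_corrected"] = correct_het_undercall(
                het, hom, corrections.het_fnr_snp
            )
            row["stop_codons_no_damage"] = sum(1 for e in stops if not e.damage_flag)
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample"
    return table


# ---------------------------------------------------------------------------
# Excess tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChiSqResult:
    table: tuple[tuple[float, float], tuple[float, float]]
    chi2: float
    df: int
    p_value: float | None
    zero_expected: bool = False


def pairwise_chisq(
    count_a: float, total_a: float, count_b: float, total_b: float
) -> ChiSqResult:
    """Pearson chi-squared on [[a, A-a], [b, B-b]], df=1, no Yates correction."""
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("need totals >= counts >= 0")
    table = np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]], dtype=float
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected == 0).any():
        logger.warning("zero expected cell; chi-squared p-value undefined")
        return ChiSqResult(tuple(map(tuple, table)), float("nan"), 1, None, True)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSqResult(tuple(map(tuple, table)), float(chi2), int(df), float(p))


@dataclass(frozen=True)
class SizeComparisonResult:
    u_statistic: float
    w_statistic: float  # R-style rank-sum: U + n1(n1+1)/2
    p_value: float
    mean_a: float
    mean_b: float
    ecdf_a: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    ecdf_b: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)
    all_tied: bool = False


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(np.asarray(x, dtype=float))
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def deletion_size_comparison(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> SizeComparisonResult:
    """Two-sided Wilcoxon rank-sum comparison of deletion length samples."""
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        u = len(a) * len(b) / 2.0
        return SizeComparisonResult(
            u, u + len(a) * (len(a) + 1) / 2.0, 1.0,
            float(a.mean()), float(b.mean()), _ecdf(a), _ecdf(b), all_tied=True,
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    u = float(res.statistic)
    return SizeComparisonResult(
        u_statistic=u,
        w_statistic=u + len(a) * (len(a) + 1) / 2.0,
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        ecdf_a=_ecdf(a),
        ecdf_b=_ecdf(b),
    )


def rank_sum_exact_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Exact two-sided rank-sum p-value by enumeration (small samples only)."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Sharing across samples
# ---------------------------------------------------------------------------


def shared_events(
    per_sample: Mapping[str, Sequence],
    kind: str,
    min_reciprocal: float = 0.5,
) -> int:
    """Events present in every sample.

    kind='deletion': calls shared by >= ``min_reciprocal`` reciprocal
    overlap in all samples; 'stop_site': identical (contig, pos, alt)
    nonsense variants; 'stop_gene' / 'retrogene': shared gene ids.
    """
    names = list(per_sample)
    if len(names) < 2:
        raise ValueError("sharing requires at least two samples")
    if kind == "deletion":
        ref = per_sample[names[0]]
        count = 0
        for c in ref:
            if all(
                any(
                    o.contig == c.contig
                    and reciprocal_overlap((c.start, c.end), (o.start, o.end))
                    >= min_reciprocal
                    for o in per_sample[s]
                )
                for s in names[1:]
            ):
                count += 1
        return count
    if kind == "stop_site":
        sets = [
            {
                (e.contig, e.pos, e.alt)
                for e in collapse_by_severity(per_sample[s])
                if e.effect_class == "nonsense"
            }
            for s in names
        ]
        return len(set.intersection(*sets))
    if kind == "stop_gene":
        sets = [
            {
                e.gene_id
                for e in collapse_by_severity(per_sample[s])
                if e.effect_class == "nonsense" and e.gene_id
            }
            for s in names
        ]
        return len(set.intersection(*sets))
    if kind == "retrogene":
        sets = [{c.gene_id for c in per_sample[s]} for s in names]
        return len(set.intersection(*sets))
    raise ValueError(f"unknown sharing kind: {kind!r}")


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def render_report(
    census: pd.DataFrame,
    tests: Mapping[str, ChiSqResult] | None,
    comparisons: Mapping[str, SizeComparisonResult] | None,
    stop_census: StopCensus | None,
    outdir: str | Path,
) -> dict:
    """Write TSV tables, eCDF plot data and a JSON of every statistic.

    Output is deterministically ordered; regenerating from the same inputs
    yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    census.sort_index().to_csv(outdir / "census.tsv", sep="\t", float_format="%.6g")

    stats_json: dict = {"census": json.loads(census.sort_index().to_json(orient="index"))}
    if tests:
        stats_json["chisq"] = {
            name: {
                "table": [list(r) for r in t.table],
                "chi2": None if t.p_value is None else t.chi2,
                "df": t.df,
                "p_value": t.p_value,
                "zero_expected": t.zero_expected,
            }
            for name, t in sorted(tests.items())
        }
    if comparisons:
        stats_json["size_comparison"] = {}
        for name, c in sorted(comparisons.items()):
            stats_json["size_comparison"][name] = {
                "U": c.u_statistic,
                "W": c.w_statistic,
                "p_value": c.p_value,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "all_tied": c.all_tied,
            }
            with open(outdir / f"ecdf_{name}.tsv", "w") as fh:
                fh.write("sample\tlength\tecdf\n")
                for label, (xs, ys) in (("a", c.ecdf_a), ("b", c.ecdf_b)):
                    for x, y in zip(xs, ys):
                        fh.write(f"{label}\t{x:.6g}\t{y:.6g}\n")
    if stop_census:
        stats_json["stop_codons"] = {
            "per_sample": {
                s: sorted(g) for s, g in sorted(stop_census.per_sample_genes.items())
            },
            "shared_sites": stop_census.shared_sites,
            "shared_genes": stop_census.shared_genes,
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(stats_json, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return stats_json
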