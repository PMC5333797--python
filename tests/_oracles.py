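"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: translation goes
through Biopython's Seq.translate, and the change-point search recomputes
residual sums of squares per candidate from scratch.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

_COMP = str.maketrans("ACGT", "TGCA")


def oracle_codon_class(codon: str, offset: int, alt: str, strand: str = "+") -> str:
    """Classify a codon change by direct translation of old and new codons."""
    if strand == "-":
        alt = alt.translate(_COMP)
    new = codon[:offset] + alt + codon[offset + 1 :]
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(new).translate())
    if aa_old == "*" and aa_new == "*":
        return "synonymous"
    if aa_new == "*":
        return "nonsense"
    if aa_old == "*":
        return "stop_loss"
    return "synonymous" if aa_old == aa_new else "nonsynonymous"


def oracle_best_tract(
    depth: np.ndarray,
    mask: np.ndarray | None = None,
    grid: int = 100,
    min_len: int = 1000,
    max_len: int = 10_000,
) -> tuple[tuple[int, int], float]:
    """Exhaustive search over every grid (start, end) pair for the tract
    minimising the two-mean residual sum of squares; returns the tract and
    the likelihood-ratio statistic n * ln(RSS1/RSS2)."""
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    keep = ~mask
    x = depth[keep]
    n_used = len(x)
    rss1 = float(((x - x.mean()) ** 2).sum())
    tot_s, tot_q = float(x.sum()), float((x**2).sum())
    # base-resolution prefix sums over unmasked positions
    d = np.where(keep, depth, 0.0)
    ps = np.concatenate([[0.0], np.cumsum(d)])
    pq = np.concatenate([[0.0], np.cumsum(d**2)])
    pc = np.concatenate([[0.0], np.cumsum(keep.astype(float))])

    def rss(s, q, c):
        return q - s * s / c

    nb = n // grid
    best, best_rss2 = None, np.inf
    for a in range(0, nb):
        for b in range(a + max(1, min_len // grid), min(nb, a + max_len // grid) + 1):
            i, j = a * grid, b * grid
            c_in = pc[j] - pc[i]
            c_out = n_used - c_in
            if c_in == 0 or c_out == 0:
                continue
            s_in, q_in = ps[j] - ps[i], pq[j] - pq[i]
            rss2 = rss(s_in, q_in, c_in) + rss(tot_s - s_in, tot_q - q_in, c_out)
            if rss2 < best_rss2:
                best_rss2, best = rss2, (i, j)
    lam = n_used * np.log(max(rss1, best_rss2) / best_rss2) if best_rss2 > 0 else np.inf
    return best, float(lam)


def oracle_pearson_chi2(table) -> float:
    """Pearson chi-squared by explicit summation over the four cells."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = t[i].sum() * t[:, j].sum() / total
            chi2 += (t[i, j] - e) ** 2 / e
    return chi2
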