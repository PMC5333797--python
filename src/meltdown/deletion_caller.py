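"""Read-depth deletion calling by windowed change-point likelihood ratio.

The genome is tiled into non-overlapping 20 kb windows.  Within each window
the per-base depth is modelled as piecewise constant: one mean (no deletion)
versus a background mean plus a single depressed tract whose boundaries lie
on a 100 bp grid and whose length is between 1 and 10 kb.  The statistic

    lambda = n * ln(RSS_1 / RSS_2)

compares the residual sum of squares under the one-mean and two-mean fits
and is referred to a chi-squared distribution with df = 1.  Significance is
Bonferroni-controlled over every candidate tract placement evaluated
genome-wide.  Calls are genotyped from tract depth relative to the local
background (homozygous iff tract mean < 10% of background) and flagged when
at least half the tract has zero coverage.  Reference-genome positions with
'N' carry no depth information and are masked out of both RSS terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

logger = logging.getLogger(__name__)

WINDOW = 20_000
GRID = 100
MIN_TRACT = 1_000
MAX_TRACT = 10_000
HOM_DEPTH_FRACTION = 0.10  # strict: hom iff tract mean < 0.10 * background
ZERO_FLAG_FRACTION = 0.5
MIN_WINDOW = 2_000
MIN_UNMASKED_FRACTION = 0.5


@dataclass
class DepthTrack:
    """Per-base integer coverage over one contig, with an exclusion mask."""

    contig: str
    depth: np.ndarray
    mask: np.ndarray | None = None  # True = excluded (e.g. reference N)

    def __post_init__(self):
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.depth.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.depth.shape:
                raise ValueError("mask and depth lengths differ")

    def __len__(self):
        return len(self.depth)


@dataclass(frozen=True)
class ChangepointFit:
    window: tuple[int, int]
    tract: tuple[int, int]
    rss1: float
    rss2: float
    lam: float
    df: int
    p_value: float
    n_used: int
    n_candidates: int
    tract_mean: float
    background: float
    zero_fraction: float


@dataclass(frozen=True)
class DeletionCall:
    contig: str
    start: int
    end: int
    zygosity: str
    tract_depth: float
    background: float
    zero_fraction: float
    zero_flag: bool
    lam: float
    p_value: float

    @property
    def length(self) -> int:
        return self.end - self.start


def genotype_call(
    tract_mean: float, background: float, zero_fraction: float
) -> tuple[str, bool]:
    """Zygosity and zero-coverage flag from depth summaries.

    Homozygous iff the tract mean is strictly below 10% of background depth;
    the zero flag marks tracts with >= 50% of positions at zero coverage
    (candidate runs of unresolvable homozygous sub-deletions).
    """
    if background <= 0:
        raise ValueError("background depth must be positive")
    zyg = "hom" if tract_mean < HOM_DEPTH_FRACTION * background else "het"
    return zyg, zero_fraction >= ZERO_FLAG_FRACTION


def fit_changepoint_window(
    depth: np.ndarray,
    mask: np.ndarray | None = None,
    offset: int = 0,
    grid: int = GRID,
    min_len: int = MIN_TRACT,
    max_len: int = MAX_TRACT,
) -> ChangepointFit | None:
    """Best single depressed/elevated tract in one window.

    Evaluates every (start, end) pair on the ``grid`` with tract length in
    [min_len, max_len], maximising lambda = n * ln(RSS_1/RSS_2) over unmasked
    positions.  Returns None when the window is too masked to fit.
    ``offset`` shifts reported coordinates to the contig frame.
    """
    depth = np.asarray(depth, dtype=np.float64)
    n = len(depth)
    if n < MIN_WINDOW:
        return None
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    keep = ~mask
    n_used = int(keep.sum())
    if n_used < MIN_UNMASKED_FRACTION * n:
        logger.info("window at %d too masked (%d/%d unmasked); skipped", offset, n_used, n)
        return None

    d = np.where(keep, depth, 0.0)
    k = keep.astype(np.float64)
    # prefix sums at grid boundaries
    nb = n // grid
    if nb < (min_len // grid) + 1:
        return None
    usable = nb * grid
    s1 = np.concatenate([[0.0], np.cumsum(d[:usable].reshape(nb, grid).sum(axis=1))])
    s2 = np.concatenate([[0.0], np.cumsum((d[:usable] ** 2).reshape(nb, grid).sum(axis=1))])
    sc = np.concatenate([[0.0], np.cumsum(k[:usable].reshape(nb, grid).sum(axis=1))])
    tot_s, tot_s2, tot_c = s1[-1], s2[-1], sc[-1]
    # fold any post-grid remainder into the totals so RSS_1 covers the window
    if usable < n:
        tot_s += d[usable:].sum()
        tot_s2 += (d[usable:] ** 2).sum()
        tot_c += k[usable:].sum()
    if tot_c < 2:
        return None
    rss1 = tot_s2 - tot_s**2 / tot_c

    min_g, max_g = max(1, min_len // grid), max_len // grid
    starts = np.arange(0, nb - min_g + 1)
    lengths = np.arange(min_g, max_g + 1)
    a = starts[:, None]
    b = a + lengths[None, :]
    valid = b <= nb
    b = np.minimum(b, nb)
    c_in = sc[b] - sc[a]
    s_in = s1[b] - s1[a]
    q_in = s2[b] - s2[a]
    c_out = tot_c - c_in
    s_out = tot_s - s_in
    q_out = tot_s2 - q_in
    ok = valid & (c_in > 0) & (c_out > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss2 = (q_in - s_in**2 / np.maximum(c_in, 1)) + (
            q_out - s_out**2 / np.maximum(c_out, 1)
        )
    rss2 = np.where(ok, rss2, np.inf)
    n_candidates = int(ok.sum())
    if n_candidates == 0:
        return None
    best = np.unravel_index(np.argmin(rss2), rss2.shape)
    best_rss2 = float(rss2[best])
    # guard against degenerate zero residuals
    if best_rss2 <= 0:
        lam = np.inf
    else:
        lam = tot_c * np.log(max(rss1, best_rss2) / best_rss2)
    p = float(chi2.sf(lam, 1)) if np.isfinite(lam) else 0.0
    ta = int(a[best[0], 0]) * grid
    tb = int(b[best[0], best[1]]) * grid
    tract_keep = keep[ta:tb]
    tract_d = depth[ta:tb][tract_keep]
    out_idx = np.concatenate([np.arange(0, ta), np.arange(tb, n)])
    out_keep = keep[out_idx]
    background = float(np.median(depth[out_idx][out_keep])) if out_keep.any() else float("nan")
    tract_mean = float(tract_d.mean()) if len(tract_d) else float("nan")
    zero_fraction = float((tract_d == 0).mean()) if len(tract_d) else 0.0
    return ChangepointFit(
        window=(offset, offset + n),
        tract=(offset + ta, offset + tb),
        rss1=float(rss1),
        rss2=best_rss2,
        lam=float(lam),
        df=1,
        p_value=p,
        n_used=int(tot_c),
        n_candidates=n_candidates,
        tract_mean=tract_mean,
        background=background,
        zero_fraction=zero_fraction,
    )


def _merge_calls(
    fits: list[ChangepointFit], track: DepthTrack, grid: int
) -> list[DeletionCall]:
    """Resolve overlapping and abutting significant tracts into calls.

    Tracts from different window phases that overlap are alternative views
    of the same event: only the highest-lambda one is kept.  Surviving
    tracts that abut within one grid step (fragments of an event longer
    than the per-window maximum) are merged and re-genotyped from pooled
    depth.
    """
    accepted: list[ChangepointFit] = []
    for f in sorted(fits, key=lambda f: -f.lam):
        if all(
            f.tract[1] <= a.tract[0] or a.tract[1] <= f.tract[0] for a in accepted
        ):
            accepted.append(f)
    groups: list[list[ChangepointFit]] = []
    for f in sorted(accepted, key=lambda f: f.tract):
        if groups and f.tract[0] <= groups[-1][-1].tract[1] + grid:
            groups[-1].append(f)
        else:
            groups.append([f])
    calls = []
    keep = ~track.mask
    for grp in groups:
        start = min(f.tract[0] for f in grp)
        end = max(f.tract[1] for f in grp)
        tract_keep = keep[start:end]
        tract_d = track.depth[start:end][tract_keep]
        flank_lo = max(0, start - WINDOW)
        flank_hi = min(len(track), end + WINDOW)
        out_idx = np.concatenate([np.arange(flank_lo, start), np.arange(end, flank_hi)])
        out_keep = keep[out_idx]
        background = (
            float(np.median(track.depth[out_idx][out_keep]))
            if out_keep.any()
            else float("nan")
        )
        tract_mean = float(tract_d.mean()) if len(tract_d) else 0.0
        zero_fraction = float((tract_d == 0).mean()) if len(tract_d) else 0.0
        zyg, flag = genotype_call(tract_mean, background, zero_fraction)
        calls.append(
            DeletionCall(
                contig=track.contig,
                start=start,
                end=end,
                zygosity=zyg,
                tract_depth=tract_mean,
                background=background,
                zero_fraction=zero_fraction,
                zero_flag=flag,
                lam=max(f.lam for f in grp),
                p_value=min(f.p_value for f in grp),
            )
        )
    return calls


def scan_genome(
    tracks: Sequence[DepthTrack] | DepthTrack,
    alpha: float = 0.05,
    window: int = WINDOW,
    grid: int = GRID,
    min_len: int = MIN_TRACT,
    max_len: int = MAX_TRACT,
    phases: int = 2,
) -> list[DeletionCall]:
    """Scan depth tracks for deletions >= ``min_len``.

    Windows are fitted independently (at most one tract per window) in
    ``phases`` tilings offset by window/phases, so every event up to
    ``max_len`` (half the window) lies wholly inside some window even when
    it straddles a tile boundary of one tiling or shares a tile with a
    second event.  A tract is kept iff its chi-squared p-value clears the
    Bonferroni threshold alpha / (total candidate placements tested across
    all windows and phases); overlapping tracts from different phases are
    reduced to the highest-lambda view and abutting fragments merged.
    """
    if isinstance(tracks, DepthTrack):
        tracks = [tracks]
    all_fits: list[tuple[DepthTrack, ChangepointFit]] = []
    n_tests = 0
    for track in tracks:
        n = len(track)
        if n < MIN_WINDOW:
            logger.warning("contig %s shorter than %d bp; skipped", track.contig, MIN_WINDOW)
            continue
        starts = sorted(
            {
                w0
                for ph in range(phases)
                for w0 in range(ph * window // phases, n, window)
            }
        )
        for w0 in starts:
            w1 = min(w0 + window, n)
            if w1 - w0 < MIN_WINDOW:
                continue
            fit = fit_changepoint_window(
                track.depth[w0:w1], track.mask[w0:w1], offset=w0,
                grid=grid, min_len=min_len, max_len=max_len,
            )
            if fit is None:
                continue
            n_tests += fit.n_candidates
            all_fits.append((track, fit))
    if n_tests == 0:
        return []
    threshold = alpha / n_tests
    calls: list[DeletionCall] = []
    for track in tracks:
        sig = [
            f
            for t, f in all_fits
            if t is track and f.p_value <= threshold and f.tract_mean < f.background
        ]
        merged = _merge_calls(sig, track, grid)
        calls.extend(c for c in merged if c.length >= min_len)
    return calls


# ---------------------------------------------------------------------------
# Cross-sample filters and evaluation
# ---------------------------------------------------------------------------


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Smaller of the two mutual overlap fractions of two intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def filter_reference_insertions(
    calls_by_sample: Mapping[str, Sequence[DeletionCall]],
    min_reciprocal: float = 0.5,
) -> dict[str, list[DeletionCall]]:
    """Drop intervals called homozygous-deleted in every sample.

    Such universal homozygous "deletions" indicate sequence inserted in the
    reference assembly rather than lost in the samples.  Intervals are
    matched across samples by reciprocal overlap.
    """
    samples = list(calls_by_sample)
    if len(samples) < 2:
        logger.warning("reference-insertion filter needs >= 2 samples; no-op")
        return {s: list(v) for s, v in calls_by_sample.items()}
    hom_sets = {
        s: [(c.contig, c.start, c.end) for c in calls_by_sample[s] if c.zygosity == "hom"]
        for s in samples
    }

    def hom_in_all(call: DeletionCall) -> bool:
        for s in samples:
            found = any(
                contig == call.contig
                and reciprocal_overlap((start, end), (call.start, call.end)) >= min_reciprocal
                for contig, start, end in hom_sets[s]
            )
            if not found:
                return False
        return True

    out: dict[str, list[DeletionCall]] = {}
    for s in samples:
        out[s] = [
            c
            for c in calls_by_sample[s]
            if not (c.zygosity == "hom" and hom_in_all(c))
        ]
    return out


def gene_overlap(calls: Sequence[DeletionCall], genes) -> dict[str, set[str]]:
    """Genes with at least one exon intersected by a call, split by zygosity."""
    hit: dict[str, set[str]] = {"hom": set(), "het": set()}
    for g in genes:
        for c in calls:
            if c.contig != g.contig:
                continue
            if any(c.start < e and s < c.end for s, e in g.exons):
                hit[c.zygosity].add(g.gene_id)
    return hit


def match_calls(
    calls: Sequence[DeletionCall],
    truth: Sequence[tuple[str, int, int]],
    min_reciprocal: float = 0.5,
) -> tuple[int, int]:
    """(matched truth intervals, total truth) by reciprocal overlap."""
    matched = 0
    for contig, start, end in truth:
        if any(
            c.contig == contig
            and reciprocal_overlap((c.start, c.end), (start, end)) >= min_reciprocal
            for c in calls
        ):
            matched += 1
    return matched, len(truth)


def downsample_track(track: DepthTrack, target_depth: float, seed: int) -> DepthTrack:
    """Binomially thin per-base depth to a target mean (unmasked positions)."""
    current = float(track.depth[~track.mask].mean())
    if target_depth >= current:
        raise ValueError(f"target depth {target_depth} >= current mean {current:.2f}")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(track.depth.astype(np.int64), target_depth / current)
    return DepthTrack(track.contig, thinned, track.mask.copy())


def estimate_recall_downsample(
    track: DepthTrack,
    target_depth: float,
    reference_calls: Sequence[DeletionCall],
    seed: int = 0,
    min_reciprocal: float = 0.5,
    **scan_kwargs,
) -> tuple[float, list[DeletionCall]]:
    """Recall of full-depth calls after thinning coverage to ``target_depth``.

    Mirrors the coverage-sensitivity check of comparing deletion calls from a
    higher-coverage genome against the same genome downsampled.
    """
    thinned = downsample_track(track, target_depth, seed)
    new_calls = scan_genome(thinned, **scan_kwargs)
    intervals = [(c.contig, c.start, c.end) for c in reference_calls]
    matched, total = match_calls(new_calls, intervals, min_reciprocal)
    recall = matched / total if total else float("nan")
    return recall, new_calls
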