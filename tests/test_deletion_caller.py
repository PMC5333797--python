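"""deletion_caller: change-point fit, genotyping, scanning, filters."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meltdown import deletion_caller as dc
from tests._oracles import oracle_best_tract


def _nb_depth(rng, n, mean=15.0, k=5.0):
    return rng.negative_binomial(k, k / (k + mean), size=n)


def _window_with_tract(seed, n=20_000, tract=None, zygosity="hom"):
    rng = np.random.default_rng(seed)
    d = _nb_depth(rng, n).astype(np.int64)
    if tract is not None:
        a, b = tract
        if zygosity == "hom":
            d[a:b] = 0
        else:
            d[a:b] = rng.binomial(d[a:b], 0.5)
    return d


# ---------------------------------------------------------------------------
# fit_changepoint_window vs the exhaustive oracle
# ---------------------------------------------------------------------------


def test_fit_matches_exhaustive_oracle_planted():
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        a = int(rng.integers(0, 100)) * 100
        length = int(rng.integers(10, 101)) * 100
        d = _window_with_tract(seed, tract=(a, min(a + length, 20_000)))
        fit = dc.fit_changepoint_window(d)
        tract, lam = oracle_best_tract(d)
        assert (fit.tract[0], fit.tract[1]) == tract
        assert np.isclose(fit.lam, lam, rtol=1e-9)


def test_fit_matches_exhaustive_oracle_null_and_masked():
    d = _window_with_tract(7)
    mask = np.zeros(len(d), dtype=bool)
    mask[5000:5500] = True  # masked stretch must not bias either fit
    fit = dc.fit_changepoint_window(d, mask)
    tract, lam = oracle_best_tract(d, mask)
    assert (fit.tract[0], fit.tract[1]) == tract
    assert np.isclose(fit.lam, lam, rtol=1e-9)


def test_fit_rss2_never_exceeds_rss1():
    for seed in range(5):
        d = _window_with_tract(seed)
        fit = dc.fit_changepoint_window(d)
        assert fit.rss2 <= fit.rss1 + 1e-9
        assert fit.lam >= 0.0
        assert fit.df == 1


@given(st.integers(0, 10_000), st.floats(0.25, 8.0))
@settings(max_examples=15)
def test_lambda_scale_invariant(seed, scale):
    """lambda = n ln(RSS1/RSS2) is invariant under depth rescaling."""
    d = _window_with_tract(seed, n=4000, tract=(1000, 2500)).astype(float)
    f1 = dc.fit_changepoint_window(d)
    f2 = dc.fit_changepoint_window(d * scale)
    assert f1.tract == f2.tract
    assert np.isclose(f1.lam, f2.lam, rtol=1e-8)


def test_fit_window_contracts():
    assert dc.fit_changepoint_window(np.ones(500)) is None  # below MIN_WINDOW
    d = _window_with_tract(3, n=4000)
    mask = np.ones(4000, dtype=bool)
    mask[:1000] = False  # 75% masked
    assert dc.fit_changepoint_window(d, mask) is None
    with pytest.raises(ValueError):
        dc.DepthTrack("c", np.array([1, -2, 3]))
    with pytest.raises(ValueError):
        dc.DepthTrack("c", np.ones(10), np.zeros(5, dtype=bool))


def test_fit_respects_length_bounds():
    """A 500 bp dropout cannot be reported as the tract boundary pair; the
    best fit still has length >= 1 kb."""
    d = _window_with_tract(11, tract=(4000, 4500))
    fit = dc.fit_changepoint_window(d)
    assert fit.tract[1] - fit.tract[0] >= dc.MIN_TRACT
    d2 = _window_with_tract(12, tract=(2000, 16_000))  # longer than MAX_TRACT
    fit2 = dc.fit_changepoint_window(d2)
    assert fit2.tract[1] - fit2.tract[0] <= dc.MAX_TRACT


def test_fit_offset_shifts_coordinates():
    d = _window_with_tract(13, tract=(3000, 5000))
    f0 = dc.fit_changepoint_window(d)
    f1 = dc.fit_changepoint_window(d, offset=40_000)
    assert f1.tract == (f0.tract[0] + 40_000, f0.tract[1] + 40_000)
    assert f1.window == (40_000, 60_000)


# ---------------------------------------------------------------------------
# genotype_call
# ---------------------------------------------------------------------------


def test_genotype_thresholds():
    assert dc.genotype_call(0.0, 30.0, 1.0) == ("hom", True)
    assert dc.genotype_call(2.9, 30.0, 0.0) == ("hom", False)
    # boundary: exactly 10% of background is NOT homozygous (strict <)
    assert dc.genotype_call(3.0, 30.0, 0.0) == ("het", False)
    assert dc.genotype_call(15.0, 30.0, 0.49) == ("het", False)
    # zero flag boundary: >= 50%
    assert dc.genotype_call(15.0, 30.0, 0.5) == ("het", True)
    with pytest.raises(ValueError):
        dc.genotype_call(1.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# scan_genome
# ---------------------------------------------------------------------------


def test_scan_recovers_planted_deletions_with_zygosity():
    rng = np.random.default_rng(42)
    n = 400_000
    depth = _nb_depth(rng, n).astype(np.int64)
    truth = [(30_000, 34_000, "hom"), (101_500, 109_000, "het"), (250_000, 251_200, "hom")]
    for a, b, z in truth:
        depth[a:b] = 0 if z == "hom" else rng.binomial(depth[a:b], 0.5)
    calls = dc.scan_genome(dc.DepthTrack("c", depth))
    assert len(calls) == 3
    for (a, b, z), c in zip(truth, sorted(calls, key=lambda c: c.start)):
        assert dc.reciprocal_overlap((c.start, c.end), (a, b)) >= 0.9
        assert c.zygosity == z
        assert c.p_value <= 0.05
    hom = [c for c in calls if c.zygosity == "hom"]
    assert all(c.zero_flag for c in hom)


def test_scan_boundary_straddling_deletion_single_call():
    """A deletion crossing a 20 kb tile edge yields one merged call."""
    rng = np.random.default_rng(5)
    depth = _nb_depth(rng, 100_000).astype(np.int64)
    depth[57_000:63_000] = 0  # straddles the 60 kb tile boundary
    calls = dc.scan_genome(dc.DepthTrack("c", depth))
    assert len(calls) == 1
    c = calls[0]
    assert dc.reciprocal_overlap((c.start, c.end), (57_000, 63_000)) >= 0.9
    assert c.zygosity == "hom"


def test_scan_null_genome_no_calls():
    rng = np.random.default_rng(987)
    depth = _nb_depth(rng, 300_000)
    assert dc.scan_genome(dc.DepthTrack("c", depth)) == []


def test_scan_ignores_amplifications():
    rng = np.random.default_rng(21)
    depth = _nb_depth(rng, 100_000).astype(np.int64)
    depth[40_000:45_000] *= 4  # elevated, not depressed
    assert dc.scan_genome(dc.DepthTrack("c", depth)) == []


def test_scan_short_contig_skipped(caplog):
    with caplog.at_level(logging.WARNING):
        calls = dc.scan_genome(dc.DepthTrack("tiny", np.ones(500)))
    assert calls == []
    assert "shorter" in caplog.text


# ---------------------------------------------------------------------------
# reciprocal overlap, cross-sample filter, gene overlap, matching
# ---------------------------------------------------------------------------


def test_reciprocal_overlap_values():
    assert dc.reciprocal_overlap((0, 100), (0, 100)) == 1.0
    assert dc.reciprocal_overlap((0, 100), (50, 150)) == 0.5
    assert dc.reciprocal_overlap((0, 100), (100, 200)) == 0.0
    # nested small interval: limited by the larger interval's fraction
    assert dc.reciprocal_overlap((0, 1000), (0, 100)) == 0.1


def _call(start, end, zyg="hom", contig="c"):
    return dc.DeletionCall(contig, start, end, zyg, 0.0, 30.0, 1.0, True, 100.0, 1e-12)


def test_reference_insertion_filter():
    shared = _call(1000, 3000)  # hom in both samples -> reference insertion
    a_only = _call(10_000, 12_000)
    het_shared_a, het_shared_b = _call(20_000, 22_000, "het"), _call(20_000, 22_000, "het")
    out = dc.filter_reference_insertions(
        {"a": [shared, a_only, het_shared_a], "b": [shared, het_shared_b]}
    )
    assert out["a"] == [a_only, het_shared_a]  # shared hom dropped, others kept
    assert out["b"] == [het_shared_b]


def test_reference_insertion_filter_single_sample_noop(caplog):
    calls = [_call(0, 2000)]
    with caplog.at_level(logging.WARNING):
        out = dc.filter_reference_insertions({"a": calls})
    assert out == {"a": calls}
    assert "no-op" in caplog.text


def test_reference_insertion_filter_requires_reciprocal_overlap():
    a = _call(0, 2000)
    b = _call(0, 10_000)  # only 20% reciprocal: not the same event
    out = dc.filter_reference_insertions({"a": [a], "b": [b]})
    assert out == {"a": [a], "b": [b]}


def test_gene_overlap_split_by_zygosity():
    from meltdown.coding_effects import GeneModel

    g1 = GeneModel("g1", "c", "+", ((100, 200), (500, 600)))
    g2 = GeneModel("g2", "c", "+", ((5000, 5100),))
    g3 = GeneModel("g3", "c", "+", ((3000, 3100),))  # outside every call
    calls = [_call(150, 1600, "hom"), _call(5050, 6100, "het")]
    hits = dc.gene_overlap(calls, [g1, g2, g3])
    assert hits == {"hom": {"g1"}, "het": {"g2"}}


def test_match_calls_and_downsample_recall():
    rng = np.random.default_rng(77)
    depth = _nb_depth(rng, 200_000, mean=30.0).astype(np.int64)
    truth = [(40_000, 45_000), (120_000, 124_000)]
    for a, b in truth:
        depth[a:b] = 0
    track = dc.DepthTrack("c", depth)
    calls = dc.scan_genome(track)
    matched, total = dc.match_calls(calls, [("c", a, b) for a, b in truth])
    assert (matched, total) == (2, 2)
    recall, new_calls = dc.estimate_recall_downsample(track, 10.0, calls, seed=3)
    assert recall == 1.0  # hom deletions survive heavy thinning
    thinned = dc.downsample_track(track, 10.0, seed=3)
    assert abs(float(thinned.depth.mean()) - 10.0) < 0.2
    with pytest.raises(ValueError):
        dc.downsample_track(track, 100.0, seed=0)
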