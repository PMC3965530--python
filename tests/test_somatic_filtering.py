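"""The calling cascade: rule-level oracles, cascade behavior, invariants."""

import math

import numpy as np
import pytest

import oncopanel as op
from oncopanel.somatic_filtering import (
    MIN_BACKGROUND_LOCI,
    top_alt_base,
)

from conftest import make_pileup


# ---------------------------------------------------------------------------
# Median coverage
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "depths, expected",
    [
        ([100, 100, 100], 100),
        ([10, 1000, 100, 500], 300),  # even count: mean of middle two
        ([7], 7),
    ],
)
def test_sample_median_coverage(depths, expected):
    pileup = make_pileup("s", depths=depths, alts=[0] * len(depths))
    assert op.sample_median_coverage(pileup) == expected


def test_sample_median_coverage_matches_sort_and_average_oracle():
    rng = np.random.default_rng(5)
    depths = rng.integers(10, 5000, size=101)
    pileup = make_pileup("s", depths=depths, alts=np.zeros(101, dtype=int))
    ordered = sorted(depths)
    assert op.sample_median_coverage(pileup) == ordered[50]


def test_sample_median_coverage_empty_rejected():
    import pandas as pd
    from oncopanel.pileup_io import PILEUP_COLUMNS
    empty = op.PileupTable("s", pd.DataFrame(columns=PILEUP_COLUMNS))
    with pytest.raises(ValueError):
        op.sample_median_coverage(empty)


# ---------------------------------------------------------------------------
# Coverage gate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "depth, median, retained",
    [
        (101, 1000, True),    # 2% of 1000 = 20; 101 > 100 and > 20
        (150, 10000, False),  # 2% of 10000 = 200; fails the median arm
        (100, 100, False),    # both comparisons strict
        (101, 100, True),
    ],
)
def test_coverage_gate_rules(depth, median, retained):
    pileup = make_pileup("s", depths=[depth], alts=[0])
    kept = op.coverage_gate(pileup, median, op.FilterConfig())
    assert (("chr1", 1) in kept) is retained


# ---------------------------------------------------------------------------
# Variant score
# ---------------------------------------------------------------------------

def test_variant_score_zero_alt_is_zero():
    assert op.variant_score(100, 0, 0.005) == 0.0


def test_variant_score_closed_form_example():
    # P[X >= 1] = 1 - (1-p)^n
    expected = -10 * math.log10(1 - 0.995 ** 100)
    assert op.variant_score(100, 1, 0.005) == pytest.approx(expected, rel=1e-9)


def test_variant_score_monotone_in_alt():
    scores = [op.variant_score(100, k, 0.005) for k in range(0, 101)]
    assert all(b >= a for a, b in zip(scores, scores[1:]))
    assert op.variant_score(100, 50, 0.005) > op.variant_score(100, 5, 0.005)


def _log10_binom_tail(n, alt, p):
    """Independent log-sum-exp binomial upper tail, math module only."""
    if alt == 0:
        return 0.0
    logs = [
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        + k * math.log(p) + (n - k) * math.log1p(-p)
        for k in range(alt, n + 1)
    ]
    m = max(logs)
    return (m + math.log(math.fsum(math.exp(l - m) for l in logs))) / math.log(10)


@pytest.mark.parametrize("n, alt, p", [
    (100, 1, 0.005),
    (100, 6, 0.005),
    (1000, 60, 0.005),
    (1000, 460, 0.002),
    (250, 250, 0.5),
])
def test_variant_score_matches_brute_force_tail_oracle(n, alt, p):
    expected = -10 * _log10_binom_tail(n, alt, p)
    assert op.variant_score(n, alt, p) == pytest.approx(expected, rel=1e-8)


def test_variant_score_rejects_alt_above_depth():
    with pytest.raises(ValueError):
        op.variant_score(10, 11, 0.005)


# ---------------------------------------------------------------------------
# Germline filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "depth, alt, flagged",
    [
        (100, 2, True),    # 2% > 1%
        (200, 0, False),   # zero evidence
        (100, 1, False),   # exactly 1%: strict >
        (0, 0, True),      # no normal coverage: conservative flag
    ],
)
def test_germline_filter(depth, alt, flagged):
    from oncopanel.somatic_filtering import germline_filter
    assert germline_filter(depth, alt, op.FilterConfig()) is flagged


# ---------------------------------------------------------------------------
# Background distribution & systematic filter
# ---------------------------------------------------------------------------

def test_background_identical_tables_all_zero(small_pair):
    _, _, tumor, _, _ = small_pair
    bg = op.background_difference_distribution(
        tumor, tumor, candidates=set(), blacklist=set(), config=op.FilterConfig()
    )
    assert np.all(bg == 0.0)


def test_background_excludes_candidates_and_blacklist(small_pair):
    _, _, tumor, normal, truth = small_pair
    config = op.FilterConfig()
    somatic = {(r["chrom"], int(r["pos"])) for _, r in truth.iterrows()
               if r["class"] == "somatic"}
    bl = {(r["chrom"], int(r["pos"])) for _, r in truth.iterrows()
          if r["class"] == "artifact"}
    bg_all = op.background_difference_distribution(
        tumor, normal, set(), set(), config
    )
    bg = op.background_difference_distribution(tumor, normal, somatic, bl, config)
    assert len(bg) == len(bg_all) - len(somatic) - len(bl)
    # planted somatic score differences are far out in the tail; excluding
    # them must remove the largest values
    assert bg.max() <= bg_all.max()


def test_background_matches_per_locus_loop_oracle(small_pair):
    _, _, tumor, normal, _ = small_pair
    config = op.FilterConfig()
    bg = op.background_difference_distribution(tumor, normal, set(), set(), config)
    n_idx = normal.records.set_index(["chrom", "pos"])
    expected = []
    for _, trow in tumor.records.iterrows():
        alt_base, t_alt = top_alt_base(trow, trow["ref_base"])
        nrow = n_idx.loc[(trow["chrom"], trow["pos"])]
        t_s = op.variant_score(int(trow["depth"]), int(t_alt), config.background_error)
        n_s = op.variant_score(
            int(nrow["depth"]), int(nrow[f"count_{alt_base}"]), config.background_error
        )
        expected.append(t_s - n_s)
    assert np.allclose(bg, np.sort(expected))


def test_background_rejects_too_few_loci():
    tumor = make_pileup("t", depths=[1000] * 50, alts=[0] * 50)
    with pytest.raises(ValueError, match="background loci"):
        op.background_difference_distribution(
            tumor, tumor, set(), set(), op.FilterConfig()
        )
    assert MIN_BACKGROUND_LOCI == 200


def test_systematic_filter_point_mass_background():
    bg = np.zeros(500)
    config = op.FilterConfig()
    from oncopanel.somatic_filtering import systematic_filter
    assert systematic_filter(0.0, bg, config) is True     # within background
    assert systematic_filter(50.0, bg, config) is False   # exceeds point mass


def test_systematic_filter_against_sorted_quantile_oracle():
    rng = np.random.default_rng(42)
    bg = np.sort(rng.standard_normal(1000))
    config = op.FilterConfig()
    # independent linear-interpolation quantile: h = (n-1)*q
    h = (len(bg) - 1) * config.diff_percentile / 100.0
    lo, frac = int(math.floor(h)), h - math.floor(h)
    cutoff = bg[lo] + frac * (bg[lo + 1] - bg[lo])
    from oncopanel.somatic_filtering import systematic_filter
    at_999 = np.quantile(bg, 0.999)
    at_990 = np.quantile(bg, 0.99)
    assert at_999 > cutoff and systematic_filter(at_999, bg, config) is False
    assert at_990 <= cutoff and systematic_filter(at_990, bg, config) is True


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def test_cascade_tumor_equals_normal_no_accepted_calls(small_pair):
    panel, _, tumor, _, _ = small_pair
    calls = op.call_somatic(tumor, tumor, panel)
    assert all(not c.accepted for c in calls)


def test_cascade_symmetric_null_across_seeds():
    """tumor == normal yields zero accepted calls, 20 independent seeds."""
    for seed in range(100, 120):
        panel = op.random_panel(400, seed=seed)
        params = op.SimParams(
            n_loci=400, n_somatic=0, n_germline=0, n_artifact_loci=5, seed=seed
        )
        tumor, _, _ = op.simulate_pair(panel, params)
        calls = op.call_somatic(tumor, tumor, panel)
        assert sum(c.accepted for c in calls) == 0


def test_cascade_accepts_clean_planted_somatic():
    """A 46% VAF tumor variant with a clean normal passes every filter."""
    n = 500
    depths = [1000] * n
    t_alts = [0] * n
    t_alts[250] = 460
    tumor = make_pileup("t", depths=depths, alts=t_alts)
    normal = make_pileup("n", depths=depths, alts=[0] * n)
    panel = op.Panel(tuple(
        op.PanelLocus("G1", "chr1", i, i + 1, "whole_exon") for i in range(n)
    ))
    calls = op.call_somatic(tumor, normal, panel)
    accepted = [c for c in calls if c.accepted]
    assert len(accepted) == 1
    assert accepted[0].pos == 251
    assert accepted[0].tumor_vaf == pytest.approx(0.46)


def test_cascade_low_vaf_flag_only():
    """5% tumor VAF: returned flagged low_vaf, everything else clean."""
    n = 500
    t_alts = [0] * n
    t_alts[100] = 50  # 5% of 1000
    tumor = make_pileup("t", depths=[1000] * n, alts=t_alts)
    normal = make_pileup("n", depths=[1000] * n, alts=[0] * n)
    panel = op.Panel(tuple(
        op.PanelLocus("G1", "chr1", i, i + 1, "whole_exon") for i in range(n)
    ))
    calls = op.call_somatic(tumor, normal, panel)
    assert len(calls) == 1
    assert calls[0].filter_flags == {"low_vaf"}


def test_cascade_rejects_mismatched_loci(small_pair):
    panel, _, tumor, normal, _ = small_pair
    clipped = op.PileupTable(
        sample_id=normal.sample_id, records=normal.records.iloc[:-5]
    )
    with pytest.raises(ValueError, match="different loci"):
        op.call_somatic(tumor, clipped, panel)


def test_flag_monotonicity_in_thresholds(small_pair):
    """Raising the call threshold, or tightening the normal-VAF cap,
    never enlarges the accepted set (set inclusion along the sweep)."""
    panel, _, tumor, normal, _ = small_pair

    def accepted(config):
        return {
            (c.chrom, c.pos)
            for c in op.call_somatic(tumor, normal, panel, config=config)
            if c.accepted
        }

    prev = None
    for vaf_min in (0.04, 0.06, 0.10, 0.20):
        cur = accepted(op.FilterConfig(tumor_vaf_min=vaf_min))
        if prev is not None:
            assert cur <= prev
        prev = cur

    prev = None
    for nmax in (0.05, 0.02, 0.01, 0.002):
        cur = accepted(op.FilterConfig(normal_vaf_max=nmax))
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_planted_germline_loci_flagged():
    """Heterozygous germline loci at depth > 100 are flagged >= 99.9%."""
    total = flagged = 0
    for seed in range(200, 210):
        panel = op.random_panel(500, seed=seed)
        params = op.SimParams(
            n_loci=500, n_somatic=0, n_germline=50, n_artifact_loci=5, seed=seed
        )
        tumor, normal, truth = op.simulate_pair(panel, params)
        calls = {(c.chrom, c.pos): c for c in op.call_somatic(tumor, normal, panel)}
        for _, row in truth[truth["class"] == "germline"].iterrows():
            key = (row["chrom"], int(row["pos"]))
            total += 1
            call = calls.get(key)
            if call is not None and "germline" in call.filter_flags:
                flagged += 1
    assert total == 500
    assert flagged / total >= 0.999


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def test_recovery_metrics_perfect_and_degenerate(small_pair):
    panel, _, tumor, normal, truth = small_pair
    calls = op.call_somatic(tumor, normal, panel)
    m = op.recovery_metrics(calls, truth)
    # hand-tallied confusion matrix over the same call list
    somatic = {(r["chrom"], int(r["pos"])) for _, r in truth.iterrows()
               if r["class"] == "somatic"}
    acc = {(c.chrom, c.pos) for c in calls if c.accepted}
    assert m["tp"] == len(acc & somatic)
    assert m["fp"] == len(acc - somatic)
    assert m["fn"] == len(somatic - acc)
    if m["tp"] + m["fp"]:
        assert m["ppv"] == pytest.approx(m["tp"] / (m["tp"] + m["fp"]))

    none_accepted = [c for c in calls if not c.accepted]
    m0 = op.recovery_metrics(none_accepted, truth)
    assert m0["sensitivity"] == 0.0
    assert m0["ppv"] is None
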