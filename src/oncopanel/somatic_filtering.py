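"""The tumor-normal somatic calling cascade.

A candidate variant at a panel locus survives five rules before it is
accepted as somatic:

1. **Coverage gate** — the locus must be deeply covered in BOTH samples:
   depth strictly greater than ``median_fraction`` x that sample's
   median coverage AND strictly greater than ``min_reads``.
2. **Call threshold** — tumor variant allele fraction (VAF) at the
   locus's top non-reference base must reach ``tumor_vaf_min``
   (default 6%), else the candidate carries the ``low_vaf`` flag.
3. **Blacklist** — loci known to produce recurrent systematic positives
   are flagged.
4. **Germline subtraction** — a matched-normal VAF strictly above
   ``normal_vaf_max`` (default 1%) flags the candidate ``germline``;
   zero normal depth is flagged conservatively (germline cannot be
   excluded).
5. **Systematic-error percentile filter** — the tumor-minus-normal
   variant-score difference must exceed the ``diff_percentile``
   (default 99.5th) percentile of score differences over background
   loci (retained, non-candidate, non-blacklisted), else the candidate
   is flagged ``systematic``.

The variant score is the Phred-scaled upper-tail binomial probability
of the observed alternate count under a background error rate:
``-10*log10 P[X >= alt | n=depth, p=background_error]``. It is zero for
alt=0 and monotone non-decreasing in alt at fixed depth.

Every nominated candidate (tumor VAF >= ``nomination_vaf_min``) is
returned with its full flag set so per-filter attrition is auditable;
accepted calls are exactly those with no flags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from oncopanel.pileup_io import BASES, Panel, PileupTable

log = logging.getLogger(__name__)

FILTER_FLAGS = frozenset(
    {"low_coverage", "low_vaf", "germline", "systematic", "blacklist"}
)

MIN_BACKGROUND_LOCI = 200
_LOG10 = math.log(10.0)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the calling cascade.

    min_reads
        Absolute depth floor for the coverage gate (strict >).
    median_fraction
        Relative depth floor as a fraction of the sample median (strict >).
    tumor_vaf_min
        Tumor VAF call threshold; candidates below it are flagged low_vaf
        (inclusive >=: a variant exactly at the threshold is callable).
    normal_vaf_max
        Matched-normal VAF above which a candidate is flagged germline
        (strict >).
    diff_percentile
        Percentile of the background score-difference distribution a
        candidate must strictly exceed.
    background_error
        Base error rate the binomial-tail variant score is computed
        against.
    nomination_vaf_min
        Evidence floor for nominating a locus as a candidate at all;
        kept well below tumor_vaf_min so near-threshold loci are
        reported with flags instead of silently dropped.
    """

    min_reads: int = 100
    median_fraction: float = 0.02
    tumor_vaf_min: float = 0.06
    normal_vaf_max: float = 0.01
    diff_percentile: float = 99.5
    background_error: float = 0.005
    nomination_vaf_min: float = 0.02

    def __post_init__(self) -> None:
        for name in ("median_fraction", "tumor_vaf_min", "normal_vaf_max",
                     "background_error", "nomination_vaf_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 < self.diff_percentile < 100.0):
            raise ValueError("diff_percentile must lie in (0, 100)")
        if not (0.0 < self.background_error < 1.0):
            raise ValueError("background_error must lie in (0, 1)")
        if self.min_reads < 0:
            raise ValueError("min_reads must be non-negative")


@dataclass
class SomaticCall:
    """One nominated candidate with its evidence and filter verdict."""

    gene: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    score_diff: float = 0.0
    filter_flags: set = dc_field(default_factory=set)
    effect: str | None = None

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_vaf(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0

    @property
    def accepted(self) -> bool:
        return not self.filter_flags


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------

def sample_median_coverage(pileup: PileupTable) -> float:
    """Median per-locus depth; even count averages the middle two."""
    if len(pileup) == 0:
        raise ValueError("cannot take the median coverage of an empty pileup")
    return float(np.median(pileup.records["depth"].to_numpy()))


def coverage_gate(
    pileup: PileupTable, median: float, config: FilterConfig
) -> set[tuple[str, int]]:
    """Loci retained for analysis: depth strictly above BOTH floors."""
    df = pileup.records
    keep = (df["depth"] > config.median_fraction * median) & (
        df["depth"] > config.min_reads
    )
    return set(zip(df.loc[keep, "chrom"], df.loc[keep, "pos"]))


def _log_binom_tail(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """Natural log of P[X >= k | n, p], stable in the far upper tail.

    Uses the plain survival function where it does not underflow;
    elsewhere anchors on logpmf(k) and sums the rapidly decaying term
    ratios pmf(j+1)/pmf(j) = (n-j)p / ((j+1)(1-p)).
    """
    sf = stats.binom.sf(k - 1, n, p)
    out = np.where(sf > 0, np.log(np.where(sf > 0, sf, 1.0)), -np.inf)
    under = sf <= 0
    if np.any(under):
        ku = k[under].astype(np.float64)
        nu = n[under].astype(np.float64)
        base = stats.binom.logpmf(k[under], n[under], p)
        total = np.ones_like(base)
        ratio = np.ones_like(base)
        j = ku.copy()
        odds = p / (1.0 - p)
        for _ in range(300):
            ratio = ratio * (nu - j) / (j + 1.0) * odds
            total += ratio
            j += 1.0
            if np.all(ratio < 1e-18):
                break
        out[under] = base + np.log(total)
    return out


def variant_score(depth, alt, background_error: float):
    """Phred-scaled binomial upper tail: -10*log10 P[X >= alt | depth, p].

    Vectorized over depth/alt arrays. alt=0 scores 0 (the tail is the
    whole distribution); computed through the log survival function so
    deep high-count loci do not underflow.
    """
    if not (0.0 < background_error < 1.0):
        raise ValueError("background_error must lie in (0, 1)")
    depth_arr = np.asarray(depth, dtype=np.int64)
    alt_arr = np.asarray(alt, dtype=np.int64)
    if np.any(alt_arr > depth_arr) or np.any(alt_arr < 0):
        raise ValueError("alt counts must satisfy 0 <= alt <= depth")
    log_tail = _log_binom_tail(
        np.atleast_1d(alt_arr), np.atleast_1d(depth_arr), background_error
    )
    score = -10.0 * log_tail.reshape(alt_arr.shape) / _LOG10
    score = np.where(alt_arr == 0, 0.0, score)
    if np.ndim(depth) == 0 and np.ndim(alt) == 0:
        return float(score)
    return score


def germline_filter(
    normal_depth: int, normal_alt: int, config: FilterConfig
) -> bool:
    """True when the candidate must be flagged germline.

    The matched normal showing strictly more than ``normal_vaf_max``
    variant reads indicates an inherited variant. Zero normal depth
    flags conservatively: germline status cannot be excluded.
    """
    if normal_depth == 0:
        return True
    return normal_alt / normal_depth > config.normal_vaf_max


def top_alt_base(row: pd.Series, ref_base: str) -> tuple[str, int]:
    """Most frequent non-reference base; ties broken alphabetically."""
    best_base, best_count = "", -1
    for b in BASES:
        if b == ref_base:
            continue
        c = int(row[f"count_{b}"])
        if c > best_count:
            best_base, best_count = b, c
    return best_base, best_count


def _top_alt_vectorized(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-row top non-reference base and its count (ties: A<C<G<T)."""
    counts = df[[f"count_{b}" for b in BASES]].to_numpy(dtype=np.int64)
    ref_idx = np.searchsorted(np.array(BASES), df["ref_base"].to_numpy())
    masked = counts.copy()
    masked[np.arange(len(df)), ref_idx] = -1
    best_idx = np.argmax(masked, axis=1)  # argmax keeps first max: alphabetical
    best_count = masked[np.arange(len(df)), best_idx]
    return np.array(BASES)[best_idx], best_count


def background_difference_distribution(
    tumor: PileupTable,
    normal: PileupTable,
    candidates: set[tuple[str, int]],
    blacklist: set[tuple[str, int]],
    config: FilterConfig,
    retained: set[tuple[str, int]] | None = None,
) -> np.ndarray:
    """Sorted tumor-minus-normal score differences over background loci.

    Background = retained loci that are neither nominated candidates nor
    blacklisted; each locus contributes the score difference at its most
    frequent non-reference base in the tumor. Fewer than
    ``MIN_BACKGROUND_LOCI`` background loci make the extreme percentile
    unstable and raise.
    """
    t = tumor.records.set_index(["chrom", "pos"])
    n = normal.records.set_index(["chrom", "pos"])
    shared = t.index.intersection(n.index)
    exclude = candidates | blacklist
    keep = [
        key
        for key in shared
        if key not in exclude and (retained is None or key in retained)
    ]
    if len(keep) < MIN_BACKGROUND_LOCI:
        raise ValueError(
            f"only {len(keep)} background loci (< {MIN_BACKGROUND_LOCI}); "
            "percentile filter would be unstable"
        )
    t_bg = t.loc[keep]
    n_bg = n.loc[keep]
    alt_bases, t_alt = _top_alt_vectorized(t_bg)
    base_cols = np.searchsorted(np.array(BASES), alt_bases)
    n_counts = n_bg[[f"count_{b}" for b in BASES]].to_numpy(dtype=np.int64)
    n_alt = n_counts[np.arange(len(n_bg)), base_cols]
    t_score = variant_score(t_bg["depth"].to_numpy(), t_alt, config.background_error)
    n_score = variant_score(n_bg["depth"].to_numpy(), n_alt, config.background_error)
    return np.sort(t_score - n_score)


def systematic_filter(
    score_diff: float, background: np.ndarray, config: FilterConfig
) -> bool:
    """True when the score difference sits within the background percentile.

    The percentile is computed by linear interpolation between closest
    order statistics (inclusive); ties with the percentile value are
    flagged (conservative).
    """
    if len(background) == 0:
        raise ValueError("empty background distribution")
    cutoff = float(np.percentile(background, config.diff_percentile, method="linear"))
    return bool(score_diff <= cutoff)


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

def call_somatic(
    tumor: PileupTable,
    normal: PileupTable,
    panel: Panel,
    blacklist: set[tuple[str, int]] | None = None,
    config: FilterConfig | None = None,
) -> list[SomaticCall]:
    """Run the full cascade on a matched pair; return all nominated calls.

    Both pileups must cover the same loci (a matched pair over one
    panel). Accepted somatic calls are those returned with an empty
    flag set.
    """
    config = config or FilterConfig()
    blacklist = blacklist or set()
    if len(tumor) == 0 or len(normal) == 0:
        raise ValueError("empty pileup table")
    t = tumor.records.set_index(["chrom", "pos"])
    n = normal.records.set_index(["chrom", "pos"])
    if not t.index.equals(n.index):
        if set(t.index) != set(n.index):
            raise ValueError("tumor and normal pileups cover different loci")
        n = n.loc[t.index]

    gene_of = _locus_gene_map(panel, t.index)

    t_median = sample_median_coverage(tumor)
    n_median = sample_median_coverage(normal)
    t_keep = coverage_gate(tumor, t_median, config)
    n_keep = coverage_gate(normal, n_median, config)
    retained = t_keep & n_keep

    # Nomination: any locus with tumor evidence above the floor.
    alt_bases, t_alt_counts = _top_alt_vectorized(t)
    t_depths = t["depth"].to_numpy(dtype=np.int64)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vafs = np.where(t_depths > 0, t_alt_counts / np.maximum(t_depths, 1), 0.0)
    nominate = (t_depths > 0) & (t_vafs >= config.nomination_vaf_min)

    base_cols = np.searchsorted(np.array(BASES), alt_bases)
    n_counts = n[[f"count_{b}" for b in BASES]].to_numpy(dtype=np.int64)
    n_alt_counts = n_counts[np.arange(len(n)), base_cols]
    n_depths = n["depth"].to_numpy(dtype=np.int64)
    ref_bases = t["ref_base"].to_numpy()

    calls: list[SomaticCall] = []
    candidate_keys: set[tuple[str, int]] = set()
    for i in np.flatnonzero(nominate):
        key = t.index[i]
        call = SomaticCall(
            gene=gene_of.get(key, "."),
            chrom=key[0],
            pos=int(key[1]),
            ref_base=str(ref_bases[i]),
            alt_base=str(alt_bases[i]),
            tumor_depth=int(t_depths[i]),
            tumor_alt=int(t_alt_counts[i]),
            normal_depth=int(n_depths[i]),
            normal_alt=int(n_alt_counts[i]),
        )
        candidate_keys.add(key)
        calls.append(call)

    background = background_difference_distribution(
        tumor, normal, candidate_keys, blacklist, config, retained=retained
    )

    attrition = {flag: 0 for flag in sorted(FILTER_FLAGS)}
    for call in calls:
        key = (call.chrom, call.pos)
        if key not in retained:
            call.filter_flags.add("low_coverage")
        if call.tumor_vaf < config.tumor_vaf_min:
            call.filter_flags.add("low_vaf")
        if key in blacklist:
            call.filter_flags.add("blacklist")
        if germline_filter(call.normal_depth, call.normal_alt, config):
            call.filter_flags.add("germline")
        t_score = variant_score(call.tumor_depth, call.tumor_alt, config.background_error)
        n_score = variant_score(call.normal_depth, call.normal_alt, config.background_error)
        call.score_diff = t_score - n_score
        if systematic_filter(call.score_diff, background, config):
            call.filter_flags.add("systematic")
        for flag in call.filter_flags:
            attrition[flag] += 1

    accepted = sum(1 for c in calls if c.accepted)
    log.info(
        "cascade: %d nominated, %d accepted; attrition %s",
        len(calls), accepted, attrition,
    )
    return calls


def _locus_gene_map(panel: Panel, index: pd.Index) -> dict[tuple[str, int], str]:
    """Map each pileup locus to its covering panel gene (1-based pos)."""
    out: dict[tuple[str, int], str] = {}
    by_chrom: dict[str, list] = {}
    for locus in panel.loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom, pos in index:
        for locus in by_chrom.get(chrom, ()):
            if locus.start < pos <= locus.end:  # pos is 1-based
                out[(chrom, pos)] = locus.gene
                break
    return out


def recovery_metrics(calls: list[SomaticCall], truth: pd.DataFrame) -> dict:
    """Confusion-matrix summary of accepted calls against planted truth.

    ``truth`` rows carry (chrom, pos, class) with class in
    {somatic, germline, artifact}. Sensitivity = TP / planted somatics;
    PPV = TP / accepted calls (None when nothing is accepted);
    specificity = TN / non-somatic assessed loci, where the assessed
    negatives are the nominated non-somatic candidates.
    """
    somatic_loci = {
        (r["chrom"], int(r["pos"]))
        for _, r in truth.iterrows()
        if r["class"] == "somatic"
    }
    accepted = {(c.chrom, c.pos) for c in calls if c.accepted}
    nominated = {(c.chrom, c.pos) for c in calls}
    tp = len(accepted & somatic_loci)
    fp = len(accepted - somatic_loci)
    fn = len(somatic_loci - accepted)
    negatives = nominated - somatic_loci
    tn = len(negatives - accepted)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "ppv": tp / (tp + fp) if (tp + fp) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
    }
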