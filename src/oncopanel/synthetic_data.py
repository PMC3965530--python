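"""Seeded generation of matched tumor/normal pileups with known truth.

The simulator emulates the statistical structure a tumor-normal filter
cascade assumes in deep targeted-panel data:

* per-locus coverage drawn negative-binomially around a target median
  (targeted amplicon coverage is markedly overdispersed relative to
  Poisson);
* a floor of per-locus sequencing error at every locus, binomial at a
  fixed base error rate on one designated non-reference base;
* shared systematic-artifact loci with an elevated error rate in BOTH
  samples (what the percentile and blacklist filters exist to remove);
* heterozygous germline variants, binomial at 50% allele fraction in
  both samples;
* somatic variants planted in the tumor only, at allele fractions drawn
  uniformly from a configurable range;
* optionally a fraction of loci forced below the coverage-gate floors.

Every planted event is recorded in a truth table so callers can score
sensitivity and positive predictive value. A cohort-level generator
produces per-patient mutation burdens under Poisson models stratified
by smoking and HPV status, for recovery of group-level effect sizes.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from oncopanel.pileup_io import (
    BASES,
    Panel,
    PanelLocus,
    PileupTable,
    write_panel_bed,
    write_pileup,
    write_blacklist,
    write_clinical,
)

TRUTH_COLUMNS = ["chrom", "pos", "sample", "class", "vaf"]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one matched-pair simulation.

    Counts of planted events must fit the panel; fractions live in
    [0, 1]; the artifact error rate must exceed the base error rate or
    artifact loci would be indistinguishable from the noise floor.
    """

    n_loci: int = 2000
    median_coverage: int = 1000
    coverage_dispersion: float = 10.0  # negative-binomial size parameter
    base_error_rate: float = 0.002
    n_germline: int = 20
    germline_het_vaf: float = 0.5
    n_somatic: int = 5
    somatic_vaf_range: tuple[float, float] = (0.08, 0.50)
    n_artifact_loci: int = 10
    artifact_error_rate: float = 0.02
    low_coverage_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.somatic_vaf_range
        fractions = {
            "base_error_rate": self.base_error_rate,
            "germline_het_vaf": self.germline_het_vaf,
            "artifact_error_rate": self.artifact_error_rate,
            "low_coverage_fraction": self.low_coverage_fraction,
            "somatic_vaf low": lo,
            "somatic_vaf high": hi,
        }
        for name, v in fractions.items():
            if not math.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if lo > hi:
            raise ValueError("somatic_vaf_range low > high")
        if self.artifact_error_rate <= self.base_error_rate:
            raise ValueError("artifact_error_rate must exceed base_error_rate")
        if not math.isfinite(self.coverage_dispersion) or self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive and finite")
        for name in ("n_loci", "median_coverage", "n_germline", "n_somatic",
                     "n_artifact_loci"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_germline + self.n_somatic + self.n_artifact_loci > self.n_loci:
            raise ValueError("planted events exceed the number of panel loci")


@dataclass(frozen=True)
class CohortParams:
    """Parameters of a cohort-level burden simulation.

    Defaults mirror the group-level effects the landscape statistics are
    asked to recover: non-smokers average 0.25 mutations per sample and
    smokers 3.2-fold more; the TP53 mutation rate is 0.43 per sample in
    HPV-negative and 0.11 in HPV-positive patients.
    """

    n_patients: int = 37
    smoker_fraction: float = 0.65
    hpv_pos_fraction: float = 0.24
    burden_mean_nonsmoker: float = 0.25
    burden_fold_smoker: float = 3.2
    tp53_rate_hpv_neg: float = 0.43
    tp53_rate_hpv_pos: float = 0.11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for name in ("smoker_fraction", "hpv_pos_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("burden_mean_nonsmoker", "burden_fold_smoker",
                     "tp53_rate_hpv_neg", "tp53_rate_hpv_pos"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative finite number")


def random_panel(n_loci: int, seed: int = 0, n_genes: int = 20) -> Panel:
    """A synthetic single-position-per-locus panel for simulations.

    Loci are laid out on one synthetic contig, partitioned round-robin
    over ``GENE01..GENEnn``, alternating hotspot and whole-exon classes.
    """
    loci = []
    for i in range(n_loci):
        gene = f"GENE{(i % n_genes) + 1:02d}"
        start = 1000 + 10 * i  # 0-based; the locus is the single base start+1
        region = "hotspot" if (i % n_genes) % 2 else "whole_exon"
        loci.append(PanelLocus(gene, "chrS", start, start + 1, region))
    return Panel(tuple(loci))


def _draw_depths(rng: np.random.Generator, n: int, params: SimParams) -> np.ndarray:
    """Negative-binomial depths with mean = median_coverage, size = dispersion."""
    size = params.coverage_dispersion
    mean = params.median_coverage
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=n)


def simulate_pair(
    panel: Panel, params: SimParams
) -> tuple[PileupTable, PileupTable, pd.DataFrame]:
    """Simulate one matched tumor/normal pileup pair over ``panel``.

    Returns (tumor, normal, truth). The truth table lists every planted
    event: one row per (locus, sample, class) with the planted allele
    fraction or error rate. Classes are disjoint per locus.
    """
    if params.n_loci != len(panel):
        raise ValueError(
            f"params.n_loci={params.n_loci} but panel has {len(panel)} loci"
        )
    rng = np.random.default_rng(params.seed)
    n = len(panel)
    chroms = np.array([l.chrom for l in panel.loci])
    positions = np.array([l.start + 1 for l in panel.loci])  # 1-based

    ref_idx = rng.integers(0, 4, size=n)
    # designated alternate base: one of the three non-reference bases
    alt_offset = rng.integers(1, 4, size=n)
    alt_idx = (ref_idx + alt_offset) % 4
    bases = np.array(BASES)
    ref_bases = bases[ref_idx]
    alt_bases = bases[alt_idx]

    t_depth = _draw_depths(rng, n, params)
    n_depth = _draw_depths(rng, n, params)

    # disjoint planted classes
    n_planted = params.n_somatic + params.n_germline + params.n_artifact_loci
    planted = rng.choice(n, size=n_planted, replace=False)
    somatic_ix = planted[: params.n_somatic]
    germline_ix = planted[params.n_somatic: params.n_somatic + params.n_germline]
    artifact_ix = planted[params.n_somatic + params.n_germline:]

    t_rate = np.full(n, params.base_error_rate)
    n_rate = np.full(n, params.base_error_rate)
    somatic_vafs = rng.uniform(*params.somatic_vaf_range, size=params.n_somatic)
    t_rate[somatic_ix] = somatic_vafs
    t_rate[germline_ix] = params.germline_het_vaf
    n_rate[germline_ix] = params.germline_het_vaf
    t_rate[artifact_ix] = params.artifact_error_rate
    n_rate[artifact_ix] = params.artifact_error_rate

    if params.low_coverage_fraction > 0:
        unplanted = np.setdiff1d(np.arange(n), planted)
        n_low = int(round(params.low_coverage_fraction * n))
        n_low = min(n_low, len(unplanted))
        low_ix = rng.choice(unplanted, size=n_low, replace=False)
        # depths well below both gate floors (absolute 100-read floor)
        t_depth[low_ix] = rng.integers(5, 60, size=n_low)
        n_depth[low_ix] = rng.integers(5, 60, size=n_low)

    t_alt = rng.binomial(t_depth, t_rate)
    n_alt = rng.binomial(n_depth, n_rate)

    def build(sample_id: str, depth, alt) -> PileupTable:
        counts = {f"count_{b}": np.zeros(n, dtype=np.int64) for b in BASES}
        frame = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": positions,
                "ref_base": ref_bases,
                "depth": depth.astype(np.int64),
                **counts,
            }
        )
        col_idx = {b: i for i, b in enumerate(BASES)}
        alt_cols = np.array([f"count_{b}" for b in BASES])[alt_idx]
        for b in BASES:
            mask = alt_cols == f"count_{b}"
            frame.loc[mask, f"count_{b}"] = alt[mask]
        return PileupTable(sample_id=sample_id, records=frame)

    tumor = build("tumor", t_depth, t_alt)
    normal = build("normal", n_depth, n_alt)

    truth_rows = []
    for ix, vaf in zip(somatic_ix, somatic_vafs):
        truth_rows.append((chroms[ix], int(positions[ix]), "tumor", "somatic", float(vaf)))
    for ix in germline_ix:
        truth_rows.append(
            (chroms[ix], int(positions[ix]), "both", "germline", params.germline_het_vaf)
        )
    for ix in artifact_ix:
        truth_rows.append(
            (chroms[ix], int(positions[ix]), "both", "artifact", params.artifact_error_rate)
        )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return tumor, normal, truth


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate cohort-level clinical covariates and mutation burdens.

    Returns (clinical, counts): clinical has sample_id, smoker (yes/no),
    hpv_status (pos/neg); counts has per-patient ``total_mutations``
    (Poisson, mean scaled by the smoker fold) and ``tp53_mutations``
    (Poisson at the HPV-stratified rate).
    """
    rng = np.random.default_rng(params.seed)
    ids = [f"S{i + 1}" for i in range(params.n_patients)]
    smoker = rng.random(params.n_patients) < params.smoker_fraction
    hpv_pos = rng.random(params.n_patients) < params.hpv_pos_fraction
    burden_mean = np.where(
        smoker,
        params.burden_mean_nonsmoker * params.burden_fold_smoker,
        params.burden_mean_nonsmoker,
    )
    tp53_rate = np.where(hpv_pos, params.tp53_rate_hpv_pos, params.tp53_rate_hpv_neg)
    total = rng.poisson(burden_mean)
    tp53 = rng.poisson(tp53_rate)
    clinical = pd.DataFrame(
        {
            "sample_id": ids,
            "smoker": np.where(smoker, "yes", "no"),
            "hpv_status": np.where(hpv_pos, "pos", "neg"),
        }
    )
    counts = pd.DataFrame(
        {"sample_id": ids, "total_mutations": total, "tp53_mutations": tp53}
    )
    return clinical, counts


def counts_to_mutation_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Expand per-patient counts into one row per mutation.

    TP53 counts become gene="TP53" rows; the remaining burden becomes
    synthetic gene="OTHER" rows, so gene-level and total-burden
    statistics can both be computed from the same table shape the
    landscape module expects.
    """
    rows = []
    pos = 1
    for _, rec in counts.iterrows():
        for _ in range(int(rec["tp53_mutations"])):
            rows.append(("TP53", "chr17", pos, "G", "A", "NON_SYNONYMOUS",
                         "cGa/cAa", "p.R1Q", rec["sample_id"]))
            pos += 1
        extra = int(rec["total_mutations"])
        for _ in range(extra):
            rows.append(("OTHER", "chrS", pos, "C", "T", "NON_SYNONYMOUS",
                         "tCa/tTa", "p.S1L", rec["sample_id"]))
            pos += 1
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "pos", "ref_base", "alt_base", "effect",
                 "cds_change", "protein_change", "sample_id"],
    )


def write_fixture_suite(outdir: str | os.PathLike, params: SimParams | None = None,
                        cohort: CohortParams | None = None) -> dict[str, str]:
    """Emit a small deterministic benchmark to ``outdir``.

    Writes a panel BED, tumor/normal pileup TSVs, a blacklist, the truth
    table and a clinical covariate table; returns a manifest mapping
    file role to path with an sha256 of each file.
    """
    params = params or SimParams(n_loci=600, n_somatic=4, n_germline=10,
                                 n_artifact_loci=6, low_coverage_fraction=0.02,
                                 seed=7)
    cohort = cohort or CohortParams(seed=7)
    os.makedirs(outdir, exist_ok=True)
    panel = random_panel(params.n_loci, seed=params.seed)
    tumor, normal, truth = simulate_pair(panel, params)
    clinical, counts = simulate_cohort(cohort)
    # blacklist: first half of the artifact loci, emulating prior knowledge
    artifacts = truth[truth["class"] == "artifact"]
    known = artifacts.head(len(artifacts) // 2)
    blacklist = {(r["chrom"], int(r["pos"])) for _, r in known.iterrows()}

    paths = {
        "panel": os.path.join(outdir, "panel.bed"),
        "tumor": os.path.join(outdir, "tumor.pileup.tsv"),
        "normal": os.path.join(outdir, "normal.pileup.tsv"),
        "blacklist": os.path.join(outdir, "blacklist.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "clinical": os.path.join(outdir, "clinical.tsv"),
        "counts": os.path.join(outdir, "cohort_counts.tsv"),
    }
    write_panel_bed(panel, paths["panel"])
    write_pileup(tumor, paths["tumor"])
    write_pileup(normal, paths["normal"])
    write_blacklist(blacklist, paths["blacklist"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_clinical(clinical, paths["clinical"])
    counts.to_csv(paths["counts"], sep="\t", index=False)

    manifest = {}
    for role, path in paths.items():
        with open(path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        manifest[role] = {"path": path, "sha256": digest}
    return manifest
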