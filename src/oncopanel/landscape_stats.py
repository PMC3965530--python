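"""Mutation-landscape summaries and clinical association statistics.

Given an annotated mutation table (one row per accepted mutation) and a
cohort size, this module computes the standard landscape quantities:
per-gene mutation counts and patient rates, per-patient burden, the
gene-by-patient mutation matrix ranked by gene rate (the oncoprint
ordering), and two-group comparisons (mean burden, fold change, Fisher
exact test on mutated-vs-not by group).

Two per-gene notions are deliberately kept separate: ``mutation_count``
counts table rows (a patient with two hits in one gene contributes 2),
while ``patients_mutated`` counts distinct patients (contributes 1);
the percent rate is patients_mutated / n_patients.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# Fisher ties: tables whose probability is within this relative slack of
# the observed table's count as "as extreme" (guards float round-off).
_TIE_EPS = 1e-9


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (29.72973 -> 29.7; 8.15 -> 8.2)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _natural_sample_key(sample_id: str):
    m = re.match(r"^([A-Za-z]*)(\d+)$", str(sample_id))
    if m:
        return (m.group(1), int(m.group(2)))
    return (str(sample_id), 0)


@dataclass
class CohortSummary:
    """Per-gene and per-patient landscape summary plus the ranked matrix."""

    n_patients: int
    per_gene: pd.DataFrame      # index gene; mutation_count, patients_mutated, percent_patients
    per_patient: pd.Series      # index sample_id; mutation count
    matrix: pd.DataFrame        # genes x patients, ranked by percent desc


def summarize(table: pd.DataFrame, n_patients: int) -> CohortSummary:
    """Summarize an annotated mutation table over a cohort of ``n_patients``.

    Multiplicities are preserved: a patient with two mutations in one
    gene contributes 2 to that gene's mutation_count and 1 to its
    patients_mutated. Percent rates are rounded to one decimal, half
    away from zero. The matrix rows are ordered by percent descending
    with alphabetical tie-break; columns by natural sample order.
    """
    observed = table["sample_id"].nunique() if len(table) else 0
    if n_patients < observed:
        raise ValueError(
            f"n_patients={n_patients} smaller than {observed} observed samples"
        )
    if len(table) == 0:
        return CohortSummary(
            n_patients=n_patients,
            per_gene=pd.DataFrame(
                columns=["mutation_count", "patients_mutated", "percent_patients"]
            ),
            per_patient=pd.Series(dtype=int),
            matrix=pd.DataFrame(),
        )
    per_gene = (
        table.groupby("gene")
        .agg(
            mutation_count=("sample_id", "size"),
            patients_mutated=("sample_id", "nunique"),
        )
        .assign(
            percent_patients=lambda df: [
                round_half_away(100.0 * k / n_patients) for k in df["patients_mutated"]
            ]
        )
    )
    per_patient = (
        table.groupby("sample_id").size().sort_index(key=lambda ix: ix.map(_natural_sample_key))
    )
    matrix = (
        table.groupby(["gene", "sample_id"]).size().unstack(fill_value=0)
    )
    # rank genes by patient rate descending, ties alphabetical
    order = sorted(per_gene.index, key=lambda g: (-per_gene.loc[g, "percent_patients"], g))
    cols = sorted(matrix.columns, key=_natural_sample_key)
    matrix = matrix.loc[order, cols]
    return CohortSummary(
        n_patients=n_patients,
        per_gene=per_gene,
        per_patient=per_patient,
        matrix=matrix,
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Computed by summing, at fixed margins, the hypergeometric
    probabilities of every table at most as probable as the observed
    one (probability-mass method, not tail doubling).
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("expected a 2x2 table of non-negative integers")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    a = arr[0, 0]
    r1, r2 = arr[0].sum(), arr[1].sum()
    c1 = arr[:, 0].sum()
    n = arr.sum()
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(pmf[pmf <= p_obs * (1 + _TIE_EPS)].sum())


@dataclass
class GroupComparison:
    """Two-group burden comparison with Fisher exact association test."""

    labels: tuple[str, str]
    means: tuple[float, float]
    fold: float                 # larger mean / smaller mean; inf when min=0<max
    table: np.ndarray           # rows: groups; cols: (any mutation, none)
    fisher_p: float


def group_burden(burdens: dict, grouping: dict) -> GroupComparison:
    """Compare per-patient mutation burden between exactly two groups.

    ``burdens`` maps sample -> mutation count (zero allowed);
    ``grouping`` maps sample -> group label; samples without a label
    are excluded. Fold is max/min of the group means (infinite when the
    smaller mean is 0 and the larger is not; 1.0 when both are 0). The
    Fisher test is on the 2x2 table (>=1 mutation vs none) x group.
    """
    labels = sorted(set(grouping.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    groups = {lab: [s for s, g in grouping.items() if g == lab] for lab in labels}
    for lab, members in groups.items():
        if not members:
            raise ValueError(f"group {lab!r} has no members")
        missing = [s for s in members if s not in burdens]
        if missing:
            raise ValueError(f"samples {missing} have no burden entry")
    means = tuple(
        float(np.mean([burdens[s] for s in groups[lab]])) for lab in labels
    )
    lo, hi = min(means), max(means)
    if hi == 0:
        fold = 1.0
    elif lo == 0:
        fold = math.inf
    else:
        fold = hi / lo
    contingency = np.array(
        [
            [
                sum(1 for s in groups[lab] if burdens[s] > 0),
                sum(1 for s in groups[lab] if burdens[s] == 0),
            ]
            for lab in labels
        ]
    )
    p = fisher_exact(contingency)
    return GroupComparison(
        labels=tuple(labels), means=means, fold=fold, table=contingency, fisher_p=p
    )


def gene_rate_by_group(
    table: pd.DataFrame, grouping: dict, gene: str
) -> dict:
    """Per-group per-sample mutation rate for one gene, and their ratio.

    rate(group) = number of ``gene`` mutation rows among the group's
    samples / group size. The ratio is reported larger/smaller along
    with its orientation; a zero rate opposite a positive one yields an
    infinite ratio.
    """
    labels = sorted(set(grouping.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    sizes = {lab: sum(1 for g in grouping.values() if g == lab) for lab in labels}
    for lab, size in sizes.items():
        if size == 0:
            raise ValueError(f"group {lab!r} is empty")
    gene_rows = table[table["gene"] == gene]
    counts = {lab: 0 for lab in labels}
    for _, row in gene_rows.iterrows():
        lab = grouping.get(row["sample_id"])
        if lab is not None:
            counts[lab] += 1
    rates = {lab: counts[lab] / sizes[lab] for lab in labels}
    vals = [rates[lab] for lab in labels]
    lo, hi = min(vals), max(vals)
    if hi == 0:
        ratio = 1.0
    elif lo == 0:
        ratio = math.inf
    else:
        ratio = hi / lo
    higher = labels[int(vals[1] > vals[0])]
    return {"rates": rates, "ratio": ratio, "higher_group": higher}


def export_matrix(summary: CohortSummary, path) -> pd.DataFrame:
    """Write the ranked gene-by-patient matrix as TSV.

    Genes as rows (rate descending, ties alphabetical), patients as
    columns, integer counts, plus a final ``TOTAL`` row of per-patient
    burdens. Returns the frame written.
    """
    matrix = summary.matrix.copy()
    totals = matrix.sum(axis=0)
    out = pd.concat([matrix, totals.to_frame("TOTAL").T])
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    return out
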