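"""Readers and writers for every external format the pipeline touches.

Formats
-------
* Panel as BED (0-based, half-open), name column ``GENE`` or
  ``GENE:region_class`` with region_class in {hotspot, whole_exon}.
* Pileups, blacklists, mutation tables and clinical covariates as
  tab-separated text with a ``#``-prefixed header line.
* Somatic calls as VCFv4.2.

Coordinates are 1-based everywhere except BED, matching each format's
convention. Chromosome names are normalized to the ``chr``-prefixed
dialect on read (mutation tables in the wild print both).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

log = logging.getLogger(__name__)

REGION_CLASSES = frozenset({"hotspot", "whole_exon"})
BASES = ("A", "C", "G", "T")
EFFECT_VOCABULARY = frozenset(
    {"NON_SYNONYMOUS", "STOP_GAINED", "SILENT", "SPLICE_SITE"}
)

PILEUP_COLUMNS = [
    "chrom",
    "pos",
    "ref_base",
    "depth",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
]

MUTATION_COLUMNS = [
    "gene",
    "chrom",
    "pos",
    "ref_base",
    "alt_base",
    "effect",
    "cds_change",
    "protein_change",
    "sample_id",
]


class FormatError(ValueError):
    """Structurally invalid input; message carries the offending line."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom if chrom.startswith("chr") else f"chr{chrom}"


class PanelLocus(NamedTuple):
    gene: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    region_class: str


@dataclass(frozen=True)
class Panel:
    """Targeted loci, sorted by (chrom, start); unique by interval."""

    loci: tuple[PanelLocus, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.loci, key=lambda l: (l.chrom, l.start, l.end)))
        object.__setattr__(self, "loci", ordered)
        seen: set[tuple[str, int, int]] = set()
        for locus in ordered:
            if locus.start >= locus.end:
                raise FormatError(
                    f"degenerate interval {locus.chrom}:{locus.start}-{locus.end}"
                )
            if locus.region_class not in REGION_CLASSES:
                raise FormatError(f"unknown region class {locus.region_class!r}")
            key = (locus.chrom, locus.start, locus.end)
            if key in seen:
                raise FormatError(f"duplicate panel interval {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.loci)

    def genes(self) -> list[str]:
        return sorted({l.gene for l in self.loci})


@dataclass
class PileupTable:
    """Per-locus read counts for one sample.

    ``records`` columns: chrom, pos (1-based), ref_base, depth,
    count_A..count_T. Each base count is bounded by depth.
    """

    sample_id: str
    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PILEUP_COLUMNS))

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"pileup table missing columns {missing}")
        self.records = df[PILEUP_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.records
        if df.empty:
            return
        bad_ref = ~df["ref_base"].isin(BASES)
        if bad_ref.any():
            row = df[bad_ref].iloc[0]
            raise FormatError(
                f"unknown ref base {row['ref_base']!r} at {row['chrom']}:{row['pos']}"
            )
        if (df["depth"] < 0).any() or (df[[f"count_{b}" for b in BASES]] < 0).any().any():
            raise FormatError("negative depth or base count")
        for b in BASES:
            over = df[f"count_{b}"] > df["depth"]
            if over.any():
                row = df[over].iloc[0]
                raise FormatError(
                    f"count_{b}={row[f'count_{b}']} exceeds depth={row['depth']} "
                    f"at {row['chrom']}:{row['pos']}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def locus_index(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.records[["chrom", "pos"]])


# ---------------------------------------------------------------------------
# Panel BED
# ---------------------------------------------------------------------------

def read_panel_bed(path: str | os.PathLike) -> Panel:
    """Parse a panel BED file (chrom, start, end, name[=gene[:region_class]]).

    Rows sorted into canonical (chrom, start) order; malformed rows are
    reported with their line number. Missing region class defaults to
    whole_exon.
    """
    loci: list[PanelLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom = normalize_chrom(fields[0])
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3]
            gene, _, region = name.partition(":")
            region = region or "whole_exon"
            if region not in REGION_CLASSES:
                raise FormatError(f"{path}:{lineno}: unknown region class {region!r}")
            loci.append(PanelLocus(gene, chrom, start, end, region))
    if not loci:
        raise FormatError(f"{path}: empty panel")
    return Panel(tuple(loci))


def write_panel_bed(panel: Panel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for l in panel.loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.gene}:{l.region_class}\n")


# ---------------------------------------------------------------------------
# Pileup TSV
# ---------------------------------------------------------------------------

def read_pileup(path: str | os.PathLike) -> PileupTable:
    """Read a pileup TSV; the header row carries the sample id.

    Header: ``#sample_id=<id>`` then a column header line. Round-trips
    with :func:`write_pileup`.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#sample_id="):
            raise FormatError(f"{path}:1: missing '#sample_id=' header")
        sample_id = first.split("=", 1)[1]
        body = fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t")
    if df.empty:
        log.warning("%s: pileup has no data rows", path)
        df = pd.DataFrame(columns=PILEUP_COLUMNS)
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing pileup columns {missing}")
    if not df.empty:
        df["chrom"] = df["chrom"].map(normalize_chrom)
    return PileupTable(sample_id=sample_id, records=df)


def write_pileup(table: PileupTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sample_id={table.sample_id}\n")
        table.records.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Blacklist TSV
# ---------------------------------------------------------------------------

def read_blacklist(path: str | os.PathLike) -> set[tuple[str, int]]:
    """Set of (chrom, pos) loci flagged as recurrent systematic positives."""
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>pos")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            key = (normalize_chrom(fields[0]), pos)
            if key in out:
                raise FormatError(f"{path}:{lineno}: duplicate blacklist entry {key}")
            out.add(key)
    return out


def write_blacklist(blacklist: Iterable[tuple[str, int]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\n")
        for chrom, pos in sorted(blacklist):
            fh.write(f"{chrom}\t{pos}\n")


# ---------------------------------------------------------------------------
# Mutation table TSV
# ---------------------------------------------------------------------------

def read_mutation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an annotated mutation table (one row per accepted mutation).

    Columns: gene, chrom, pos, ref_base, alt_base, effect, cds_change,
    protein_change, sample_id. The effect vocabulary is closed:
    NON_SYNONYMOUS, STOP_GAINED, SILENT, SPLICE_SITE. Chromosomes are
    accepted with or without the ``chr`` prefix and normalized to the
    prefixed dialect.
    """
    df = pd.read_csv(path, sep="\t", comment=None, dtype={"chrom": str})
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mutation-table columns {missing}")
    bad = ~df["effect"].isin(EFFECT_VOCABULARY)
    if bad.any():
        label = df.loc[bad, "effect"].iloc[0]
        raise FormatError(f"{path}: unknown effect label {label!r}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    return df[MUTATION_COLUMNS].reset_index(drop=True)


def write_mutation_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def table3_fixture() -> pd.DataFrame:
    """The packaged 26-row worked-example mutation table.

    A published 51-gene panel study of 37 head-and-neck squamous cell
    carcinoma tumor/normal pairs; 26 accepted point mutations across 11
    genes. Used throughout the tests and the worked example.
    """
    here = os.path.dirname(__file__)
    return read_mutation_table(os.path.join(here, "data", "hnscc37_mutations.tsv"))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_FILTERS = {
    "low_coverage": "Locus fails the coverage gate in tumor or normal",
    "low_vaf": "Tumor variant allele fraction below the call threshold",
    "germline": "Matched normal shows >1% variant reads (putative germline)",
    "systematic": "Score difference within the background percentile (systematic error)",
    "blacklist": "Locus on the recurrent systematic-positive blacklist",
}

_VCF_INFO = {
    "TVAF": ("1", "Float", "Tumor variant allele fraction"),
    "NVAF": ("1", "Float", "Normal variant allele fraction"),
    "SCOREDIFF": ("1", "Float", "Tumor minus normal Phred-scaled variant score"),
    "GENE": ("1", "String", "Panel gene symbol"),
    "EFFECT": ("1", "String", "Codon-level effect class"),
}


def write_vcf(calls: Sequence, path: str | os.PathLike) -> None:
    """Write somatic calls as VCFv4.2.

    FILTER is ``PASS`` for accepted calls, else the semicolon-joined,
    alphabetically sorted flag set. Records are sorted by (chrom, pos);
    unsorted input is sorted, never rejected.
    """
    lines = ["##fileformat=VCFv4.2", "##source=oncopanel"]
    for name, desc in sorted(_VCF_FILTERS.items()):
        lines.append(f'##FILTER=<ID={name},Description="{desc}">')
    for key, (num, typ, desc) in _VCF_INFO.items():
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    def sort_key(c):
        return (c.chrom, c.pos)

    for call in sorted(calls, key=sort_key):
        if not call.ref_base or not call.alt_base:
            raise FormatError(f"call at {call.chrom}:{call.pos} missing ref/alt")
        flt = "PASS" if not call.filter_flags else ";".join(sorted(call.filter_flags))
        info = (
            f"TVAF={call.tumor_vaf:.6g};NVAF={call.normal_vaf:.6g};"
            f"SCOREDIFF={call.score_diff:.6g};GENE={call.gene}"
        )
        if getattr(call, "effect", None):
            info += f";EFFECT={call.effect}"
        lines.append(
            f"{call.chrom}\t{call.pos}\t.\t{call.ref_base}\t{call.alt_base}"
            f"\t.\t{flt}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    """Clinical covariates: sample_id, smoker (yes/no/ND), hpv_status (pos/neg/ND)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "smoker", "hpv_status"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing clinical column {col!r}")
    return df


def write_clinical(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
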