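"""Codon-level effect classification for single-base substitutions.

Mutation tables in targeted-panel studies print a compact CDS-change
dialect, e.g. ``aTc/aCc``: reference and alternate codon separated by
a slash, with exactly one uppercase letter per codon marking the
substituted position. This module parses that dialect, translates both
codons under the standard genetic code, and assigns one of four effect
classes: NON_SYNONYMOUS (missense), STOP_GAINED (nonsense), SILENT
(synonymous), or SPLICE_SITE. Splice-site effects depend on locus
annotation, not codon content, so they are carried through but never
inferred here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

log = logging.getLogger(__name__)

# Standard genetic code, stop rendered "*".
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

EFFECT_CLASSES = ("NON_SYNONYMOUS", "STOP_GAINED", "SILENT", "SPLICE_SITE")

EffectClass = str


class CdsChangeError(ValueError):
    """Malformed CDS-change string."""


@dataclass(frozen=True)
class CodonChange:
    """A single-base codon substitution.

    ref_codon/alt_codon are uppercase DNA triplets differing at exactly
    ``changed_index``; codon_number is the 1-based protein position when
    known (0 when the table omits it).
    """

    ref_codon: str
    alt_codon: str
    changed_index: int
    codon_number: int = 0

    def __post_init__(self) -> None:
        for codon in (self.ref_codon, self.alt_codon):
            if len(codon) != 3 or any(b not in "ACGT" for b in codon):
                raise CdsChangeError(f"invalid codon {codon!r}")
        diffs = [i for i in range(3) if self.ref_codon[i] != self.alt_codon[i]]
        if diffs != [self.changed_index]:
            raise CdsChangeError(
                f"codons {self.ref_codon}/{self.alt_codon} must differ exactly "
                f"at index {self.changed_index}"
            )


def parse_cds_change(text: str, codon_number: int = 0) -> CodonChange:
    """Parse a ``refCodon/altCodon`` CDS-change string.

    Exactly one uppercase letter per codon, at the same index in both,
    marks the substituted base, e.g. ``"aTc/aCc"`` -> (ATC, ACC, 1).
    """
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise CdsChangeError(f"{text!r}: expected '<codon>/<codon>'")
    ref_raw, alt_raw = parts
    if len(ref_raw) != 3 or len(alt_raw) != 3:
        raise CdsChangeError(f"{text!r}: codons must be 3 letters")
    ref_upper = [i for i, c in enumerate(ref_raw) if c.isupper()]
    alt_upper = [i for i, c in enumerate(alt_raw) if c.isupper()]
    if len(ref_upper) != 1 or len(alt_upper) != 1:
        raise CdsChangeError(f"{text!r}: exactly one uppercase letter per codon")
    if ref_upper != alt_upper:
        raise CdsChangeError(f"{text!r}: uppercase positions disagree")
    idx = ref_upper[0]
    ref_codon, alt_codon = ref_raw.upper(), alt_raw.upper()
    if ref_codon == alt_codon:
        raise CdsChangeError(f"{text!r}: reference and alternate codons identical")
    return CodonChange(ref_codon, alt_codon, idx, codon_number)


def translate_codon(codon: str) -> str:
    try:
        return GENETIC_CODE[codon.upper()]
    except KeyError as exc:
        raise CdsChangeError(f"codon {codon!r} contains non-ACGT characters") from exc


def classify_effect(change: CodonChange) -> EffectClass:
    """Assign an effect class from the two translated codons.

    Alternate codon is a stop and reference is not -> STOP_GAINED; equal
    amino acids -> SILENT; otherwise NON_SYNONYMOUS. Loss of a reference
    stop codon is classified NON_SYNONYMOUS with a warning (read-through
    is outside the four-class vocabulary).
    """
    ref_aa = translate_codon(change.ref_codon)
    alt_aa = translate_codon(change.alt_codon)
    if ref_aa == "*":
        log.warning(
            "reference codon %s is a stop (stop-loss); classifying NON_SYNONYMOUS",
            change.ref_codon,
        )
        return "NON_SYNONYMOUS"
    if alt_aa == "*":
        return "STOP_GAINED"
    if ref_aa == alt_aa:
        return "SILENT"
    return "NON_SYNONYMOUS"


def protein_change(change: CodonChange) -> str:
    """HGVS-flavored short protein change, e.g. ``p.I96T``; stop is ``*``."""
    ref_aa = translate_codon(change.ref_codon)
    alt_aa = translate_codon(change.alt_codon)
    return f"p.{ref_aa}{change.codon_number}{alt_aa}"


def _codon_number_from_protein(text: str) -> int:
    digits = "".join(c for c in str(text) if c.isdigit())
    return int(digits) if digits else 0


def verify_mutation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Re-derive effect and protein change for every row; report mismatches.

    Returns a report frame with one row per input row: the recomputed
    values, and boolean ``effect_ok`` / ``protein_ok`` columns. Rows whose
    CDS change cannot be parsed are reported (parse_error column), not
    raised. SPLICE_SITE rows are exempt from effect recomputation since
    that class is locus-, not codon-, derived.
    """
    rows = []
    for _, rec in table.iterrows():
        entry = {
            "gene": rec["gene"],
            "sample_id": rec["sample_id"],
            "cds_change": rec["cds_change"],
            "printed_effect": rec["effect"],
            "printed_protein": rec["protein_change"],
            "recomputed_effect": None,
            "recomputed_protein": None,
            "parse_error": "",
            "effect_ok": False,
            "protein_ok": False,
        }
        try:
            change = parse_cds_change(
                rec["cds_change"], _codon_number_from_protein(rec["protein_change"])
            )
        except CdsChangeError as exc:
            entry["parse_error"] = str(exc)
            rows.append(entry)
            continue
        eff = classify_effect(change)
        prot = protein_change(change)
        entry["recomputed_effect"] = eff
        entry["recomputed_protein"] = prot
        entry["effect_ok"] = (
            rec["effect"] == "SPLICE_SITE" or eff == rec["effect"]
        )
        entry["protein_ok"] = prot == rec["protein_change"]
        rows.append(entry)
    columns = [
        "gene", "sample_id", "cds_change", "printed_effect", "printed_protein",
        "recomputed_effect", "recomputed_protein", "parse_error",
        "effect_ok", "protein_ok",
    ]
    return pd.DataFrame(rows, columns=columns)


def annotate_calls(calls: Iterable, cds_changes: dict) -> None:
    """Attach effect classes to somatic calls given locus->CDS-change map."""
    for call in calls:
        key = (call.chrom, call.pos)
        if key in cds_changes:
            call.effect = classify_effect(parse_cds_change(cds_changes[key]))
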