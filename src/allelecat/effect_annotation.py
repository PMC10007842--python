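"""Functional-effect prediction for coding SNPs/indels and splice-core variants.

Each variant ALT is evaluated against a gene's primary transcript (the one
with the longest total CDS).  The classifier distinguishes synonymous,
missense, stop-gain/loss, start-loss, frameshift, conservative/disruptive
in-frame indels and splice donor/acceptor core changes (the first/last two
bases of an intron), and attaches a compact amino-acid-change notation such
as ``T27A``, ``R75fs`` or ``T2del``.

Effect terms map onto two orthogonal labels used downstream:

* severity — ``null`` (predicted loss of function), ``modifying`` (changes
  the protein but may retain function) or ``non_modifying``; only non-
  ``non_modifying`` effects enter the allele catalog.
* display_color — the color token a front-end would use for the cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .io_formats import GeneModel, GenomeSequence, Transcript, VariantRecord

__all__ = [
    "EFFECT_TERMS",
    "EffectCall",
    "AnnotatedVariant",
    "NoCodingTranscript",
    "primary_transcript",
    "extract_cds",
    "translate",
    "reverse_complement",
    "annotate_variant",
    "annotate_panel",
    "classify_severity",
    "aa_change_notation",
    "effects_from_ann",
]


class NoCodingTranscript(Exception):
    """Signals a gene with no CDS-bearing transcript."""


# severity class -> effect terms; splice variants are treated as null
# (function-abolishing) but display green, which takes precedence over red.
_NULL_TERMS = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)
_MODIFYING_ONLY_TERMS = frozenset(
    {
        "missense_variant",
        "conservative_inframe_insertion",
        "conservative_inframe_deletion",
        "disruptive_inframe_insertion",
        "disruptive_inframe_deletion",
    }
)
_NON_MODIFYING_TERMS = frozenset({"synonymous_variant", "non_coding_or_other"})

EFFECT_TERMS: tuple[str, ...] = tuple(
    sorted(_NULL_TERMS | _MODIFYING_ONLY_TERMS | _NON_MODIFYING_TERMS)
)

_COLORS = {
    "missense_variant": "blue",
    "conservative_inframe_insertion": "orange",
    "conservative_inframe_deletion": "orange",
    "splice_donor_variant": "green",
    "splice_acceptor_variant": "green",
    "stop_gained": "red",
    "stop_lost": "red",
    "start_lost": "red",
    "frameshift_variant": "red",
    "disruptive_inframe_insertion": "white",
    "disruptive_inframe_deletion": "white",
    "synonymous_variant": "white",
    "non_coding_or_other": "white",
}


def classify_severity(effect_term: str) -> tuple[str, str]:
    """Map an effect term to its (severity, display_color) pair."""
    if effect_term in _NULL_TERMS:
        return "null", _COLORS[effect_term]
    if effect_term in _MODIFYING_ONLY_TERMS:
        return "modifying", _COLORS[effect_term]
    if effect_term in _NON_MODIFYING_TERMS:
        return "non_modifying", _COLORS[effect_term]
    raise ValueError(f"unknown effect term {effect_term!r}")


@dataclass(frozen=True)
class EffectCall:
    """One (variant, alt, gene) functional consequence."""

    gene_id: str
    transcript_id: str
    effect_term: str
    aa_notation: str
    severity: str
    display_color: str


@dataclass
class AnnotatedVariant:
    """A variant record plus its effect calls keyed by (gene_id, alt_index)."""

    record: VariantRecord
    effects: dict[tuple[str, int], EffectCall]


_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def primary_transcript(gene: GeneModel) -> str:
    """The transcript effects are computed on: longest total CDS, ties broken
    by lexicographically smallest transcript id."""
    coding = [tx for tx in gene.transcripts if tx.cds]
    if not coding:
        raise NoCodingTranscript(gene.gene_id)
    return min(coding, key=lambda tx: (-tx.cds_length, tx.transcript_id)).transcript_id


def extract_cds(genome: GenomeSequence, gene: GeneModel, transcript_id: str) -> str:
    """Spliced coding sequence in transcription (5'->3') order."""
    tx = gene.transcript(transcript_id)
    parts = [genome.fetch(gene.chrom, s, e) for s, e in tx.cds_intervals]
    seq = "".join(parts)
    return reverse_complement(seq) if gene.strand == "-" else seq


def translate(cds: str) -> str:
    """Standard-genetic-code translation.

    Stops at the first stop codon, rendered ``*``; a trailing incomplete
    codon is ignored; any codon containing N translates to ``X``.
    """
    aas: list[str] = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in _CODON_TABLE.stop_codons:
            aas.append("*")
            break
        aas.append(_CODON_TABLE.forward_table.get(codon, "X"))
    return "".join(aas)


def aa_change_notation(
    effect_term: str, position: int, ref_aa: str = "", alt_aa: str = ""
) -> str:
    """Compact protein-change notation (one-letter amino-acid codes)."""
    if effect_term == "missense_variant":
        return f"{ref_aa}{position}{alt_aa}"
    if effect_term == "stop_gained":
        return f"{ref_aa}{position}*"
    if effect_term == "stop_lost":
        return f"*{position}ext"
    if effect_term == "start_lost":
        return "M1?"
    if effect_term == "frameshift_variant":
        return f"{ref_aa}{position}fs"
    if effect_term.endswith("inframe_deletion"):
        return f"{ref_aa}{position}del"
    if effect_term.endswith("inframe_insertion"):
        return f"{ref_aa}{position}ins"
    return ""


# ---------------------------------------------------------------------------
# Edit normalization and application


def _normalize_edit(pos: int, ref: str, alt: str) -> tuple[int, int, str]:
    """Reduce a VCF (pos, REF, ALT) to a minimal genomic edit.

    Returns (del_start, del_end, inserted) where [del_start, del_end] is the
    deleted reference interval (empty when del_start > del_end) and
    ``inserted`` replaces it at del_start.  Shared prefix then shared suffix
    are stripped, so anchor bases disappear.
    """
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    s = 0
    while s < len(ref) - p and s < len(alt) - p and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]:
        s += 1
    return pos + p, pos + len(ref) - 1 - s, alt[p : len(alt) - s]


def _splice_windows(
    tx: Transcript, strand: str
) -> list[tuple[str, tuple[int, int]]]:
    """Donor/acceptor 2-base windows for each intron of the transcript.

    Introns are the gaps between consecutive CDS segments; the donor is the
    intron end adjacent to the exon transcribed first.
    """
    windows: list[tuple[str, tuple[int, int]]] = []
    ivs = sorted(tx.cds_intervals)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        a, b = e1 + 1, s2 - 1
        if b - a + 1 < 2:
            continue
        if strand == "+":
            windows.append(("splice_donor_variant", (a, a + 1)))
            windows.append(("splice_acceptor_variant", (b - 1, b)))
        else:
            windows.append(("splice_donor_variant", (b - 1, b)))
            windows.append(("splice_acceptor_variant", (a, a + 1)))
    return windows


def _mutated_cds(
    genome: GenomeSequence,
    gene: GeneModel,
    cds_intervals: Iterable[tuple[int, int]],
    del_start: int,
    del_end: int,
    inserted: str,
) -> str:
    """Apply the normalized edit to the spliced CDS.

    Only bases inside CDS segments are removed; the inserted sequence lands
    at its anchor when the anchor falls inside a segment.
    """
    chrom_seq = genome.sequences[gene.chrom]
    out: list[str] = []
    for s, e in cds_intervals:
        for g in range(s, e + 1):
            if g == del_start and inserted:
                out.append(inserted)
            if not (del_start <= g <= del_end):
                out.append(chrom_seq[g - 1])
    seq = "".join(out)
    return reverse_complement(seq) if gene.strand == "-" else seq


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _first_difference(orig: str, mut: str) -> int:
    """Index of the first differing residue (may equal min length)."""
    i = 0
    m = min(len(orig), len(mut))
    while i < m and orig[i] == mut[i]:
        i += 1
    return i


def annotate_variant(
    variant: VariantRecord, alt_index: int, gene: GeneModel, genome: GenomeSequence
) -> EffectCall:
    """Predict the functional effect of one ALT allele on one gene.

    Splice-core windows are checked first; then CDS overlap drives the
    coding classification: an indel whose net length is not a multiple of 3
    is a frameshift, a multiple-of-3 indel is in-frame (conservative when
    the replaced interval is codon-aligned), and substitutions are compared
    codon-by-codon via re-translation.
    """
    if not 1 <= alt_index <= len(variant.alt_seqs):
        raise ValueError(f"alt_index {alt_index} out of range")
    alt = variant.alt_seqs[alt_index - 1]
    if alt.startswith("<"):
        raise ValueError(f"symbolic ALT {alt!r} cannot be annotated")

    tid = primary_transcript(gene)
    tx = gene.transcript(tid)

    def call(term: str, aa: str = "") -> EffectCall:
        sev, color = classify_severity(term)
        return EffectCall(gene.gene_id, tid, term, aa, sev, color)

    ds, de, ins = _normalize_edit(variant.pos, variant.ref_seq, alt)
    has_deletion = ds <= de
    if not has_deletion and not ins:  # REF == ALT; nothing changes
        return call("non_coding_or_other")

    for term, (ws, we) in _splice_windows(tx, gene.strand):
        if has_deletion:
            if ds <= we and de >= ws:
                return call(term)
        elif ws < ds <= we:  # insertion strictly inside the 2-base core
            return call(term)

    cds_ivs = tx.cds_intervals
    touches_cds = any(
        (has_deletion and ds <= e and de >= s) or (not has_deletion and s < ds <= e)
        for s, e in cds_ivs
    )
    if not touches_cds:
        return call("non_coding_or_other")

    orig_cds = extract_cds(genome, gene, tid)
    mut_cds = _mutated_cds(genome, gene, cds_ivs, ds, de, ins)
    orig_p = translate(orig_cds)
    mut_p = translate(mut_cds)
    net = len(mut_cds) - len(orig_cds)
    i = _first_difference(orig_p, mut_p)

    def ref_aa_at(idx: int) -> str:
        return orig_p[idx] if idx < len(orig_p) else "*"

    if i == 0 and orig_p[:1] == "M" and mut_p[:1] != "M":
        return call("start_lost", aa_change_notation("start_lost", 1))
    if net % 3 != 0:
        return call(
            "frameshift_variant",
            aa_change_notation("frameshift_variant", i + 1, ref_aa_at(i)),
        )
    if net != 0:
        cp = _common_prefix_len(orig_cds, mut_cds)
        cs_bound = min(len(orig_cds), len(mut_cds)) - cp
        cs = 0
        while (
            cs < cs_bound
            and orig_cds[len(orig_cds) - 1 - cs] == mut_cds[len(mut_cds) - 1 - cs]
        ):
            cs += 1
        deleted = len(orig_cds) - cp - cs
        aligned = cp % 3 == 0 and deleted % 3 == 0
        kind = "insertion" if net > 0 else "deletion"
        term = f"{'conservative' if aligned else 'disruptive'}_inframe_{kind}"
        return call(term, aa_change_notation(term, i + 1, ref_aa_at(i)))
    if orig_p == mut_p:
        return call("synonymous_variant")
    if i >= min(len(orig_p), len(mut_p)):
        # proteins agree over the overlap but differ in length (change 3' of
        # the stop codon): treat as not affecting the protein product
        return call("synonymous_variant")
    if mut_p[i] == "*":
        return call("stop_gained", aa_change_notation("stop_gained", i + 1, orig_p[i]))
    if orig_p[i] == "*":
        return call("stop_lost", aa_change_notation("stop_lost", i + 1))
    return call(
        "missense_variant",
        aa_change_notation("missense_variant", i + 1, orig_p[i], mut_p[i]),
    )


def annotate_panel(
    records: Iterable[VariantRecord],
    genes: Iterable[GeneModel],
    genome: GenomeSequence,
    use_ann: bool = False,
) -> list[AnnotatedVariant]:
    """Annotate every concrete ALT of every record against overlapping genes.

    With ``use_ann`` set, records carrying SnpEff-style ANN strings are
    annotated from those instead of the internal classifier; records without
    ANN fall back to the internal path.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    gene_ids: set[str] = set()
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
        gene_ids.add(gene.gene_id)
    out: list[AnnotatedVariant] = []
    for rec in records:
        if use_ann and rec.ann:
            out.append(AnnotatedVariant(rec, effects_from_ann(rec, gene_ids)))
            continue
        effects: dict[tuple[str, int], EffectCall] = {}
        for gene in by_chrom.get(rec.chrom, ()):
            if rec.end < gene.start or rec.pos > gene.end:
                continue
            for ai in range(1, len(rec.alt_seqs) + 1):
                if rec.alt_seqs[ai - 1].startswith("<"):
                    continue
                effects[(gene.gene_id, ai)] = annotate_variant(rec, ai, gene, genome)
        out.append(AnnotatedVariant(rec, effects))
    return out


# ---------------------------------------------------------------------------
# SnpEff ANN-field compatibility

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}

_HGVS_P = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)(.*)$")


def _hgvs_p_to_short(hgvs: str) -> str:
    """Convert HGVS.p three-letter notation to the catalog's short form."""
    m = _HGVS_P.match(hgvs)
    if not m:
        return ""
    ref3, pos, rest = m.groups()
    ref1 = _AA3TO1.get(ref3, "X")
    if rest in _AA3TO1:
        return f"{ref1}{pos}{_AA3TO1[rest]}"
    if rest.startswith("fs") or rest == "fs":
        return f"{ref1}{pos}fs"
    if rest.startswith("del"):
        return f"{ref1}{pos}del"
    if rest.startswith("ins") or rest.startswith("dup"):
        return f"{ref1}{pos}ins"
    if rest == "?":
        return "M1?" if ref1 == "M" and pos == "1" else f"{ref1}{pos}?"
    if rest.startswith("ext") or (ref3 == "Ter" and rest):
        return f"*{pos}ext"
    return ""


_ANN_TERM_MAP = {
    "synonymous_variant": "synonymous_variant",
    "stop_retained_variant": "synonymous_variant",
    "missense_variant": "missense_variant",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "start_lost": "start_lost",
    "frameshift_variant": "frameshift_variant",
    "conservative_inframe_insertion": "conservative_inframe_insertion",
    "conservative_inframe_deletion": "conservative_inframe_deletion",
    "disruptive_inframe_insertion": "disruptive_inframe_insertion",
    "disruptive_inframe_deletion": "disruptive_inframe_deletion",
    "inframe_insertion": "conservative_inframe_insertion",
    "inframe_deletion": "conservative_inframe_deletion",
    "splice_donor_variant": "splice_donor_variant",
    "splice_acceptor_variant": "splice_acceptor_variant",
}


def effects_from_ann(
    record: VariantRecord, known_gene_ids: set[str]
) -> dict[tuple[str, int], EffectCall]:
    """Map ANN-field entries onto internal effect calls.

    Each ANN entry is ``Allele|Annotation|Impact|GeneName|GeneID|FeatureType|
    FeatureID|...|HGVS.c|HGVS.p|...``; composite ``&``-joined annotations use
    their first recognized term, anything unrecognized becomes
    ``non_coding_or_other``.
    """
    effects: dict[tuple[str, int], EffectCall] = {}
    alt_to_index = {alt: i for i, alt in enumerate(record.alt_seqs, 1)}
    for entry in record.ann or ():
        fields = entry.split("|")
        if len(fields) < 5:
            continue
        allele, raw_terms = fields[0], fields[1]
        gene_id = fields[4] or fields[3]
        if allele not in alt_to_index or gene_id not in known_gene_ids:
            continue
        term = "non_coding_or_other"
        for raw in raw_terms.split("&"):
            if raw in _ANN_TERM_MAP:
                term = _ANN_TERM_MAP[raw]
                break
        hgvs_p = fields[10] if len(fields) > 10 else ""
        aa = _hgvs_p_to_short(hgvs_p) if term not in _NON_MODIFYING_TERMS else ""
        if term in ("splice_donor_variant", "splice_acceptor_variant"):
            aa = ""
        sev, color = classify_severity(term)
        tid = fields[6] if len(fields) > 6 else ""
        key = (gene_id, alt_to_index[allele])
        if key not in effects:  # keep the first (most severe per SnpEff order)
            effects[key] = EffectCall(gene_id, tid, term, aa, sev, color)
    return effects
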