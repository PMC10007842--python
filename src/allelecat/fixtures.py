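"""Deterministic synthetic panels with constructive ground truth.

The generator writes a toy genome (FASTA), multi-exon gene models on both
strands (GFF3), a diploid panel VCF with planted variants of every
supported effect class plus injected missing calls, an accession
meta-information table, a category spec, and a truth manifest recording —
by construction, not by running the annotator — the expected effect of
every planted variant, every gene's accession->allele partition, the
frequency tables, the per-gene imputation flags and the dataset summary.

Genes are designed in transcript space (start codon, random sense codons,
stop codon, GT..AG introns) and embedded forward or reverse-complemented,
so every planted edit has a known protein consequence.  Missing calls are
only injected where majority filling provably restores the planted
genotype, keeping allele-level truth exact under the built-in imputer.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .catalog_builder import AlleleCatalog
from .io_formats import CategorySpec

__all__ = [
    "FixtureSpecError",
    "FixtureSpec",
    "PlantedVariant",
    "AlleleTruth",
    "GeneTruth",
    "TruthManifest",
    "generate_fixture",
    "verify_against_truth",
    "default_variant_plan",
]


class FixtureSpecError(ValueError):
    """Raised for infeasible fixture specifications."""


_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOP_CODONS
    )
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# effect classes the planner knows how to plant
PLANTABLE_CLASSES = (
    "missense_variant",
    "synonymous_variant",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "conservative_inframe_deletion",
    "disruptive_inframe_deletion",
    "conservative_inframe_insertion",
    "disruptive_inframe_insertion",
    "splice_donor_variant",
    "splice_acceptor_variant",
    "intergenic",
)

_NULL_CLASSES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "splice_donor_variant",
        "splice_acceptor_variant",
    }
)
_NON_MODIFYING_CLASSES = frozenset({"synonymous_variant", "intergenic"})


def default_variant_plan() -> dict[str, int]:
    """The default planted-variant mix: every supported class at least once."""
    return {
        "missense_variant": 3,
        "synonymous_variant": 2,
        "stop_gained": 1,
        "stop_lost": 1,
        "start_lost": 1,
        "frameshift_variant": 2,
        "conservative_inframe_deletion": 1,
        "disruptive_inframe_deletion": 1,
        "conservative_inframe_insertion": 1,
        "disruptive_inframe_insertion": 1,
        "splice_donor_variant": 1,
        "splice_acceptor_variant": 1,
        "intergenic": 1,
    }


@dataclass
class FixtureSpec:
    """Parameters of one synthetic panel.

    Defaults emulate a small re-sequenced germplasm panel: 20 inbred
    (homozygous) accessions over 6 genes on 2 chromosomes, an improvement-
    status partition with a wild/landrace/elite split and ~10% uncategorized
    accessions, a Cultivar flag inside Elite, and a 3% missing-call rate.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 12000
    n_genes: int = 6
    n_accessions: int = 20
    min_codons: int = 40
    max_codons: int = 90
    category_proportions: dict[str, float] = field(
        default_factory=lambda: {"G. soja": 0.2, "Landrace": 0.4, "Elite": 0.3}
    )
    cultivar_fraction: float = 0.5
    variant_plan: dict[str, int] = field(default_factory=default_variant_plan)
    missing_rate: float = 0.03

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.variant_plan.values()):
            raise FixtureSpecError("variant plan counts must be non-negative")
        unknown = set(self.variant_plan) - set(PLANTABLE_CLASSES)
        if unknown:
            raise FixtureSpecError(f"unknown effect classes in plan: {sorted(unknown)}")
        if sum(self.category_proportions.values()) > 1 + 1e-9:
            raise FixtureSpecError("category proportions must sum to <= 1")
        if not 0 <= self.missing_rate < 1:
            raise FixtureSpecError("missing rate must be in [0, 1)")
        if self.n_accessions < 1:
            raise FixtureSpecError("need at least one accession")
        genic = sum(
            c for k, c in self.variant_plan.items() if k != "intergenic"
        )
        if genic and self.n_genes < 1:
            raise FixtureSpecError("genic variants planned but no genes requested")
        splice = self.variant_plan.get("splice_donor_variant", 0) + self.variant_plan.get(
            "splice_acceptor_variant", 0
        )
        if splice and self.n_genes < 2:
            raise FixtureSpecError(
                "splice variants require at least one multi-exon gene (n_genes >= 2)"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class PlantedVariant:
    """One planted variant with its constructively derived expectation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    effect_term: str
    aa_notation: str
    severity: str


@dataclass(frozen=True)
class AlleleTruth:
    state_vector: tuple[str, ...]
    carriers: tuple[str, ...]

    @property
    def total(self) -> int:
        return len(self.carriers)


@dataclass
class GeneTruth:
    position_labels: list[str]
    partition: list[AlleleTruth]
    frequency_rows: list[dict]
    imputation: dict[str, str]  # accession -> "+"/"-"


@dataclass
class TruthManifest:
    seed: int
    accessions: list[str]
    planted: list[PlantedVariant]
    gene_truth: dict[str, GeneTruth]
    masked_cells: list[tuple[str, str, int]]  # (accession, chrom, pos)
    summary: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "accessions": self.accessions,
            "planted": [pv.__dict__ for pv in self.planted],
            "gene_truth": {
                gid: {
                    "position_labels": gt.position_labels,
                    "partition": [
                        {"state_vector": list(at.state_vector), "carriers": list(at.carriers)}
                        for at in gt.partition
                    ],
                    "frequency_rows": gt.frequency_rows,
                    "imputation": gt.imputation,
                }
                for gid, gt in self.gene_truth.items()
            },
            "masked_cells": [list(c) for c in self.masked_cells],
            "summary": self.summary,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            seed=data["seed"],
            accessions=data["accessions"],
            planted=[PlantedVariant(**pv) for pv in data["planted"]],
            gene_truth={
                gid: GeneTruth(
                    position_labels=gt["position_labels"],
                    partition=[
                        AlleleTruth(tuple(a["state_vector"]), tuple(a["carriers"]))
                        for a in gt["partition"]
                    ],
                    frequency_rows=gt["frequency_rows"],
                    imputation=gt["imputation"],
                )
                for gid, gt in data["gene_truth"].items()
            },
            masked_cells=[tuple(c) for c in data["masked_cells"]],
            summary=data["summary"],
        )


# ---------------------------------------------------------------------------
# Transcript-space expectation (independent of the annotation module)


def _tx_translate(cds: str) -> str:
    n = len(cds) // 3 * 3
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        protein = str(Seq(cds[:n]).translate())
    stop = protein.find("*")
    return protein[: stop + 1] if stop >= 0 else protein


def _expected_change(cds: str, off: int, ref_len: int, new_seq: str) -> tuple[str, str]:
    """Classify a transcript-space edit by applying it and diffing proteins.

    Mirrors the field's effect vocabulary: start-loss, frameshift for
    net-length-not-multiple-of-3 indels, conservative/disruptive in-frame
    indels by codon alignment of the replaced interval, stop gain/loss and
    missense from the first differing residue.
    """
    mut = cds[:off] + new_seq + cds[off + ref_len :]
    p0, p1 = _tx_translate(cds), _tx_translate(mut)
    net = len(new_seq) - ref_len
    i = 0
    m = min(len(p0), len(p1))
    while i < m and p0[i] == p1[i]:
        i += 1
    ref_aa = p0[i] if i < len(p0) else "*"
    if i == 0 and p0[:1] == "M" and p1[:1] != "M":
        return "start_lost", "M1?"
    if net % 3 != 0:
        return "frameshift_variant", f"{ref_aa}{i + 1}fs"
    if net != 0:
        cp = 0
        while cp < min(len(cds), len(mut)) and cds[cp] == mut[cp]:
            cp += 1
        cs = 0
        bound = min(len(cds), len(mut)) - cp
        while cs < bound and cds[len(cds) - 1 - cs] == mut[len(mut) - 1 - cs]:
            cs += 1
        deleted = len(cds) - cp - cs
        aligned = cp % 3 == 0 and deleted % 3 == 0
        kind = "insertion" if net > 0 else "deletion"
        term = f"{'conservative' if aligned else 'disruptive'}_inframe_{kind}"
        return term, f"{ref_aa}{i + 1}{'ins' if net > 0 else 'del'}"
    if p0 == p1 or i >= m:
        return "synonymous_variant", ""
    if p1[i] == "*":
        return "stop_gained", f"{p0[i]}{i + 1}*"
    if p0[i] == "*":
        return "stop_lost", f"*{i + 1}ext"
    return "missense_variant", f"{p0[i]}{i + 1}{p1[i]}"


def _severity_of(effect_class: str) -> str:
    if effect_class in _NULL_CLASSES:
        return "null"
    if effect_class in _NON_MODIFYING_CLASSES:
        return "non_modifying"
    return "modifying"


# ---------------------------------------------------------------------------
# Gene design


@dataclass
class _Intron:
    start: int  # genomic, 1-based inclusive
    end: int
    donor: tuple[int, int]  # genomic window, first base first in transcript order
    acceptor: tuple[int, int]
    donor_used: bool = False
    acceptor_used: bool = False


@dataclass
class _GeneDesign:
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds: str  # transcript orientation
    cds_segments: list[tuple[int, int]]  # genomic ascending
    gmap: list[int]  # transcript CDS offset -> genomic position
    introns: list[_Intron]
    n_codons: int
    reserved: set[int] = field(default_factory=set)
    start_used: bool = False
    stop_used: bool = False

    def codon(self, k: int) -> str:
        return self.cds[3 * k : 3 * k + 3]

    def reserve(self, off: int, length: int) -> None:
        self.reserved.update(range(off - 3, off + length + 3))

    def is_free(self, off: int, length: int) -> bool:
        return not any(o in self.reserved for o in range(off - 3, off + length + 3))


def _design_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    n_codons: int,
    n_exons: int,
) -> _GeneDesign:
    """Design one gene and return its genomic embedding."""
    body = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"

    # choose intron insertion offsets within the CDS (transcript coords)
    cut_offsets: list[int] = []
    attempts = 0
    while len(cut_offsets) < n_exons - 1:
        off = int(rng.integers(9, len(cds) - 9))
        if all(abs(off - o) >= 15 for o in cut_offsets):
            cut_offsets.append(off)
        attempts += 1
        if attempts > 500:
            raise FixtureSpecError(f"cannot place {n_exons} exons in {gene_id}")
    cut_offsets.sort()

    pieces: list[str] = []
    intron_seqs: list[str] = []
    prev = 0
    for off in cut_offsets:
        pieces.append(cds[prev:off])
        length = int(rng.integers(60, 121))
        inner = "".join(
            _BASES[i] for i in rng.integers(0, 4, size=length - 4)
        )
        intron_seqs.append("GT" + inner + "AG")
        prev = off
    pieces.append(cds[prev:])

    # transcript-orientation locus with introns interleaved
    locus_parts: list[str] = []
    piece_spans: list[tuple[int, int]] = []  # 1-based within locus (tx orientation)
    intron_spans: list[tuple[int, int]] = []
    cursor = 1
    for i, piece in enumerate(pieces):
        locus_parts.append(piece)
        piece_spans.append((cursor, cursor + len(piece) - 1))
        cursor += len(piece)
        if i < len(intron_seqs):
            locus_parts.append(intron_seqs[i])
            intron_spans.append((cursor, cursor + len(intron_seqs[i]) - 1))
            cursor += len(intron_seqs[i])
    locus_tx = "".join(locus_parts)
    locus_len = len(locus_tx)

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        """Map a transcript-orientation locus interval to genomic coords."""
        if strand == "+":
            return start + a - 1, start + b - 1
        return start + locus_len - b, start + locus_len - a

    cds_segments = sorted(to_genomic(a, b) for a, b in piece_spans)
    introns: list[_Intron] = []
    for a, b in intron_spans:
        gs, ge = to_genomic(a, b)
        if strand == "+":
            donor, acceptor = (gs, gs + 1), (ge - 1, ge)
        else:
            donor, acceptor = (ge, ge - 1), (gs + 1, gs)
        introns.append(_Intron(gs, ge, donor, acceptor))

    # transcript CDS offset -> genomic position
    gmap: list[int] = []
    segs = cds_segments if strand == "+" else list(reversed(cds_segments))
    for s, e in segs:
        rng_iter = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
        gmap.extend(rng_iter)

    design = _GeneDesign(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        start=start,
        end=start + locus_len - 1,
        cds=cds,
        cds_segments=cds_segments,
        gmap=gmap,
        introns=introns,
        n_codons=n_codons,
    )
    # stash the genomic locus sequence for pasting into the chromosome
    design.locus_genomic = locus_tx if strand == "+" else locus_tx.translate(_COMPLEMENT)[::-1]  # type: ignore[attr-defined]
    return design


# ---------------------------------------------------------------------------
# Variant planting


@dataclass
class _PlantedSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[_GeneDesign]
    effect_class: str
    effect_term: str
    aa_notation: str
    severity: str
    genotypes: list[Optional[tuple[int, int]]] = field(default_factory=list)
    masked: list[bool] = field(default_factory=list)


def _genomic_snv(
    chrom_seq: str, g: _GeneDesign, off: int, new_base_tx: str
) -> tuple[int, str, str]:
    gp = g.gmap[off]
    ref = chrom_seq[gp - 1]
    alt = new_base_tx if g.strand == "+" else new_base_tx.translate(_COMPLEMENT)
    return gp, ref, alt


def _genomic_deletion(
    chrom_seq: str, g: _GeneDesign, off: int, length: int
) -> Optional[tuple[int, str, str]]:
    """VCF-style (pos, ref, alt) for deleting transcript offsets [off, off+length-1]."""
    gpositions = [g.gmap[o] for o in range(off, off + length)]
    glo, ghi = min(gpositions), max(gpositions)
    if ghi - glo != length - 1:  # spans an intron
        return None
    anchor = glo - 1
    if anchor < 1:
        return None
    ref = chrom_seq[anchor - 1 : ghi]
    return anchor, ref, ref[0]


def _genomic_insertion(
    chrom_seq: str, g: _GeneDesign, off: int, tx_seq: str
) -> Optional[tuple[int, str, str]]:
    """VCF-style record inserting ``tx_seq`` before transcript offset ``off``."""
    if off == 0:
        return None
    if abs(g.gmap[off] - g.gmap[off - 1]) != 1:  # exon boundary
        return None
    if g.strand == "+":
        anchor = g.gmap[off] - 1
        ins = tx_seq
    else:
        anchor = g.gmap[off]
        ins = tx_seq.translate(_COMPLEMENT)[::-1]
    ref = chrom_seq[anchor - 1]
    return anchor, ref, ref + ins


def _aa_of(codon: str) -> str:
    return _tx_translate(codon + "TAA")[0] if codon not in _STOP_CODONS else "*"


class _Planter:
    """Plants one variant per request, verifying the expected class."""

    def __init__(self, rng: np.random.Generator, chrom_seqs: dict[str, str]):
        self.rng = rng
        self.chrom_seqs = chrom_seqs
        self.used_positions: set[tuple[str, int]] = set()

    def _accept(
        self,
        g: Optional[_GeneDesign],
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        effect_class: str,
        term: str,
        aa: str,
    ) -> _PlantedSite:
        self.used_positions.add((chrom, pos))
        return _PlantedSite(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=g,
            effect_class=effect_class,
            effect_term=term,
            aa_notation=aa,
            severity=_severity_of(effect_class),
        )

    def _pick_codon(self, g: _GeneDesign, length: int, lo: int = 2) -> Optional[int]:
        hi = g.n_codons - 3  # keep clear of the stop codon
        if hi <= lo:
            return None
        k = int(self.rng.integers(lo, hi))
        off = 3 * k
        if not g.is_free(off, length):
            return None
        return k

    def plant(self, effect_class: str, g: Optional[_GeneDesign]) -> Optional[_PlantedSite]:
        if effect_class == "intergenic":
            raise ValueError("intergenic planting handled separately")
        assert g is not None
        chrom_seq = self.chrom_seqs[g.chrom]

        if effect_class in ("splice_donor_variant", "splice_acceptor_variant"):
            for intron in g.introns:
                window, used = (
                    (intron.donor, intron.donor_used)
                    if effect_class == "splice_donor_variant"
                    else (intron.acceptor, intron.acceptor_used)
                )
                if used:
                    continue
                gp = window[0]  # first base in transcript order
                if (g.chrom, gp) in self.used_positions:
                    continue
                ref = chrom_seq[gp - 1]
                alt = _BASES[(self.rng.integers(1, 4) + _BASES.index(ref)) % 4]
                if effect_class == "splice_donor_variant":
                    intron.donor_used = True
                else:
                    intron.acceptor_used = True
                return self._accept(g, g.chrom, gp, ref, alt, effect_class, effect_class, "")
            return None

        if effect_class == "start_lost":
            if g.start_used:
                return None
            j = int(self.rng.integers(0, 3))
            old = g.cds[j]
            new = _BASES[(self.rng.integers(1, 4) + _BASES.index(old)) % 4]
            term, aa = _expected_change(g.cds, j, 1, new)
            if term != "start_lost":
                return None
            gp, ref, alt = _genomic_snv(chrom_seq, g, j, new)
            if (g.chrom, gp) in self.used_positions:
                return None
            g.start_used = True
            g.reserve(0, 3)
            return self._accept(g, g.chrom, gp, ref, alt, effect_class, term, aa)

        if effect_class == "stop_lost":
            if g.stop_used:
                return None
            off = 3 * (g.n_codons - 1)
            codon = g.codon(g.n_codons - 1)
            options = [
                (j, b)
                for j in range(3)
                for b in _BASES
                if b != codon[j] and codon[:j] + b + codon[j + 1 :] not in _STOP_CODONS
            ]
            if not options:
                return None
            j, b = options[int(self.rng.integers(0, len(options)))]
            term, aa = _expected_change(g.cds, off + j, 1, b)
            if term != "stop_lost":
                return None
            gp, ref, alt = _genomic_snv(chrom_seq, g, off + j, b)
            if (g.chrom, gp) in self.used_positions:
                return None
            g.stop_used = True
            g.reserve(off, 3)
            return self._accept(g, g.chrom, gp, ref, alt, effect_class, term, aa)

        if effect_class in ("missense_variant", "synonymous_variant", "stop_gained"):
            k = self._pick_codon(g, 3)
            if k is None:
                return None
            codon = g.codon(k)
            options = []
            for j in range(3):
                for b in _BASES:
                    if b == codon[j]:
                        continue
                    new_codon = codon[:j] + b + codon[j + 1 :]
                    if effect_class == "stop_gained" and new_codon in _STOP_CODONS:
                        options.append((j, b))
                    elif effect_class == "synonymous_variant" and (
                        new_codon not in _STOP_CODONS
                        and _aa_of(new_codon) == _aa_of(codon)
                    ):
                        options.append((j, b))
                    elif effect_class == "missense_variant" and (
                        new_codon not in _STOP_CODONS
                        and _aa_of(new_codon) != _aa_of(codon)
                    ):
                        options.append((j, b))
            if not options:
                return None
            j, b = options[int(self.rng.integers(0, len(options)))]
            off = 3 * k + j
            term, aa = _expected_change(g.cds, off, 1, b)
            if term != effect_class:
                return None
            gp, ref, alt = _genomic_snv(chrom_seq, g, off, b)
            if (g.chrom, gp) in self.used_positions:
                return None
            g.reserve(3 * k, 3)
            return self._accept(g, g.chrom, gp, ref, alt, effect_class, term, aa)

        if effect_class == "frameshift_variant":
            k = self._pick_codon(g, 1)
            if k is None:
                return None
            off = 3 * k
            term, aa = _expected_change(g.cds, off, 1, "")
            if term != "frameshift_variant":
                return None
            edit = _genomic_deletion(chrom_seq, g, off, 1)
            if edit is None:
                return None
            pos, ref, alt = edit
            if (g.chrom, pos) in self.used_positions:
                return None
            g.reserve(off, 1)
            return self._accept(g, g.chrom, pos, ref, alt, effect_class, term, aa)

        if effect_class.endswith("inframe_deletion"):
            conservative = effect_class.startswith("conservative")
            k = self._pick_codon(g, 4)
            if k is None:
                return None
            off = 3 * k if conservative else 3 * k + 1
            # keep the minimal edit anchored: the base following the deleted
            # block must differ from its first base, or normalization slides
            if g.cds[off] == g.cds[off + 3]:
                return None
            term, aa = _expected_change(g.cds, off, 3, "")
            if term != effect_class:
                return None
            edit = _genomic_deletion(chrom_seq, g, off, 3)
            if edit is None:
                return None
            pos, ref, alt = edit
            if (g.chrom, pos) in self.used_positions:
                return None
            g.reserve(off, 3)
            return self._accept(g, g.chrom, pos, ref, alt, effect_class, term, aa)

        if effect_class.endswith("inframe_insertion"):
            conservative = effect_class.startswith("conservative")
            k = self._pick_codon(g, 1)
            if k is None:
                return None
            off = 3 * k if conservative else 3 * k + 1
            ins = _SENSE_CODONS[int(self.rng.integers(0, len(_SENSE_CODONS)))]
            if ins[0] == g.cds[off]:
                return None
            term, aa = _expected_change(g.cds, off, 0, ins)
            if term != effect_class:
                return None
            edit = _genomic_insertion(chrom_seq, g, off, ins)
            if edit is None:
                return None
            pos, ref, alt = edit
            if (g.chrom, pos) in self.used_positions:
                return None
            g.reserve(off, 1)
            return self._accept(g, g.chrom, pos, ref, alt, effect_class, term, aa)

        raise ValueError(f"unplantable effect class {effect_class!r}")


# ---------------------------------------------------------------------------
# Fixture generation


def _majority_winner(counts: dict[tuple[int, int], int]) -> tuple[int, int]:
    """Most frequent genotype; ties ref-ward then lowest indices (the same
    rule the imputer states, re-derived here for plant-time guarantees)."""
    return min(counts, key=lambda gt: (-counts[gt], -sum(a == 0 for a in gt), gt))


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[dict[str, Path], TruthManifest]:
    """Generate a panel and its ground truth; same seed, same bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    chroms = [f"Chr{i + 1}" for i in range(spec.n_chromosomes)]
    backgrounds = {
        c: "".join(_BASES[i] for i in rng.integers(0, 4, size=spec.chromosome_length))
        for c in chroms
    }

    # --- genes
    designs: list[_GeneDesign] = []
    cursors = {c: 1 for c in chroms}
    for gi in range(spec.n_genes):
        chrom = chroms[gi % len(chroms)]
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = (gi % 3) + 1
        n_codons = int(rng.integers(spec.min_codons, spec.max_codons + 1))
        gap = int(rng.integers(150, 301))
        start = cursors[chrom] + gap
        design = _design_gene(
            rng, f"g{gi + 1:03d}", chrom, strand, start, n_codons, n_exons
        )
        if design.end + 50 > spec.chromosome_length:
            raise FixtureSpecError(
                f"gene {design.gene_id} does not fit: chromosome_length too small"
            )
        cursors[chrom] = design.end
        designs.append(design)

    chrom_seqs = {}
    for c in chroms:
        arr = list(backgrounds[c])
        for d in designs:
            if d.chrom == c:
                arr[d.start - 1 : d.end] = list(d.locus_genomic)  # type: ignore[attr-defined]
        chrom_seqs[c] = "".join(arr)

    # --- plant variants
    planter = _Planter(rng, chrom_seqs)
    sites: list[_PlantedSite] = []
    for effect_class in PLANTABLE_CLASSES:
        count = spec.variant_plan.get(effect_class, 0)
        for n in range(count):
            if effect_class == "intergenic":
                planted = None
                for _ in range(200):
                    chrom = chroms[int(rng.integers(0, len(chroms)))]
                    pos = int(rng.integers(20, spec.chromosome_length - 20))
                    inside = any(
                        d.chrom == chrom and d.start - 5 <= pos <= d.end + 5
                        for d in designs
                    )
                    if inside or (chrom, pos) in planter.used_positions:
                        continue
                    ref = chrom_seqs[chrom][pos - 1]
                    alt = _BASES[(int(rng.integers(1, 4)) + _BASES.index(ref)) % 4]
                    planter.used_positions.add((chrom, pos))
                    planted = _PlantedSite(
                        chrom, pos, ref, alt, None, "intergenic",
                        "non_coding_or_other", "", "non_modifying",
                    )
                    break
            else:
                eligible = [
                    d for d in designs
                    if d.introns or not effect_class.startswith("splice")
                ]
                if not eligible:
                    raise FixtureSpecError(
                        f"no eligible gene for {effect_class} (need multi-exon genes)"
                    )
                planted = None
                for attempt in range(300):
                    g = eligible[(n + attempt) % len(eligible)]
                    planted = planter.plant(effect_class, g)
                    if planted is not None:
                        break
            if planted is None:
                raise FixtureSpecError(
                    f"could not plant {effect_class} #{n + 1}; "
                    "increase gene count or codon range"
                )
            sites.append(planted)

    sites.sort(key=lambda s: (s.chrom, s.pos))

    # --- genotypes: inbred panel, homozygous calls only
    accessions = [f"ACC{i + 1:03d}" for i in range(spec.n_accessions)]
    n_acc = spec.n_accessions
    for site in sites:
        max_carriers = max(2, n_acc // 3 + 1)
        n_carriers = int(rng.integers(1, max_carriers))
        carrier_idx = set(
            int(i) for i in rng.choice(n_acc, size=n_carriers, replace=False)
        )
        site.genotypes = [
            (1, 1) if i in carrier_idx else (0, 0) for i in range(n_acc)
        ]
        site.masked = [False] * n_acc

    # --- inject missing calls only where majority fill provably restores them
    target = round(spec.missing_rate * n_acc * len(sites))
    cell_order = rng.permutation(n_acc * len(sites))
    masked_cells: list[tuple[str, str, int]] = []
    for flat in cell_order:
        if len(masked_cells) >= target:
            break
        si, ai = divmod(int(flat), n_acc)
        site = sites[si]
        visible = [
            gt
            for i, gt in enumerate(site.genotypes)
            if not site.masked[i] and i != ai
        ]
        if not visible:
            continue
        counts: dict[tuple[int, int], int] = {}
        for gt in visible:
            counts[gt] = counts.get(gt, 0) + 1
        if _majority_winner(counts) == site.genotypes[ai]:
            site.masked[ai] = True
            masked_cells.append((accessions[ai], site.chrom, site.pos))
    masked_cells.sort()

    # --- metadata
    values = list(spec.category_proportions)
    perm = [int(i) for i in rng.permutation(n_acc)]
    assignment: dict[str, tuple[str, str]] = {}  # acc -> (status, cultivar)
    idx = 0
    for value in values:
        n_val = round(spec.category_proportions[value] * n_acc)
        for i in perm[idx : idx + n_val]:
            assignment[accessions[i]] = (value, "No")
        idx += n_val
    elite = [a for a, (v, _) in assignment.items() if v == "Elite"]
    elite.sort()
    n_cult = round(spec.cultivar_fraction * len(elite))
    for a in elite[:n_cult]:
        assignment[a] = ("Elite", "Yes")
    maturity_pool = ["0", "I", "II", "III", "IV"]
    country_pool = ["China", "USA", "Japan", "Korea", "Brazil"]
    state_pool = {"USA": ["MO", "IL", "IA"]}
    details: dict[str, tuple[str, str, str]] = {}
    for acc in accessions:
        mg = maturity_pool[int(rng.integers(0, len(maturity_pool)))]
        country = country_pool[int(rng.integers(0, len(country_pool)))]
        state = (
            state_pool[country][int(rng.integers(0, len(state_pool[country])))]
            if country in state_pool
            else ""
        )
        details[acc] = (mg, country, state)

    category_spec = CategorySpec(
        category_column="Improvement Status",
        values=tuple(values),
        flag_columns={"Cultivar": ("Yes",)},
        detail_columns=("Maturity Group", "Country", "State"),
    )

    # --- per-gene truth
    gene_truth: dict[str, GeneTruth] = {}
    for d in designs:
        gene_sites = [
            s
            for s in sites
            if s.gene is d and s.severity != "non_modifying"
        ]
        gene_sites.sort(key=lambda s: (s.chrom, s.pos))
        labels = [f"{s.chrom}:{s.pos}" for s in gene_sites]
        groups: dict[tuple[str, ...], list[str]] = {}
        for i, acc in enumerate(accessions):
            vec = tuple(
                s.alt if s.genotypes[i] == (1, 1) else s.ref for s in gene_sites
            )
            groups.setdefault(vec, []).append(acc)
        partition = sorted(
            (AlleleTruth(vec, tuple(carriers)) for vec, carriers in groups.items()),
            key=lambda at: (-at.total, at.state_vector),
        )
        freq_rows = []
        for at in partition:
            counts = {v: 0 for v in values}
            cultivar = 0
            for acc in at.carriers:
                if acc in assignment:
                    status, cult = assignment[acc]
                    counts[status] += 1
                    if cult == "Yes":
                        cultivar += 1
            freq_rows.append({**counts, "Cultivar": cultivar, "Total": at.total})
        imputation = {}
        for i, acc in enumerate(accessions):
            imputation[acc] = (
                "+" if any(s.masked[i] for s in gene_sites) else "-"
            )
        gene_truth[d.gene_id] = GeneTruth(
            position_labels=labels,
            partition=partition,
            frequency_rows=freq_rows,
            imputation=imputation,
        )

    # --- summary truth
    import statistics as _stats

    genic = [s for s in sites if s.gene is not None and s.severity != "non_modifying"]
    pos_counts = [
        len(gt.position_labels)
        for gt in gene_truth.values()
        if gt.position_labels
    ]
    allele_counts = [
        len(gt.partition) for gt in gene_truth.values() if gt.position_labels
    ]
    null_genes = {s.gene.gene_id for s in genic if s.severity == "null"}
    summary = {
        "n_genes": spec.n_genes,
        "n_genes_reference_only": spec.n_genes - len(pos_counts),
        "n_genes_with_null_alleles": len(null_genes),
        "n_modifying_variants": len(genic),
        "n_null_variants": sum(1 for s in genic if s.severity == "null"),
        "mean_positions_per_gene": float(_stats.mean(pos_counts)) if pos_counts else 0.0,
        "median_positions_per_gene": float(_stats.median(pos_counts)) if pos_counts else 0.0,
        "mean_alleles_per_gene": float(_stats.mean(allele_counts)) if allele_counts else 0.0,
        "median_alleles_per_gene": float(_stats.median(allele_counts)) if allele_counts else 0.0,
        "mean_missing_per_accession": len(masked_cells) / n_acc,
    }

    # --- write files
    paths = {
        "fasta": out / "genome.fa",
        "gff": out / "genes.gff3",
        "vcf": out / "panel.vcf",
        "metadata": out / "metadata.tsv",
        "category_spec": out / "categories.json",
        "truth": out / "truth.json",
        "config": out / "config.json",
    }

    with open(paths["fasta"], "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = chrom_seqs[c]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for d in designs:
            col9 = f"ID={d.gene_id}"
            fh.write(
                f"{d.chrom}\tsynthetic\tgene\t{d.start}\t{d.end}\t.\t{d.strand}\t.\t{col9}\n"
            )
            fh.write(
                f"{d.chrom}\tsynthetic\tmRNA\t{d.start}\t{d.end}\t.\t{d.strand}\t.\t"
                f"ID={d.transcript_id};Parent={d.gene_id}\n"
            )
            # phases follow transcription order
            ordered = (
                d.cds_segments if d.strand == "+" else list(reversed(d.cds_segments))
            )
            phases = {}
            cum = 0
            for s, e in ordered:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s + 1
            for i, (s, e) in enumerate(d.cds_segments, 1):
                fh.write(
                    f"{d.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t{d.strand}\t.\t"
                    f"ID={d.transcript_id}.exon{i};Parent={d.transcript_id}\n"
                )
            for i, (s, e) in enumerate(d.cds_segments, 1):
                fh.write(
                    f"{d.chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t{d.strand}\t{phases[(s, e)]}\t"
                    f"ID={d.transcript_id}.cds{i};Parent={d.transcript_id}\n"
                )

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={spec.chromosome_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(accessions)
            + "\n"
        )
        for site in sites:
            calls = []
            for i in range(n_acc):
                if site.masked[i]:
                    calls.append("./.")
                else:
                    a, b = site.genotypes[i]
                    calls.append(f"{a}/{b}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )

    with open(paths["metadata"], "w") as fh:
        fh.write("Accession\tImprovement Status\tCultivar\tMaturity Group\tCountry\tState\n")
        for acc in accessions:
            if acc not in assignment:
                continue  # uncategorized accessions stay out of the table
            status, cult = assignment[acc]
            mg, country, state = details[acc]
            fh.write(f"{acc}\t{status}\t{cult}\t{mg}\t{country}\t{state}\n")

    category_spec.to_json(paths["category_spec"])

    manifest = TruthManifest(
        seed=spec.seed,
        accessions=accessions,
        planted=[
            PlantedVariant(
                s.chrom, s.pos, s.ref, s.alt,
                s.gene.gene_id if s.gene else None,
                s.effect_term, s.aa_notation, s.severity,
            )
            for s in sites
        ],
        gene_truth=gene_truth,
        masked_cells=masked_cells,
        summary=summary,
    )
    manifest.to_json(paths["truth"])

    config = {
        "fasta": str(paths["fasta"]),
        "gff": str(paths["gff"]),
        "vcf": str(paths["vcf"]),
        "metadata": str(paths["metadata"]),
        "category_spec": str(paths["category_spec"]),
        "out_dir": str(out / "results"),
    }
    with open(paths["config"], "w") as fh:
        json.dump(config, fh, indent=2)
        fh.write("\n")

    return paths, manifest


# ---------------------------------------------------------------------------
# Verification


def verify_against_truth(catalog: AlleleCatalog, manifest: TruthManifest) -> list[str]:
    """Compare pipeline outputs against the manifest; empty list = pass."""
    report: list[str] = []

    # effect calls
    for pv in manifest.planted:
        if pv.gene_id is None or pv.severity == "non_modifying":
            for gid, gs in catalog.gene_sets.items():
                for p in gs.positions:
                    if p.chrom == pv.chrom and p.pos == pv.pos:
                        report.append(
                            f"non-modifying variant {pv.chrom}:{pv.pos} appears in gene {gid}"
                        )
            continue
        gs = catalog.gene_sets.get(pv.gene_id)
        site = None
        if gs is not None:
            site = next(
                (p for p in gs.positions if p.chrom == pv.chrom and p.pos == pv.pos),
                None,
            )
        if site is None:
            report.append(
                f"variant {pv.chrom}:{pv.pos} missing from gene {pv.gene_id} set"
            )
            continue
        try:
            ai = site.record.alt_seqs.index(pv.alt) + 1
        except ValueError:
            report.append(f"variant {pv.chrom}:{pv.pos}: alt {pv.alt} not in record")
            continue
        eff = site.alt_effects.get(ai)
        if eff is None:
            report.append(f"variant {pv.chrom}:{pv.pos}: alt {pv.alt} has no effect call")
            continue
        if eff.effect_term != pv.effect_term:
            report.append(
                f"variant {pv.chrom}:{pv.pos}: effect {eff.effect_term} != {pv.effect_term}"
            )
        if eff.aa_notation != pv.aa_notation:
            report.append(
                f"variant {pv.chrom}:{pv.pos}: aa {eff.aa_notation!r} != {pv.aa_notation!r}"
            )
        if eff.severity != pv.severity:
            report.append(
                f"variant {pv.chrom}:{pv.pos}: severity {eff.severity} != {pv.severity}"
            )

    # allele partitions, frequency tables, imputation flags
    for gid, truth in manifest.gene_truth.items():
        alleles = catalog.alleles.get(gid)
        if alleles is None:
            report.append(f"gene {gid}: missing from catalog")
            continue
        gs = catalog.gene_sets[gid]
        if gs.labels != truth.position_labels:
            report.append(
                f"gene {gid}: positions {gs.labels} != {truth.position_labels}"
            )
        if len(alleles) != len(truth.partition):
            report.append(
                f"gene {gid}: {len(alleles)} alleles != expected {len(truth.partition)}"
            )
        for i, (actual, expected) in enumerate(zip(alleles, truth.partition), 1):
            if actual.state_vector != expected.state_vector:
                report.append(
                    f"gene {gid} allele {i}: states {actual.state_vector} != "
                    f"{expected.state_vector}"
                )
            if sorted(actual.carriers) != sorted(expected.carriers):
                report.append(f"gene {gid} allele {i}: carrier sets differ")
            if actual.total != expected.total:
                report.append(
                    f"gene {gid} allele {i}: total {actual.total} != {expected.total}"
                )
        table = catalog.tables.get(gid)
        if table is not None:
            for i, (row, exp) in enumerate(zip(table.rows, truth.frequency_rows), 1):
                actual_counts = {**row.counts, **row.flag_counts, "Total": row.total}
                if actual_counts != exp:
                    report.append(
                        f"gene {gid} frequency row {i}: {actual_counts} != {exp}"
                    )
        actual_imp = catalog.gene_imputation(gid)
        for acc, flag in truth.imputation.items():
            if actual_imp.get(acc) != flag:
                report.append(
                    f"gene {gid} accession {acc}: imputation flag "
                    f"{actual_imp.get(acc)} != {flag}"
                )

    # dataset summary
    actual_summary = catalog.summary.to_dict()
    for key, expected in manifest.summary.items():
        actual = actual_summary.get(key)
        if actual is None or abs(float(actual) - float(expected)) > 1e-9:
            report.append(f"summary {key}: {actual} != {expected}")

    return report
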