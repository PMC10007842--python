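"""Standard-format readers/writers and the tab-delimited allele-catalog dialect.

The pipeline consumes four inputs — a reference genome (FASTA), a gene
annotation (GFF3), a multi-sample diploid VCF and a tab-delimited accession
meta-information table — and emits allele-catalog tables in a small
tab-delimited dialect that round-trips byte-identically.

Coordinates are 1-based inclusive everywhere, matching both VCF and GFF3.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ConfigError",
    "GenomeSequence",
    "Transcript",
    "GeneModel",
    "VariantRecord",
    "SampleMetadata",
    "CategorySpec",
    "CatalogCell",
    "CatalogRow",
    "read_fasta",
    "read_gff",
    "read_vcf",
    "filter_symbolic_alts",
    "read_metadata",
    "write_allele_catalog",
    "read_allele_catalog",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ConfigError(ValueError):
    """Raised when a configuration (category spec, run config) is invalid."""


_ALPHABET = set("ACGTN")
_SYMBOLIC_ALT = re.compile(r"^<.*>$")

#: Diploid genotype as a pair of allele indices (0 = REF), or None if missing.
Genotype = Optional[tuple[int, int]]


@dataclass(frozen=True)
class GenomeSequence:
    """Reference genome: chromosome name -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``chrom`` from ``start`` to ``end`` (1-based, inclusive)."""
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise ValueError(
                f"coordinates {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
            )
        return seq[start - 1 : end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class Transcript:
    """One transcript: exon and CDS segments as 1-based inclusive intervals.

    CDS segments carry their phase (0/1/2) and are stored in ascending
    genomic order regardless of strand.
    """

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int, int], ...]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        return tuple((s, e) for s, e, _ in self.cds)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its transcripts; the coordinate frame for effect calls."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")
        for tx in self.transcripts:
            for s, e in tx.exons + tx.cds_intervals:
                if s < self.start or e > self.end or s > e:
                    raise FormatError(
                        f"gene {self.gene_id}: segment {s}-{e} outside gene span"
                    )
            ivs = sorted(tx.cds_intervals)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise FormatError(
                        f"gene {self.gene_id}: overlapping CDS segments in {tx.transcript_id}"
                    )

    def transcript(self, transcript_id: str) -> Transcript:
        for tx in self.transcripts:
            if tx.transcript_id == transcript_id:
                return tx
        raise KeyError(transcript_id)


@dataclass
class VariantRecord:
    """One VCF site with per-accession diploid genotypes.

    ``missing_flags`` records which calls were originally missing ("./.")
    before any imputation; imputation fills ``genotypes`` but never clears
    the flags, so provenance survives the whole pipeline.
    """

    chrom: str
    pos: int
    ref_seq: str
    alt_seqs: tuple[str, ...]
    genotypes: list[Genotype]
    missing_flags: list[bool]
    ann: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not self.ref_seq:
            raise FormatError(f"{self.chrom}:{self.pos}: empty REF")
        if not self.alt_seqs:
            raise FormatError(f"{self.chrom}:{self.pos}: empty ALT list")
        if len(self.missing_flags) != len(self.genotypes):
            raise FormatError(f"{self.chrom}:{self.pos}: flag/genotype length mismatch")
        n_alleles = 1 + len(self.alt_seqs)
        for gt in self.genotypes:
            if gt is not None and any(a >= n_alleles or a < 0 for a in gt):
                raise FormatError(
                    f"{self.chrom}:{self.pos}: allele index out of range in {gt}"
                )

    @property
    def end(self) -> int:
        """Last reference base covered by this record (1-based inclusive)."""
        return self.pos + len(self.ref_seq) - 1

    def allele_seq(self, index: int) -> str:
        """Sequence of allele ``index`` (0 = REF, i>=1 = ALT i)."""
        return self.ref_seq if index == 0 else self.alt_seqs[index - 1]

    def has_symbolic_alt(self) -> bool:
        return any(_SYMBOLIC_ALT.fullmatch(a) for a in self.alt_seqs)


@dataclass(frozen=True)
class SampleMetadata:
    """One accession's categorical labels and free-form details."""

    accession: str
    categories: dict[str, str] = field(default_factory=dict)
    details: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class CategorySpec:
    """Panel-specific declaration of which metadata columns mean what.

    ``category_column`` partitions accessions (e.g. Improvement Status with
    values G. soja / Landrace / Elite); ``flag_columns`` are independent
    yes/no-style columns counted separately (e.g. Cultivar); everything in
    ``detail_columns`` is carried through verbatim into catalog rows.
    """

    category_column: Optional[str] = None
    values: tuple[str, ...] = ()
    flag_columns: dict[str, tuple[str, ...]] = field(default_factory=dict)
    detail_columns: tuple[str, ...] = ()

    @property
    def category_columns(self) -> tuple[str, ...]:
        cols = () if self.category_column is None else (self.category_column,)
        return cols + tuple(self.flag_columns)

    @classmethod
    def from_json(cls, path: str | Path) -> "CategorySpec":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            category_column=data.get("category_column"),
            values=tuple(data.get("values", ())),
            flag_columns={k: tuple(v) for k, v in data.get("flag_columns", {}).items()},
            detail_columns=tuple(data.get("detail_columns", ())),
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "category_column": self.category_column,
            "values": list(self.values),
            "flag_columns": {k: list(v) for k, v in self.flag_columns.items()},
            "detail_columns": list(self.detail_columns),
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence` (uppercased)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA-formatted")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-ACGTN characters {sorted(bad)}"
            )
        sequences[rec.id] = seq
    return GenomeSequence(sequences)


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features from a GFF3 file into gene models.

    Transcripts are attached to their parent genes via Parent attributes;
    CDS segments are stored in ascending genomic order with their phase.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    def _parent_id(feature) -> str:
        parents = feature.attributes.get("Parent", [])
        if not parents:
            raise FormatError(f"{path}: {feature.featuretype} {feature.id} has no Parent")
        return parents[0]

    mrna_parent: dict[str, str] = {}
    for mrna in db.features_of_type("mRNA"):
        pid = _parent_id(mrna)
        try:
            parent = db[pid]
        except gffutils.FeatureNotFoundError:
            raise FormatError(f"{path}: mRNA {mrna.id} has unknown Parent {pid!r}")
        if parent.featuretype != "gene":
            raise FormatError(f"{path}: mRNA {mrna.id} Parent {pid!r} is not a gene")
        mrna_parent[mrna.id] = pid

    for feat_type in ("CDS", "exon"):
        for feat in db.features_of_type(feat_type):
            pid = _parent_id(feat)
            if pid not in mrna_parent:
                raise FormatError(
                    f"{path}: {feat_type} at {feat.seqid}:{feat.start} has no parent mRNA {pid!r}"
                )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = tuple(
                sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
            )
            cds = tuple(
                sorted(
                    (f.start, f.end, int(f.frame) if f.frame not in (None, ".") else 0)
                    for f in db.children(mrna, featuretype="CDS")
                )
            )
            transcripts.append(Transcript(mrna.id, exons, cds))
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                transcripts=tuple(transcripts),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Read a multi-sample diploid VCF (text or bgzip).

    Returns the accession list in VCF column order plus one
    :class:`VariantRecord` per site.  "./." and ".|." become missing
    genotypes with ``missing_flags`` set; phased and unphased separators are
    both accepted.  SnpEff-style ANN INFO strings, when present, are carried
    along for the alternative annotation path.
    """
    vf = pysam.VariantFile(str(path))
    accessions = list(vf.header.samples)
    has_ann = "ANN" in vf.header.info
    records: list[VariantRecord] = []
    for rec in vf:
        if "GT" not in rec.format:
            raise FormatError(f"{path}: {rec.chrom}:{rec.pos} has no GT field")
        if rec.alts is None:
            raise FormatError(f"{path}: {rec.chrom}:{rec.pos} has no ALT allele")
        genotypes: list[Genotype] = []
        flags: list[bool] = []
        for acc in accessions:
            gt = rec.samples[acc]["GT"]
            if gt is None or all(a is None for a in gt):
                genotypes.append(None)
                flags.append(True)
                continue
            if len(gt) != 2 or any(a is None for a in gt):
                raise FormatError(
                    f"{path}: {rec.chrom}:{rec.pos} sample {acc}: non-diploid call {gt}"
                )
            genotypes.append((int(gt[0]), int(gt[1])))
            flags.append(False)
        ann = rec.info.get("ANN") if has_ann else None
        if isinstance(ann, str):
            ann = (ann,)
        records.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_seq=rec.ref,
                alt_seqs=tuple(rec.alts),
                genotypes=genotypes,
                missing_flags=flags,
                ann=tuple(ann) if ann is not None else None,
            )
        )
    return accessions, records


def filter_symbolic_alts(
    records: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], int]:
    """Drop records whose ALT list contains a symbolic token like ``<DEL>``.

    The whole record is removed even when one ALT is concrete; kept records
    are returned unchanged, along with the dropped count.
    """
    kept: list[VariantRecord] = []
    dropped = 0
    for rec in records:
        if rec.has_symbolic_alt():
            dropped += 1
        else:
            kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# Metadata


def read_metadata(
    path: str | Path, category_spec: Optional[CategorySpec] = None
) -> list[SampleMetadata]:
    """Read the tab-delimited accession meta-information table.

    The first column is the accession identifier.  Columns declared in the
    category spec are parsed into ``categories``; all remaining columns
    become ``details``.  Accessions present in the VCF but absent here are
    permitted and treated as uncategorized downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no columns")
    spec = category_spec or CategorySpec()
    for col in spec.category_columns:
        if col not in df.columns[1:]:
            raise ConfigError(f"{path}: declared category column {col!r} not in header")
    acc_col = df.columns[0]
    category_cols = [c for c in df.columns[1:] if c in spec.category_columns]
    detail_cols = [c for c in df.columns[1:] if c not in spec.category_columns]
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        acc = row[acc_col]
        if acc in seen:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        out.append(
            SampleMetadata(
                accession=acc,
                categories={c: row[c] for c in category_cols},
                details={c: row[c] for c in detail_cols},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Allele-catalog dialect
#
# One file per gene.  Header: Accession, <detail columns>, Gene, Imputation,
# then one column per variant position labeled "Chrom:Pos".  Cell grammar:
#   STATE ( "|" EFFECT_TERM "|" AA_NOTATION )? ( "|+" )?
# where STATE is the genotype rendering (single sequence when homozygous,
# "A/G"-style when heterozygous), the effect part is present for alternate
# states, and the trailing "|+" marks an originally-missing, imputed call.
# The per-gene Imputation column is "+" when any cell of the row is imputed,
# "-" otherwise.  Missing metadata renders as the empty string.


@dataclass(frozen=True)
class CatalogCell:
    """One genotype cell of a catalog row."""

    label: str
    state: str
    effect_term: str = ""
    aa_notation: str = ""
    imputed: bool = False

    def render(self) -> str:
        parts = [self.state]
        if self.effect_term:
            parts += [self.effect_term, self.aa_notation]
        if self.imputed:
            parts.append("+")
        return "|".join(parts)

    @classmethod
    def parse(cls, label: str, text: str) -> "CatalogCell":
        parts = text.split("|")
        imputed = False
        if len(parts) > 1 and parts[-1] == "+":
            imputed = True
            parts = parts[:-1]
        if len(parts) == 1:
            return cls(label, parts[0], imputed=imputed)
        if len(parts) == 3:
            return cls(label, parts[0], parts[1], parts[2], imputed)
        raise FormatError(f"malformed catalog cell {text!r}")


@dataclass(frozen=True)
class CatalogRow:
    """One (accession, gene) row of the allele catalog."""

    accession: str
    details: tuple[tuple[str, str], ...]
    gene_id: str
    cells: tuple[CatalogCell, ...]
    gene_imputed: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.gene_imputed not in ("+", "-"):
            raise FormatError(f"gene_imputed must be '+' or '-', got {self.gene_imputed!r}")
        expected = "+" if any(c.imputed for c in self.cells) else "-"
        if self.gene_imputed != expected:
            raise FormatError(
                f"row {self.accession}/{self.gene_id}: Imputation column "
                f"{self.gene_imputed!r} does not match OR of cell flags"
            )


def write_allele_catalog(rows: Sequence[CatalogRow], path: str | Path) -> None:
    """Write one gene's catalog rows in the tab-delimited dialect."""
    if not rows:
        raise FormatError("cannot write an empty catalog (no rows)")
    gene_ids = {r.gene_id for r in rows}
    if len(gene_ids) != 1:
        raise FormatError(f"one catalog file holds one gene, got {sorted(gene_ids)}")
    detail_keys = tuple(k for k, _ in rows[0].details)
    labels = tuple(c.label for c in rows[0].cells)
    for row in rows:
        if tuple(k for k, _ in row.details) != detail_keys:
            raise FormatError(f"row {row.accession}: inconsistent detail columns")
        if tuple(c.label for c in row.cells) != labels:
            raise FormatError(f"row {row.accession}: inconsistent position columns")
    with open(path, "w") as fh:
        fh.write("\t".join(("Accession",) + detail_keys + ("Gene", "Imputation") + labels))
        fh.write("\n")
        for row in rows:
            fields = [row.accession]
            fields += [v for _, v in row.details]
            fields += [row.gene_id, row.gene_imputed]
            fields += [c.render() for c in row.cells]
            fh.write("\t".join(fields))
            fh.write("\n")


def read_allele_catalog(path: str | Path) -> list[CatalogRow]:
    """Read a catalog file written by :func:`write_allele_catalog`."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines = lines[:-1]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    try:
        gene_idx = header.index("Gene")
        imp_idx = header.index("Imputation")
    except ValueError:
        raise FormatError(f"{path}: header lacks Gene/Imputation columns")
    if header[0] != "Accession" or imp_idx != gene_idx + 1:
        raise FormatError(f"{path}: malformed header")
    detail_keys = header[1:gene_idx]
    labels = header[imp_idx + 1 :]
    rows: list[CatalogRow] = []
    for lineno, line in enumerate(lines[1:], 2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row ({len(fields)} fields)")
        details = tuple(zip(detail_keys, fields[1:gene_idx]))
        cells = tuple(
            CatalogCell.parse(label, text)
            for label, text in zip(labels, fields[imp_idx + 1 :])
        )
        rows.append(
            CatalogRow(
                accession=fields[0],
                details=details,
                gene_id=fields[gene_idx],
                cells=cells,
                gene_imputed=fields[imp_idx],
            )
        )
    return rows
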