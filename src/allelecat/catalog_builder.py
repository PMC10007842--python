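"""Core allele-catalog computation.

Variant positions whose predicted effect modifies a gene's product are
collated per gene; each accession's genotype states over those positions
form a state vector, and the distinct state vectors are the gene's alleles.
Alleles are counted per metadata category into frequency tables ordered by
Total descending, and the whole panel is condensed into a summary of
dataset-level statistics.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .effect_annotation import (
    AnnotatedVariant,
    EffectCall,
    annotate_panel,
)
from .imputation import gene_imputation_flag, impute_major
from .io_formats import (
    CatalogCell,
    CatalogRow,
    CategorySpec,
    ConfigError,
    GeneModel,
    GenomeSequence,
    SampleMetadata,
    VariantRecord,
    filter_symbolic_alts,
)

__all__ = [
    "GenePosition",
    "GeneVariantSet",
    "Allele",
    "FrequencyRow",
    "FrequencyTable",
    "CatalogSummary",
    "AlleleCatalog",
    "genotype_state",
    "assign_variants_to_genes",
    "assemble_alleles",
    "build_frequency_table",
    "summarize_catalog",
    "build_catalog",
    "catalog_rows",
]


@dataclass
class GenePosition:
    """One catalog column: a variant site with its modifying ALT effects.

    Multi-allelic sites contribute a single position; ``alt_effects`` maps
    each modifying alt index to its effect call, and the genotype state at
    the position distinguishes which alt an accession carries.
    """

    chrom: str
    pos: int
    ref_seq: str
    record: VariantRecord
    alt_effects: dict[int, EffectCall]

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class GeneVariantSet:
    """A gene's modifying variant positions, ascending by position."""

    gene_id: str
    positions: list[GenePosition]

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.positions]


@dataclass
class Allele:
    """One gene-level allele: a unique genotype-state vector plus carriers."""

    gene_id: str
    state_vector: tuple[str, ...]
    effects: tuple[Optional[EffectCall], ...]
    carriers: tuple[str, ...]
    carrier_flags: dict[str, tuple[bool, ...]]

    @property
    def total(self) -> int:
        return len(self.carriers)


@dataclass
class FrequencyRow:
    """One allele's per-category counts; ``counts`` covers the primary
    partition, ``flag_counts`` the independent flag columns."""

    allele_index: int  # 1-based, Total-descending
    state_vector: tuple[str, ...]
    counts: dict[str, int]
    flag_counts: dict[str, int]
    total: int


@dataclass
class FrequencyTable:
    gene_id: str
    columns: tuple[str, ...]
    rows: list[FrequencyRow]

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "columns": list(self.columns),
            "rows": [
                {
                    "allele": r.allele_index,
                    "state_vector": list(r.state_vector),
                    **r.counts,
                    **r.flag_counts,
                    "Total": r.total,
                }
                for r in self.rows
            ],
        }

    def to_tsv(self) -> str:
        lines = ["\t".join(("Allele", "States") + self.columns)]
        for r in self.rows:
            cells = [str(r.allele_index), ",".join(r.state_vector)]
            for col in self.columns:
                if col == "Total":
                    cells.append(str(r.total))
                elif col in r.counts:
                    cells.append(str(r.counts[col]))
                else:
                    cells.append(str(r.flag_counts[col]))
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


@dataclass
class CatalogSummary:
    """Dataset-wide statistics over the processed panel."""

    n_genes: int
    n_genes_reference_only: int
    n_genes_with_null_alleles: int
    n_modifying_variants: int
    n_null_variants: int
    mean_positions_per_gene: float
    median_positions_per_gene: float
    mean_alleles_per_gene: float
    median_alleles_per_gene: float
    mean_missing_per_accession: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def genotype_state(record: VariantRecord, sample_index: int) -> str:
    """Render a filled diploid call as a state string.

    Homozygous calls render as the single allele sequence; heterozygous
    calls sort the two allele indices and join their sequences with "/".
    """
    gt = record.genotypes[sample_index]
    if gt is None:
        raise ValueError(
            f"{record.chrom}:{record.pos}: missing genotype at sample {sample_index}; "
            "impute before assembling alleles"
        )
    a, b = sorted(gt)
    if a == b:
        return record.allele_seq(a)
    return f"{record.allele_seq(a)}/{record.allele_seq(b)}"


def assign_variants_to_genes(
    annotated: Iterable[AnnotatedVariant], genes: Iterable[GeneModel]
) -> dict[str, GeneVariantSet]:
    """Collect, per gene, the (site, alt) pairs with modifying effects.

    A (variant, alt) enters gene G's set iff its effect on G has severity
    other than ``non_modifying``; a variant may appear in several
    overlapping genes.  Positions come out ascending.
    """
    sets: dict[str, GeneVariantSet] = {
        g.gene_id: GeneVariantSet(g.gene_id, []) for g in genes
    }
    for av in annotated:
        per_gene: dict[str, dict[int, EffectCall]] = {}
        for (gene_id, alt_index), eff in av.effects.items():
            if eff.severity == "non_modifying":
                continue
            per_gene.setdefault(gene_id, {})[alt_index] = eff
        for gene_id, alt_effects in per_gene.items():
            sets[gene_id].positions.append(
                GenePosition(
                    chrom=av.record.chrom,
                    pos=av.record.pos,
                    ref_seq=av.record.ref_seq,
                    record=av.record,
                    alt_effects=alt_effects,
                )
            )
    for gs in sets.values():
        gs.positions.sort(key=lambda p: (p.chrom, p.pos))
    return sets


def assemble_alleles(
    gene_set: GeneVariantSet, accessions: Sequence[str]
) -> list[Allele]:
    """Group accessions by identical state vectors over the gene's positions.

    Alleles come out ordered by total descending, ties broken by state
    vector lexicographically; a gene with zero positions yields exactly one
    all-reference allele carrying every accession.
    """
    groups: dict[tuple[str, ...], dict] = {}
    for idx, acc in enumerate(accessions):
        vec = tuple(genotype_state(p.record, idx) for p in gene_set.positions)
        flags = tuple(p.record.missing_flags[idx] for p in gene_set.positions)
        group = groups.setdefault(vec, {"carriers": [], "flags": {}, "rep": idx})
        group["carriers"].append(acc)
        group["flags"][acc] = flags

    alleles: list[Allele] = []
    for vec, group in groups.items():
        rep = group["rep"]
        effects: list[Optional[EffectCall]] = []
        for j, p in enumerate(gene_set.positions):
            if vec[j] == p.ref_seq:
                effects.append(None)
                continue
            gt = p.record.genotypes[rep]
            alt_indices = sorted(a for a in gt if a != 0)
            eff = None
            for ai in alt_indices:
                if ai in p.alt_effects:
                    eff = p.alt_effects[ai]
                    break
            effects.append(eff)
        alleles.append(
            Allele(
                gene_id=gene_set.gene_id,
                state_vector=vec,
                effects=tuple(effects),
                carriers=tuple(group["carriers"]),
                carrier_flags=group["flags"],
            )
        )
    alleles.sort(key=lambda a: (-a.total, a.state_vector))
    return alleles


def build_frequency_table(
    alleles: Sequence[Allele],
    metadata: dict[str, SampleMetadata],
    category_spec: CategorySpec,
) -> FrequencyTable:
    """Count carriers per category value for each allele.

    Uncategorized carriers (absent from the metadata, or carrying a value
    outside the declared ones) count only toward Total; flag columns are
    counted independently of the primary partition.
    """
    spec = category_spec
    if spec.category_column is not None and metadata:
        sample = next(iter(metadata.values()))
        if spec.category_column not in sample.categories:
            raise ConfigError(
                f"category column {spec.category_column!r} not present in metadata"
            )
    columns = spec.values + tuple(spec.flag_columns) + ("Total",)
    rows: list[FrequencyRow] = []
    gene_id = alleles[0].gene_id if alleles else ""
    for rank, allele in enumerate(alleles, 1):
        counts = {v: 0 for v in spec.values}
        flag_counts = {f: 0 for f in spec.flag_columns}
        for acc in allele.carriers:
            md = metadata.get(acc)
            if md is None:
                continue
            if spec.category_column is not None:
                value = md.categories.get(spec.category_column)
                if value in counts:
                    counts[value] += 1
            for flag, accepted in spec.flag_columns.items():
                if md.categories.get(flag) in accepted:
                    flag_counts[flag] += 1
        rows.append(
            FrequencyRow(
                allele_index=rank,
                state_vector=allele.state_vector,
                counts=counts,
                flag_counts=flag_counts,
                total=allele.total,
            )
        )
    return FrequencyTable(gene_id=gene_id, columns=columns, rows=rows)


def summarize_catalog(
    genes: Sequence[GeneModel],
    gene_sets: dict[str, GeneVariantSet],
    alleles_by_gene: dict[str, list[Allele]],
    pre_imputation_records: Sequence[VariantRecord],
    n_accessions: int,
) -> CatalogSummary:
    """Dataset-level statistics.

    A reference-only gene has zero modifying positions; a gene with null
    alleles has at least one position whose effect severity is ``null``.
    Variant counts are over distinct (chrom, pos, alt) pairs; per-gene
    means/medians run over genes with at least one modifying position.
    """
    with_positions = [
        g.gene_id
        for g in genes
        if g.gene_id in gene_sets and gene_sets[g.gene_id].positions
    ]
    n_null_genes = 0
    modifying_pairs: set[tuple[str, int, str]] = set()
    null_pairs: set[tuple[str, int, str]] = set()
    for gid in with_positions:
        has_null = False
        for p in gene_sets[gid].positions:
            for ai, eff in p.alt_effects.items():
                key = (p.chrom, p.pos, p.record.alt_seqs[ai - 1])
                modifying_pairs.add(key)
                if eff.severity == "null":
                    null_pairs.add(key)
                    has_null = True
        if has_null:
            n_null_genes += 1

    pos_counts = [len(gene_sets[gid].positions) for gid in with_positions]
    allele_counts = [len(alleles_by_gene[gid]) for gid in with_positions]
    n_missing = sum(sum(rec.missing_flags) for rec in pre_imputation_records)

    def _mean(xs: list[int]) -> float:
        return float(statistics.mean(xs)) if xs else 0.0

    def _median(xs: list[int]) -> float:
        return float(statistics.median(xs)) if xs else 0.0

    return CatalogSummary(
        n_genes=len(genes),
        n_genes_reference_only=len(genes) - len(with_positions),
        n_genes_with_null_alleles=n_null_genes,
        n_modifying_variants=len(modifying_pairs),
        n_null_variants=len(null_pairs),
        mean_positions_per_gene=_mean(pos_counts),
        median_positions_per_gene=_median(pos_counts),
        mean_alleles_per_gene=_mean(allele_counts),
        median_alleles_per_gene=_median(allele_counts),
        mean_missing_per_accession=n_missing / n_accessions if n_accessions else 0.0,
    )


@dataclass
class AlleleCatalog:
    """The fully processed panel: inputs, per-gene alleles and summaries."""

    accessions: list[str]
    metadata: dict[str, SampleMetadata]
    category_spec: CategorySpec
    genes: dict[str, GeneModel]
    gene_sets: dict[str, GeneVariantSet]
    alleles: dict[str, list[Allele]]
    tables: dict[str, FrequencyTable]
    summary: CatalogSummary
    n_symbolic_dropped: int = 0
    n_imputed_calls: int = 0

    def gene_imputation(self, gene_id: str) -> dict[str, str]:
        """Per-accession "+"/"-" gene imputation flags."""
        out: dict[str, str] = {}
        for allele in self.alleles[gene_id]:
            for acc in allele.carriers:
                out[acc] = gene_imputation_flag(allele.carrier_flags[acc])
        return out


def build_catalog(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    records: Sequence[VariantRecord],
    accessions: Sequence[str],
    metadata: Sequence[SampleMetadata],
    category_spec: CategorySpec,
    drop_symbolic: bool = True,
    impute: bool = True,
    use_ann: bool = False,
) -> AlleleCatalog:
    """Run the full in-memory pipeline: filter, impute, annotate, assemble."""
    working = list(records)
    n_dropped = 0
    if drop_symbolic:
        working, n_dropped = filter_symbolic_alts(working)
    n_filled = 0
    if impute:
        result = impute_major(working)
        working = result.records
        n_filled = result.n_filled
    annotated = annotate_panel(working, genes, genome, use_ann=use_ann)
    gene_sets = assign_variants_to_genes(annotated, genes)
    alleles = {
        gid: assemble_alleles(gs, accessions) for gid, gs in gene_sets.items()
    }
    md = {m.accession: m for m in metadata}
    tables = {
        gid: build_frequency_table(alleles[gid], md, category_spec)
        for gid in gene_sets
    }
    summary = summarize_catalog(genes, gene_sets, alleles, working, len(accessions))
    return AlleleCatalog(
        accessions=list(accessions),
        metadata=md,
        category_spec=category_spec,
        genes={g.gene_id: g for g in genes},
        gene_sets=gene_sets,
        alleles=alleles,
        tables=tables,
        summary=summary,
        n_symbolic_dropped=n_dropped,
        n_imputed_calls=n_filled,
    )


def catalog_rows(
    catalog: AlleleCatalog,
    gene_id: str,
    accessions: Optional[Sequence[str]] = None,
) -> list[CatalogRow]:
    """Catalog rows for one gene, grouped by allele (Total-descending) and
    panel order within each allele; optionally restricted to a subset."""
    gene_set = catalog.gene_sets[gene_id]
    subset = None if accessions is None else set(accessions)
    spec = catalog.category_spec
    rows: list[CatalogRow] = []
    for allele in catalog.alleles[gene_id]:
        for acc in allele.carriers:
            if subset is not None and acc not in subset:
                continue
            md = catalog.metadata.get(acc)
            details = tuple(
                (col, md.details.get(col, "") if md else "")
                for col in spec.detail_columns
            )
            flags = allele.carrier_flags[acc]
            cells = tuple(
                CatalogCell(
                    label=p.label,
                    state=allele.state_vector[j],
                    effect_term=allele.effects[j].effect_term if allele.effects[j] else "",
                    aa_notation=allele.effects[j].aa_notation if allele.effects[j] else "",
                    imputed=flags[j],
                )
                for j, p in enumerate(gene_set.positions)
            )
            rows.append(
                CatalogRow(
                    accession=acc,
                    details=details,
                    gene_id=gene_id,
                    cells=cells,
                    gene_imputed=gene_imputation_flag(flags),
                )
            )
    return rows
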