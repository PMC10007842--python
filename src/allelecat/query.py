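"""Library equivalents of the interactive search modes.

``search_by_gene_ids`` reproduces the per-gene frequency-table view with
optional categorical filtering; ``search_by_accessions_and_gene`` genotypes
a list of accessions for one gene without frequencies; ``accession_detail``
is the modal-popup view listing the carriers behind one frequency cell,
including per-cell ``|+`` imputation marks and the per-gene ``+``/``-``
flag.  Results serialize to JSON or TSV; display colors are emitted as
tokens per cell so any front-end can render them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .catalog_builder import (
    Allele,
    AlleleCatalog,
    FrequencyTable,
    build_frequency_table,
    catalog_rows,
)
from .imputation import gene_imputation_flag
from .io_formats import CatalogCell, CatalogRow, ConfigError

__all__ = [
    "NoResultsError",
    "GeneQueryResult",
    "AccessionDetail",
    "search_by_gene_ids",
    "search_by_accessions_and_gene",
    "accession_detail",
    "gene_results_to_json",
    "gene_results_to_tsv",
    "details_to_json",
    "details_to_tsv",
]


class NoResultsError(LookupError):
    """Raised when none of the requested gene ids exist in the catalog."""

    def __init__(self, unknown: Sequence[str]):
        super().__init__(f"no known gene ids among {list(unknown)}")
        self.unknown = list(unknown)


@dataclass
class GeneQueryResult:
    """One gene's query output: frequency table plus per-allele row groups."""

    gene_id: str
    table: FrequencyTable
    position_labels: tuple[str, ...]
    allele_rows: list[list[CatalogRow]]
    cell_colors: dict[str, tuple[str, ...]]  # accession -> per-cell color tokens


@dataclass
class AccessionDetail:
    """One accession's genotype cells for a gene, with imputation marks."""

    accession: str
    details: tuple[tuple[str, str], ...]
    cells: tuple[CatalogCell, ...]
    gene_imputed: str
    colors: tuple[str, ...]


def _allele_colors(catalog: AlleleCatalog, gene_id: str, allele: Allele) -> tuple[str, ...]:
    """Per-position display colors: reference states render grey, alternate
    states take the effect's color (white when no modifying effect)."""
    gene_set = catalog.gene_sets[gene_id]
    colors = []
    for j, p in enumerate(gene_set.positions):
        if allele.state_vector[j] == p.ref_seq:
            colors.append("grey")
        elif allele.effects[j] is not None:
            colors.append(allele.effects[j].display_color)
        else:
            colors.append("white")
    return tuple(colors)


def _detail_for(
    catalog: AlleleCatalog, gene_id: str, allele: Allele, accession: str
) -> AccessionDetail:
    gene_set = catalog.gene_sets[gene_id]
    md = catalog.metadata.get(accession)
    spec = catalog.category_spec
    details = tuple(
        (col, md.details.get(col, "") if md else "") for col in spec.detail_columns
    )
    flags = allele.carrier_flags[accession]
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
    return AccessionDetail(
        accession=accession,
        details=details,
        cells=cells,
        gene_imputed=gene_imputation_flag(flags),
        colors=_allele_colors(catalog, gene_id, allele),
    )


def _matching_accessions(
    catalog: AlleleCatalog, category_filter: Optional[dict[str, Iterable[str]]]
) -> Optional[set[str]]:
    if not category_filter:
        return None
    spec = catalog.category_spec
    known = set(spec.category_columns)
    allowed = set(catalog.accessions)
    for column, values in category_filter.items():
        if column not in known:
            raise ConfigError(f"unknown category column {column!r} in filter")
        wanted = set(values)
        allowed = {
            acc
            for acc in allowed
            if acc in catalog.metadata
            and catalog.metadata[acc].categories.get(column) in wanted
        }
    return allowed


def _filtered_alleles(alleles: Sequence[Allele], allowed: set[str]) -> list[Allele]:
    out = []
    for allele in alleles:
        carriers = tuple(c for c in allele.carriers if c in allowed)
        if not carriers:
            continue
        out.append(
            replace(
                allele,
                carriers=carriers,
                carrier_flags={c: allele.carrier_flags[c] for c in carriers},
            )
        )
    out.sort(key=lambda a: (-a.total, a.state_vector))
    return out


def search_by_gene_ids(
    catalog: AlleleCatalog,
    gene_ids: Sequence[str],
    category_filter: Optional[dict[str, Iterable[str]]] = None,
) -> tuple[list[GeneQueryResult], list[str]]:
    """Frequency-table query for a list of genes.

    Unknown ids are reported in the returned warnings, not fatal; if every
    id is unknown a :class:`NoResultsError` is raised.  A category filter
    restricts the counted accessions before frequencies are computed.
    """
    if not gene_ids:
        raise ValueError("gene_ids must be non-empty")
    known = [g for g in gene_ids if g in catalog.genes]
    unknown = [g for g in gene_ids if g not in catalog.genes]
    warnings = [f"unknown gene id: {g}" for g in unknown]
    if not known:
        raise NoResultsError(unknown)
    allowed = _matching_accessions(catalog, category_filter)
    results: list[GeneQueryResult] = []
    for gene_id in known:
        alleles = catalog.alleles[gene_id]
        if allowed is not None:
            alleles = _filtered_alleles(alleles, allowed)
        table = build_frequency_table(alleles, catalog.metadata, catalog.category_spec)
        table.gene_id = gene_id
        gene_set = catalog.gene_sets[gene_id]
        allele_rows: list[list[CatalogRow]] = []
        cell_colors: dict[str, tuple[str, ...]] = {}
        for allele in alleles:
            colors = _allele_colors(catalog, gene_id, allele)
            group = []
            for acc in allele.carriers:
                detail = _detail_for(catalog, gene_id, allele, acc)
                group.append(
                    CatalogRow(
                        accession=acc,
                        details=detail.details,
                        gene_id=gene_id,
                        cells=detail.cells,
                        gene_imputed=detail.gene_imputed,
                    )
                )
                cell_colors[acc] = colors
            allele_rows.append(group)
        results.append(
            GeneQueryResult(
                gene_id=gene_id,
                table=table,
                position_labels=tuple(gene_set.labels),
                allele_rows=allele_rows,
                cell_colors=cell_colors,
            )
        )
    return results, warnings


def search_by_accessions_and_gene(
    catalog: AlleleCatalog, accessions: Sequence[str], gene_id: str
) -> tuple[list[AccessionDetail], list[str]]:
    """Genotype a list of accessions for one gene, without frequencies.

    Rows come back in request order for accessions present in the panel;
    unknown accessions are reported in the warnings.  An unknown gene is an
    error.
    """
    if gene_id not in catalog.genes:
        raise KeyError(f"unknown gene id: {gene_id}")
    panel = set(catalog.accessions)
    warnings = [f"accession not in panel: {a}" for a in accessions if a not in panel]
    by_acc: dict[str, Allele] = {}
    for allele in catalog.alleles[gene_id]:
        for acc in allele.carriers:
            by_acc[acc] = allele
    return (
        [
            _detail_for(catalog, gene_id, by_acc[acc], acc)
            for acc in accessions
            if acc in panel
        ],
        warnings,
    )


def accession_detail(
    catalog: AlleleCatalog,
    gene_id: str,
    allele_index: int,
    category_value: str,
) -> list[AccessionDetail]:
    """The modal-popup view: carriers of one allele within one category.

    ``allele_index`` is 1-based top-down in Total-descending order;
    ``category_value`` is a declared category value, a flag column name, or
    "Total" for all carriers.  A zero-count cell yields an empty list.
    """
    if gene_id not in catalog.genes:
        raise KeyError(f"unknown gene id: {gene_id}")
    alleles = catalog.alleles[gene_id]
    if not 1 <= allele_index <= len(alleles):
        raise IndexError(f"allele index {allele_index} out of range 1..{len(alleles)}")
    allele = alleles[allele_index - 1]
    spec = catalog.category_spec

    def _selected(acc: str) -> bool:
        if category_value == "Total":
            return True
        md = catalog.metadata.get(acc)
        if md is None:
            return False
        if category_value in spec.values:
            return md.categories.get(spec.category_column) == category_value
        if category_value in spec.flag_columns:
            return md.categories.get(category_value) in spec.flag_columns[category_value]
        raise ValueError(f"unknown category value {category_value!r}")

    return [
        _detail_for(catalog, gene_id, allele, acc)
        for acc in allele.carriers
        if _selected(acc)
    ]


# ---------------------------------------------------------------------------
# Serialization


def _detail_dict(d: AccessionDetail) -> dict:
    return {
        "accession": d.accession,
        "details": dict(d.details),
        "gene_imputation": d.gene_imputed,
        "cells": [
            {
                "position": c.label,
                "state": c.state,
                "effect": c.effect_term,
                "aa_change": c.aa_notation,
                "imputed": c.imputed,
                "display_color": color,
            }
            for c, color in zip(d.cells, d.colors)
        ],
    }


def gene_results_to_json(results: Sequence[GeneQueryResult], warnings: Sequence[str]) -> str:
    payload = {
        "warnings": list(warnings),
        "genes": [
            {
                "gene_id": r.gene_id,
                "positions": list(r.position_labels),
                "frequency_table": r.table.to_dict(),
                "alleles": [
                    [
                        {
                            "accession": row.accession,
                            "details": dict(row.details),
                            "gene_imputation": row.gene_imputed,
                            "cells": [
                                {
                                    "position": c.label,
                                    "state": c.state,
                                    "effect": c.effect_term,
                                    "aa_change": c.aa_notation,
                                    "imputed": c.imputed,
                                    "display_color": color,
                                }
                                for c, color in zip(row.cells, r.cell_colors[row.accession])
                            ],
                        }
                        for row in group
                    ]
                    for group in r.allele_rows
                ],
            }
            for r in results
        ],
    }
    return json.dumps(payload, indent=2) + "\n"


def gene_results_to_tsv(results: Sequence[GeneQueryResult], warnings: Sequence[str]) -> str:
    blocks = [f"# {w}" for w in warnings]
    for r in results:
        blocks.append(f"# Gene: {r.gene_id}")
        blocks.append(r.table.to_tsv().rstrip("\n"))
    return "\n".join(blocks) + "\n"


def details_to_json(details: Sequence[AccessionDetail], warnings: Sequence[str]) -> str:
    return (
        json.dumps(
            {"warnings": list(warnings), "accessions": [_detail_dict(d) for d in details]},
            indent=2,
        )
        + "\n"
    )


def details_to_tsv(details: Sequence[AccessionDetail], warnings: Sequence[str]) -> str:
    lines = [f"# {w}" for w in warnings]
    if details:
        detail_cols = [k for k, _ in details[0].details]
        labels = [c.label for c in details[0].cells]
        lines.append("\t".join(["Accession"] + detail_cols + ["Imputation"] + labels))
        for d in details:
            lines.append(
                "\t".join(
                    [d.accession]
                    + [v for _, v in d.details]
                    + [d.gene_imputed]
                    + [c.render() for c in d.cells]
                )
            )
    return "\n".join(lines) + "\n"
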