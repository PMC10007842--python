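"""Missing-genotype filling with per-call provenance flags.

Missing diploid calls are filled per site with the most frequent non-missing
genotype (ties broken toward the genotype with more reference alleles, then
lowest allele indices).  Every filled call stays flagged, so catalogs can
render the cell-level ``|+`` mark and the per-gene ``+``/``-`` column.

Externally imputed VCFs (no missing calls left) pass through unchanged; a
sidecar mask of originally-missing cells can restore the provenance flags
for such inputs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .io_formats import VariantRecord

__all__ = [
    "ImputationResult",
    "impute_major",
    "gene_imputation_flag",
    "read_missingness_mask",
    "apply_missingness_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class ImputationResult:
    """Filled records plus the per-site fill genotype and a fill count."""

    records: list[VariantRecord]
    site_fill: list[tuple[int, int]]
    n_filled: int

    @property
    def imputed_flags(self) -> list[list[bool]]:
        return [list(rec.missing_flags) for rec in self.records]


def _fill_genotype(record: VariantRecord) -> tuple[int, int]:
    """Most frequent non-missing genotype; ties broken ref-ward then by
    lowest allele indices; all-missing sites fill homozygous-reference."""
    counts = Counter(
        tuple(sorted(gt)) for gt in record.genotypes if gt is not None
    )
    if not counts:
        logger.warning(
            "site %s:%d has no called genotypes; filling homozygous reference",
            record.chrom,
            record.pos,
        )
        return (0, 0)
    # max count, then most reference alleles, then lexicographically smallest
    return min(counts, key=lambda gt: (-counts[gt], -sum(a == 0 for a in gt), gt))


def impute_major(records: Iterable[VariantRecord]) -> ImputationResult:
    """Fill every missing call with its site's majority genotype.

    Non-missing genotypes are never altered; ``missing_flags`` mark exactly
    the filled cells.  Input records are not mutated.
    """
    filled: list[VariantRecord] = []
    site_fill: list[tuple[int, int]] = []
    n_filled = 0
    for rec in records:
        fill = _fill_genotype(rec)
        genotypes = []
        for gt in rec.genotypes:
            if gt is None:
                genotypes.append(fill)
                n_filled += 1
            else:
                genotypes.append(gt)
        filled.append(replace(rec, genotypes=genotypes, missing_flags=list(rec.missing_flags)))
        site_fill.append(fill)
    return ImputationResult(records=filled, site_fill=site_fill, n_filled=n_filled)


def gene_imputation_flag(cell_flags: Iterable[bool]) -> str:
    """Per-gene imputation column: "+" iff any cell was imputed, else "-"."""
    return "+" if any(cell_flags) else "-"


def read_missingness_mask(path: str | Path) -> set[tuple[str, str, int]]:
    """Read a sidecar mask TSV of (accession, chrom, pos) originally-missing
    cells, used when consuming pre-imputed VCFs."""
    mask: set[tuple[str, str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            mask.add((fields[0], fields[1], int(fields[2])))
    return mask


def apply_missingness_mask(
    records: Sequence[VariantRecord],
    accessions: Sequence[str],
    mask: set[tuple[str, str, int]],
) -> None:
    """Set ``missing_flags`` (in place) for cells named in the sidecar mask.

    Genotypes are left untouched: the mask documents provenance for calls an
    external imputer already filled.
    """
    acc_index = {acc: i for i, acc in enumerate(accessions)}
    for rec in records:
        for acc, chrom, pos in mask:
            if chrom == rec.chrom and pos == rec.pos and acc in acc_index:
                rec.missing_flags[acc_index[acc]] = True
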