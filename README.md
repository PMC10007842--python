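# allelecat

Gene-level allele cataloging for re-sequenced germplasm panels.

Genome-wide association hits are SNP-level; breeders and geneticists
usually need the *gene and allele* level — which combinations of
protein-changing variants exist in a gene, how common each combination is,
and which accessions (wild relatives, landraces, elite lines, released
cultivars) carry it. `allelecat` builds that view from standard inputs: a
multi-sample diploid VCF, a GFF3 gene annotation, a reference FASTA and a
tab-delimited accession meta-information table.

## The model

For each gene *g*, let *P(g)* be the variant positions whose predicted
effect **modifies** the gene product (missense, in-frame indels, stop
gain/loss, start loss, frameshift, splice donor/acceptor core — synonymous
and non-coding changes are excluded). Each accession's genotype states over
*P(g)* form a state vector; accessions with identical vectors share an
**allele** of *g*. Alleles partition the panel, are ordered by carrier
count (Total) descending, and are cross-tabulated against categorical
metadata. Missing genotypes are filled by per-site majority (a documented,
deterministic stand-in for haplotype-based imputation) and every filled
call carries a provenance flag, rendered `|+` per cell and `+`/`-` per
gene.

The pipeline: read → symbolic-ALT filter (`<INS>`/`<DEL>`-style records
dropped) → impute → annotate → assign to genes → assemble alleles →
frequency tables → dataset summary. Same inputs, same bytes out.

## Worked example

Generate a synthetic 20-accession, 6-gene panel (with known ground truth)
and run the pipeline:

```sh
allelecat simulate --seed 0 --out demo
allelecat build --config demo/config.json
cat demo/results/summary.json
```

```json
{
  "n_genes": 6,
  "n_genes_reference_only": 2,
  "n_genes_with_null_alleles": 3,
  "n_modifying_variants": 14,
  "n_null_variants": 7,
  "mean_positions_per_gene": 3.5,
  "median_positions_per_gene": 4.0,
  "mean_alleles_per_gene": 5.75,
  "median_alleles_per_gene": 5.5,
  "mean_missing_per_accession": 0.5
}
```

Two of the six genes carry no modifying variants (reference-only), three
contain at least one predicted null (function-abolishing) variant, and the
panel averages 5.75 alleles per variant-bearing gene with half a missing
call per accession before imputation.

Per-gene outputs land in `demo/results/genes/`. The frequency table for
gene `g001` (five modifying positions):

```
Allele  States          G. soja  Landrace  Elite  Cultivar  Total
1       T,GAAG,CA,G,A   3        6         0      0         10
2       T,GAAG,CA,T,A   1        1         2      1         4
3       T,GAAG,CA,G,T   0        0         2      1         2
...
```

Row 1 is the most frequent allele (10 of 20 accessions); category counts
need not sum to Total because uncategorized accessions count only there.
The companion catalog file lists one row per accession with the cell
dialect `STATE(|EFFECT|AA)?(|+)?`:

```
Accession  ...  Gene  Imputation  Chr1:226  Chr1:249  Chr1:278  Chr1:324                    Chr1:347
ACC017     ...  g001  +           T         GAAG|+    CA        G                           A
ACC008     ...  g001  +           T         GAAG      CA        T|missense_variant|V34L     A|+
ACC009     ...  g001  -           T         GAAG      CA        T|missense_variant|V34L     A
```

ACC008 carries a valine→leucine missense change at residue 34 (`V34L`) and
had its Chr1:347 call imputed (`A|+`), so its gene-level Imputation column
is `+`; ACC009 carries the same allele with no imputed calls.

Query the catalog like the interactive tool:

```sh
allelecat query-genes --config demo/config.json --genes g001 \
    --category-filter "Improvement Status=Elite" --format json
allelecat query-accessions --config demo/config.json \
    --accessions ACC008,ACC009 --gene g001 --format tsv
```

The same operations are available as library calls
(`allelecat.search_by_gene_ids`, `allelecat.search_by_accessions_and_gene`,
`allelecat.accession_detail`).

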