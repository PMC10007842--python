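# Methods

## The allele-catalog model

Given a re-sequenced germplasm panel (a multi-sample diploid VCF), a gene
annotation (GFF3) and a reference genome (FASTA), the pipeline reduces each
gene to a small set of *alleles*: a gene's allele is the unique combination
of reference/alternate genotype states over the gene's *modifying* variant
positions — the positions whose predicted effect changes the gene product.
Accessions carrying identical state vectors share an allele, so the panel is
partitioned per gene, and allele frequencies can be cross-tabulated against
categorical metadata (improvement status, cultivar membership, origin).
This is a gene-level haplotype-class summary, not phased haplotypes: states
are per-site genotype renderings, and for the inbred panels this tool
targets (homozygous at almost every site) the two views coincide.

Stages run in a fixed order: read → symbolic-ALT filter → imputation →
effect annotation → per-gene assignment → allele assembly → frequency
tables → dataset summary. Identical inputs and configuration produce
byte-identical outputs.

## Effect annotation

The annotator re-implements the subset of coding-effect prediction the
catalog needs. Effects are computed against a gene's *primary transcript*
(longest total CDS; ties broken by lexicographically smallest transcript
id), on 1-based inclusive coordinates throughout.

Each VCF ALT is first reduced to a minimal edit (shared prefix, then shared
suffix, stripped), then classified:

1. **Splice core first.** The first and last two bases of each intron
   (donor on the side of the exon transcribed first) are checked before
   anything else; a hit is `splice_donor_variant`/`splice_acceptor_variant`
   with no amino-acid notation. Extended splice regions are out of scope.
2. **CDS overlap.** The edit is applied to the spliced CDS (only in-CDS
   bases are removed; insertions land at their anchor) and both coding
   sequences are translated with the standard table — translation stops at
   the first stop codon (rendered `*`), trailing partial codons are
   ignored, N-containing codons give `X`. From the protein diff and net
   length:
   - first residue no longer Met → `start_lost` (`M1?`);
   - net length ≢ 0 (mod 3) → `frameshift_variant` (`R75fs`-style, at the
     first differing residue);
   - net ≡ 0 but ≠ 0 → in-frame indel; *conservative* iff the replaced CDS
     interval is codon-aligned (`T2del`/`G7ins`), otherwise *disruptive*;
   - equal proteins → `synonymous_variant`;
   - otherwise stop gained (`L4*`), stop lost (`*158ext`) or missense
     (`T27A`) from the first differing residue.

Severity classes drive catalog membership: **null** = {stop gained/lost,
start lost, frameshift, splice donor/acceptor}; **modifying** additionally
includes missense and all in-frame indels; synonymous and everything
non-coding is **non-modifying** and never enters the catalog. Display
colors follow the tool's convention (reference grey, missense blue,
conservative in-frame indel orange, splice green, other null classes red,
everything else white; green takes precedence over red for splice).
Treating stop-loss/start-loss as null is an assumption — the upstream
convention is not documented — and is isolated in one table in
`effect_annotation.py`.

One effect is reported per (variant, alt, gene), on the primary transcript
only; variants are annotated only against genes they overlap. Pre-annotated
VCFs carrying SnpEff-style `ANN` strings can be consumed instead of the
internal annotator (`use_ann_field`); the ANN vocabulary is mapped onto the
internal term set and HGVS.p three-letter notation is converted to the
compact one-letter form.

## Imputation stand-in

The catalog only needs filled genotypes plus provenance, so missing calls
are filled per site with the most frequent non-missing genotype, ties
broken toward more reference alleles and then lowest allele indices;
all-missing sites fill homozygous-reference with a logged warning. This is
deterministic and dependency-free, and deliberately *not* a
haplotype-phasing imputer: on real panels its filled values will differ
from a phasing model's. Every filled cell keeps its flag, rendered `|+` per
cell and aggregated to the per-gene `+`/`-` column. Externally imputed VCFs
pass through unchanged, optionally with a sidecar mask TSV restoring the
originally-missing flags.

## Assembly, tables, summary

Multi-allelic sites contribute one catalog position; the state string at
that position (`A`, `T`, `A/T`, …) distinguishes which alt an accession
carries, so alleles still separate by alt. Heterozygous states sort the two
allele indices and join sequences with `/`; homozygous states render the
single sequence. Alleles are ordered by Total descending, ties broken by
state vector lexicographically (so repeat runs are byte-identical). A gene
with zero modifying positions yields exactly one all-reference allele
carrying the whole panel; "genes with only the reference allele" in the
summary are exactly these genes, which makes the count well-defined (any
included VCF position has at least one alt carrier and would force a second
allele).

Frequency tables count carriers per declared category value; carriers
without metadata (or with undeclared values) count only in Total; flag
columns (e.g. Cultivar) are counted independently of the partition.
Dataset summary statistics count distinct (site, alt) pairs per severity
class, and per-gene means/medians of positions and alleles are computed
over genes with at least one modifying position — the denominator is a
documented choice, as the convention is not fixed upstream.

## Queries

`search_by_gene_ids` reproduces the frequency-table view (optionally
filtered to a category subset, with totals recomputed over the filtered
accessions); `search_by_accessions_and_gene` genotypes a request-ordered
accession list for one gene without frequencies; `accession_detail` is the
modal-popup equivalent, selecting one allele (1-based, Total-descending
index) within one category value or "Total". Outputs are JSON/TSV; display
colors are emitted as tokens per cell.

## Synthetic panels and what they do (not) show

The generator designs genes in transcript space — `ATG`, random sense
codons, `TAA`, split by `GT…AG` introns, embedded forward or
reverse-complemented on toy chromosomes — so every planted edit has a known
protein consequence *by construction*. Defaults: 2 chromosomes, 6 genes
cycling 1/2/3 exons and alternating strands, 40–90 codons per gene, 20
homozygous accessions, an improvement-status split of 20% wild / 40%
landrace / 30% elite (remainder uncategorized, half of elite flagged
Cultivar), one planted variant of every supported effect class (plus spares
for the common ones) and a 3% missing-call rate.

Two safeguards keep truth exact. Planted indels sit in
normalization-stable contexts (the base after a deleted block differs from
its first base; insertions start with a base different from the insertion
point), so the minimal-edit interval — and hence codon alignment — is
unambiguous. And missing calls are only injected into cells whose genotype
the per-site majority provably restores, so the post-imputation partition
equals the designed one.

What passing these fixtures does *not* show: realistic linkage or
population structure, heterozygosity, multi-allelic sites at density,
overlapping genes, UTR-bearing gene models, or agreement with a
haplotype-based imputer on non-majority missing calls. The generator is a
correctness instrument, not a population simulator.

## Verification layers

Three independent paths must agree on every planted variant: the annotator
(codon-table walk over the spliced CDS), the plant-time expectation
(transcript-space apply-and-diff inside the generator), and the test-suite
oracle (chromosome-level mutation with shifted CDS coordinates and
coordinate-arithmetic codon alignment). `verify_against_truth` then checks
the full pipeline — effect calls, allele partitions, frequency tables,
imputation flags, summary — and induced-fault tests confirm it actually
flags corrupted severity tables and dropped flags.

Problem sizes used by the test suite and the acceptance script: a 30-gene
panel with 225 planted variants for the annotator-vs-oracle sweep, and 20–21
independently seeded default panels for recovery, conservation, imputation
and round-trip checks; the whole suite runs in well under a minute.

## Known limitations

- Effects on transcripts other than the primary one are not reported.
- Upstream/promoter, UTR and regulatory effects are out of scope.
- Insertions anchored exactly at an exon's first base are treated as
  intronic; edits spanning an exon/intron boundary are classified by their
  splice-core overlap (checked first) or by their in-CDS bases only.
- The majority-fill imputer ignores linkage entirely.
- Catalog files are one-per-gene; a panel-wide single-file layout would
  need a different header convention.
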