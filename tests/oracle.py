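"""Brute-force effect oracle, independent of the package's codon arithmetic.

The oracle applies a variant to the chromosome sequence itself, shifts the
gene's CDS segment coordinates past the edit, re-extracts the coding
sequence from the mutated genome, translates both proteins with Biopython
and classifies the change from the protein diff plus coordinate arithmetic
(codon alignment is computed by counting CDS bases in transcription order,
not by string normalization against the mutated CDS).
"""

from Bio.Seq import Seq

from allelecat.io_formats import GeneModel, GenomeSequence, VariantRecord


def _translate(seq: str) -> str:
    n = len(seq) // 3 * 3
    protein = str(Seq(seq[:n]).translate())
    stop = protein.find("*")
    return protein[: stop + 1] if stop >= 0 else protein


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _minimal_edit(pos: int, ref: str, alt: str):
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    s = 0
    while s < len(ref) - p and s < len(alt) - p and ref[-1 - s] == alt[-1 - s]:
        s += 1
    return pos + p, pos + len(ref) - 1 - s, alt[p : len(alt) - s]


def _primary_tx(gene: GeneModel):
    coding = [t for t in gene.transcripts if t.cds]
    return min(coding, key=lambda t: (-sum(e - s + 1 for s, e, _ in t.cds), t.transcript_id))


def _cds_offset(ivs, strand: str, gpos: int) -> int:
    """Number of CDS bases transcriptionally strictly before genomic ``gpos``."""
    if strand == "+":
        return sum(max(0, min(e, gpos - 1) - s + 1) for s, e in ivs)
    return sum(max(0, e - max(s, gpos + 1) + 1) for s, e in ivs)


def oracle_effect(
    genome: GenomeSequence, gene: GeneModel, record: VariantRecord, alt_index: int
):
    """Return (effect_term, aa_notation) for one ALT by apply-and-retranslate."""
    chrom = genome.sequences[gene.chrom]
    ref, alt = record.ref_seq, record.alt_seqs[alt_index - 1]
    assert chrom[record.pos - 1 : record.pos - 1 + len(ref)] == ref, "REF mismatch"
    tx = _primary_tx(gene)
    ivs = sorted((s, e) for s, e, _ in tx.cds)
    ds, de, ins = _minimal_edit(record.pos, ref, alt)
    has_del = ds <= de
    if not has_del and not ins:
        return "non_coding_or_other", ""

    # splice cores: first/last 2 bases of each intron, donor on the side of
    # the exon transcribed first
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        a, b = e1 + 1, s2 - 1
        if b - a + 1 < 2:
            continue
        donor, acceptor = ((a, a + 1), (b - 1, b)) if gene.strand == "+" else ((b - 1, b), (a, a + 1))
        for term, (ws, we) in (
            ("splice_donor_variant", donor),
            ("splice_acceptor_variant", acceptor),
        ):
            hit = (ds <= we and de >= ws) if has_del else (ws < ds <= we)
            if hit:
                return term, ""

    touches = any(
        (has_del and ds <= e and de >= s) or (not has_del and s < ds <= e)
        for s, e in ivs
    )
    if not touches:
        return "non_coding_or_other", ""

    # mutate the chromosome and shift downstream CDS coordinates
    mchrom = chrom[: record.pos - 1] + alt + chrom[record.pos - 1 + len(ref) :]
    net = len(alt) - len(ref)
    new_ivs = []
    for s, e in ivs:
        if e < ds:
            new_ivs.append((s, e))
        elif s > de:
            new_ivs.append((s + net, e + net))
        else:  # edit inside the segment
            new_ivs.append((s, e + net))

    def spliced(seq: str, segments) -> str:
        out = "".join(seq[s - 1 : e] for s, e in segments)
        return _revcomp(out) if gene.strand == "-" else out

    p0 = _translate(spliced(chrom, ivs))
    p1 = _translate(spliced(mchrom, new_ivs))
    i = 0
    while i < min(len(p0), len(p1)) and p0[i] == p1[i]:
        i += 1
    ref_aa = p0[i] if i < len(p0) else "*"

    if i == 0 and p0[:1] == "M" and p1[:1] != "M":
        return "start_lost", "M1?"
    cds_net = sum(e - s + 1 for s, e in new_ivs) - sum(e - s + 1 for s, e in ivs)
    if cds_net % 3 != 0:
        return "frameshift_variant", f"{ref_aa}{i + 1}fs"
    if cds_net != 0:
        if has_del:
            first_tx = ds if gene.strand == "+" else de
            off = _cds_offset(ivs, gene.strand, first_tx)
            aligned = off % 3 == 0 and (de - ds + 1) % 3 == 0
        else:
            anchor = ds if gene.strand == "+" else ds - 1
            off = _cds_offset(ivs, gene.strand, anchor)
            aligned = off % 3 == 0
        kind = "insertion" if cds_net > 0 else "deletion"
        term = f"{'conservative' if aligned else 'disruptive'}_inframe_{kind}"
        return term, f"{ref_aa}{i + 1}{'ins' if cds_net > 0 else 'del'}"
    if p0 == p1 or i >= min(len(p0), len(p1)):
        return "synonymous_variant", ""
    if p1[i] == "*":
        return "stop_gained", f"{p0[i]}{i + 1}*"
    if p0[i] == "*":
        return "stop_lost", f"*{i + 1}ext"
    return "missense_variant", f"{p0[i]}{i + 1}{p1[i]}"
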