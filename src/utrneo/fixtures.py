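"""Synthetic reference bundles for end-to-end testing at toy scale.

Emits a self-consistent mini-genome (FASTA), Ensembl-dialect GTF,
VEP-style annotated VCF, canonical proteome FASTA and a machine-readable
truth table. Expected outcomes in the truth table are computed by an
embedded naive oracle (full mutant-sequence rescan plus codon-by-codon
translation through Biopython) that shares no code with the neoORF
engine, so engine defects cannot validate themselves.

The builtin toy carries one plus-strand single-exon transcript (T1), its
minus-strand mirror (T1M) and a spliced two-exon transcript (T2), with a
spiked variant panel covering every mutation class, a deliberately
mislabelled final-codon SNV (to exercise the stop-loss override) and one
non-PASS record. ``make_random_reference`` scales the same construction
to arbitrarily many seeded transcripts and variants.
"""

from __future__ import annotations

import logging
import random
import zlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from utrneo.refmodel import TranscriptModel

logger = logging.getLogger(__name__)

POLYK_LEN = 12  # matches the engine default so truth peptides align

_SENSE_CODONS = sorted(
    {
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - {"TAA", "TAG", "TGA"}
)

_CONSEQUENCE_BY_CLASS = {
    "utr5_variant": "5_prime_UTR_variant",
    "stop_loss": "stop_lost",
    "frameshift": "frameshift_variant",
    "missense": "missense_variant",
    "other": "non_coding_transcript_variant",
}


@dataclass
class FixtureBundle:
    outdir: Path
    genome: Path
    gtf: Path
    vcf: Path
    proteome: Path
    truth: Path
    sample: str


@dataclass
class _Tx:
    """Generator-side transcript description (pre-file-format)."""

    tid: str
    gene: str
    chrom: str
    strand: str
    utr5: str
    cds: str  # includes the stop codon
    utr3: str
    exon_breaks: list[int]  # cdna split points (exclusive of 0 and len)
    pad: int = 10

    @property
    def cdna(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_start(self) -> int:
        return len(self.utr5)

    @property
    def cds_end(self) -> int:
        return len(self.utr5) + len(self.cds)

    def exon_pieces(self) -> list[str]:
        bounds = [0] + sorted(self.exon_breaks) + [len(self.cdna)]
        return [self.cdna[a:b] for a, b in zip(bounds, bounds[1:])]


# ---------------------------------------------------------------------------
# Independent naive oracle
# ---------------------------------------------------------------------------


def oracle_translate(seq: str, polyk: int = POLYK_LEN) -> tuple[str, bool]:
    """Naive translation of ``seq`` to the first stop; poly-K on read-through."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(trimmed).translate())
    if "*" in aa:
        return aa.split("*")[0], True
    return aa + "K" * polyk, False


def oracle_expectations(
    tx: _Tx, start: int, end: int, ref: str, alt: str, hgvs_c: str
) -> dict:
    """Expected class/peptides for one spiked change, by full-sequence rescan.

    Provenance of every mutant base is tracked through an explicit list of
    reference indices (None for substituted/inserted bases); a mutant ATG
    is new unless its three bases carry consecutive unchanged provenance.
    """
    cdna = tx.cdna
    assert cdna[start:end] == ref
    mut = cdna[:start] + alt + cdna[end:]
    prov: list[int | None] = list(range(start)) + [None] * len(alt) + list(
        range(end, len(cdna))
    )
    shift = len(alt) - len(ref)
    mut_cs = tx.cds_start + shift if end <= tx.cds_start else tx.cds_start
    mut_ce = tx.cds_end + shift if start < tx.cds_end else tx.cds_end

    # -- classification (mirrors the junction rule: insertions judged by both flanks)
    if ref == "":
        span_start, span_end = max(start - 1, 0), start + 1
    else:
        span_start, span_end = start, end
    if span_end <= tx.cds_start:
        cls = "utr5_variant"
    elif span_start >= tx.cds_start and span_end <= tx.cds_end:
        stop_span = (tx.cds_end - 3, tx.cds_end)
        is_stop_sub = (
            len(ref) == 1
            and len(alt) == 1
            and stop_span[0] <= start < stop_span[1]
            and cdna[stop_span[0] : stop_span[1]] in {"TAA", "TAG", "TGA"}
        )
        if is_stop_sub:
            codon = list(cdna[stop_span[0] : stop_span[1]])
            codon[start - stop_span[0]] = alt
            cls = "stop_loss" if "".join(codon) not in {"TAA", "TAG", "TGA"} else "other"
        elif shift % 3 != 0:
            cls = "frameshift"
        else:
            cls = "missense"
    else:
        cls = "other"

    # -- expected neoORF records -------------------------------------------
    peptides: list[str] = []
    spans: list[tuple[int, int]] = []
    kozaks: list[str] = []
    stops: list[bool] = []
    polyks: list[int] = []

    if cls == "utr5_variant":
        for p in range(0, mut_cs - 2):
            if mut[p : p + 3] != "ATG":
                continue
            triple = prov[p : p + 3]
            if None not in triple and triple[1] == triple[0] + 1 and triple[2] == triple[1] + 1:
                continue  # pre-existing reference ATG, merely shifted
            pep, found = oracle_translate(mut[p:])
            minus3 = mut[p - 3] if p >= 3 else ""
            plus4 = mut[p + 3] if p + 3 < len(mut) else ""
            met = (minus3 in {"A", "G"}) + (plus4 == "G")
            peptides.append(pep)
            spans.append((0, len(pep)))
            kozaks.append(("weak", "moderate", "strong")[met])
            stops.append(found)
            polyks.append(0 if found else POLYK_LEN)
    elif cls == "stop_loss":
        if mut[mut_ce - 3 : mut_ce] not in {"TAA", "TAG", "TGA"}:
            pep, found = oracle_translate(mut[mut_cs:])
            canonical = (tx.cds_end - tx.cds_start) // 3 - 1
            peptides.append(pep)
            spans.append((canonical, len(pep)))
            kozaks.append("NA")
            stops.append(found)
            polyks.append(0 if found else POLYK_LEN)
    elif cls == "frameshift":
        pep, found = oracle_translate(mut[mut_cs:])
        first = (start - tx.cds_start) // 3
        if len(pep) > first:
            peptides.append(pep)
            spans.append((first, len(pep)))
            kozaks.append("NA")
            stops.append(found)
            polyks.append(0 if found else POLYK_LEN)
    elif cls == "missense":
        ref_pep, _ = oracle_translate(cdna[tx.cds_start :], polyk=0)
        pep, found = oracle_translate(mut[mut_cs:])
        if pep != ref_pep and not (len(pep) < len(ref_pep) and ref_pep.startswith(pep)):
            lo = 0
            while lo < min(len(ref_pep), len(pep)) and ref_pep[lo] == pep[lo]:
                lo += 1
            hi = 0
            while (
                hi < min(len(ref_pep), len(pep)) - lo
                and ref_pep[-1 - hi] == pep[-1 - hi]
            ):
                hi += 1
            span = (lo, len(pep) - hi)
            if span[0] >= span[1]:
                j = min(span[0], len(pep) - 1)
                span = (j, j + 1)
            peptides.append(pep)
            spans.append(span)
            kozaks.append("NA")
            stops.append(found)
            polyks.append(0 if found else POLYK_LEN)

    kmer_counts = {L: _count_kmers(peptides, spans, polyks, L) for L in (9, 10, 11)}
    return {
        "expected_class": cls,
        "n_neoorfs": len(peptides),
        "expected_peptide": ";".join(sorted(peptides)),
        "expected_novel_span": ";".join(f"{a}-{b}" for a, b in sorted(spans)),
        "expected_kozak": ";".join(sorted(kozaks)),
        "expected_stop_found": ";".join(str(s) for s in sorted(stops)),
        "expected_kmers_9": kmer_counts[9],
        "expected_kmers_10": kmer_counts[10],
        "expected_kmers_11": kmer_counts[11],
    }


def _count_kmers(
    peptides: list[str], spans: list[tuple[int, int]], polyks: list[int], L: int
) -> int:
    """Brute-force count of unique novel-overlapping L-mers across one row's ORFs."""
    seen: set[str] = set()
    for pep, (lo, hi), polyk in zip(peptides, spans, polyks):
        eff = len(pep) - polyk
        hi = min(hi, eff)
        for s in range(0, eff - L + 1):
            if s + L > lo and s < hi:
                seen.add(pep[s : s + L])
    return len(seen)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def _genomic_layout(tx: _Tx) -> tuple[str, list[tuple[int, int]]]:
    """Contig sequence and exon intervals (genomic order) for a transcript."""
    rng = random.Random(zlib.crc32(tx.tid.encode()) % (2**31))
    pieces = tx.exon_pieces()
    if tx.strand == "-":
        pieces = [str(Seq(p).reverse_complement()) for p in reversed(pieces)]
    pad5 = "".join(rng.choice("ACGT") for _ in range(tx.pad))
    pad3 = "".join(rng.choice("ACGT") for _ in range(tx.pad))
    introns = [
        "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 18)))
        for _ in range(len(pieces) - 1)
    ]
    seq = pad5
    intervals = []
    for i, piece in enumerate(pieces):
        start = len(seq)
        seq += piece
        intervals.append((start, len(seq)))
        if i < len(introns):
            seq += introns[i]
    seq += pad3
    return seq, intervals


def _tx_model(tx: _Tx, contig_seq: str, intervals: list[tuple[int, int]]) -> TranscriptModel:
    exon_order = tuple(reversed(intervals)) if tx.strand == "-" else tuple(intervals)
    return TranscriptModel(
        transcript_id=tx.tid,
        gene_symbol=tx.gene,
        chromosome=tx.chrom,
        strand=tx.strand,
        exons=exon_order,
        cdna=tx.cdna,
        cds_start=tx.cds_start,
        cds_end=tx.cds_end,
    )


def _gtf_lines(tx: _Tx, model: TranscriptModel) -> list[str]:
    """Ensembl-dialect exon/CDS/stop_codon lines (CDS excludes the stop codon)."""
    attrs = (
        f'gene_id "{tx.gene}G"; transcript_id "{tx.tid}.1"; '
        f'gene_name "{tx.gene}"; gene_biotype "protein_coding";'
    )

    def line(feature: str, start0: int, end0: int) -> str:
        return "\t".join(
            [
                tx.chrom,
                "toy",
                feature,
                str(start0 + 1),
                str(end0),
                ".",
                tx.strand,
                "0" if feature in {"CDS", "stop_codon"} else ".",
                attrs,
            ]
        )

    lines = [line("exon", s, e) for s, e in sorted(model.exons)]

    def genomic_intervals(c_lo: int, c_hi: int) -> list[tuple[int, int]]:
        positions = sorted(model.cdna_to_genomic(i) for i in range(c_lo, c_hi))
        runs: list[tuple[int, int]] = []
        for g in positions:
            if runs and g == runs[-1][1]:
                runs[-1] = (runs[-1][0], g + 1)
            else:
                runs.append((g, g + 1))
        return runs

    for s, e in genomic_intervals(tx.cds_start, tx.cds_end - 3):
        lines.append(line("CDS", s, e))
    for s, e in genomic_intervals(tx.cds_end - 3, tx.cds_end):
        lines.append(line("stop_codon", s, e))
    return lines


def change_to_vcf(
    model: TranscriptModel, contig_seq: str, start: int, end: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """VCF (POS, REF, ALT) for a cdna-space change; indels get a left anchor base.

    Requires the affected cdna span to be genomically contiguous (spiked
    changes are kept within one exon).
    """
    revcomp = lambda s: str(Seq(s).reverse_complement())  # noqa: E731
    if len(ref) == 1 and len(alt) == 1:
        g = model.cdna_to_genomic(start)
        if model.strand == "-":
            return g + 1, revcomp(ref), revcomp(alt)
        return g + 1, ref, alt
    positions = sorted(model.cdna_to_genomic(i) for i in range(start, end))
    if positions:  # deletion / delins: anchor immediately left of the genomic run
        g_lo, g_hi = positions[0], positions[-1] + 1
        assert g_hi - g_lo == len(positions), "indel spans a splice junction"
        anchor = g_lo - 1
    else:  # pure insertion between cdna start-1 and start
        if model.strand == "-":
            anchor = model.cdna_to_genomic(start)  # genomically left of the gap
        else:
            anchor = model.cdna_to_genomic(start - 1)
        g_hi = anchor + 1
    g_ref = contig_seq[anchor:g_hi]
    g_ins = revcomp(alt) if model.strand == "-" else alt
    g_alt = contig_seq[anchor] + g_ins
    return anchor + 1, g_ref, g_alt


def _hgvs_of(tx: _Tx, start: int, end: int, ref: str, alt: str) -> str:
    """Compose the HGVS c. string for a generated change."""
    model_like = _TxCpos(tx)
    if len(ref) == 1 and len(alt) == 1:
        return f"c.{model_like.cpos(start)}{ref}>{alt}"
    if alt == "":
        if end - start == 1:
            return f"c.{model_like.cpos(start)}del"
        return f"c.{model_like.cpos(start)}_{model_like.cpos(end - 1)}del"
    if ref == "":
        return f"c.{model_like.cpos(start - 1)}_{model_like.cpos(start)}ins{alt}"
    if end - start == 1:
        return f"c.{model_like.cpos(start)}delins{alt}"
    return f"c.{model_like.cpos(start)}_{model_like.cpos(end - 1)}delins{alt}"


class _TxCpos:
    def __init__(self, tx: _Tx):
        self.cs, self.ce = tx.cds_start, tx.cds_end

    def cpos(self, index: int) -> str:
        if index < self.cs:
            return str(index - self.cs)
        if index < self.ce:
            return str(index - self.cs + 1)
        return f"*{index - self.ce + 1}"


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=LowQual,Description="Low quality">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Allele|Consequence|Feature|HGVSc">
{contigs}
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_bundle(
    outdir: Path,
    sample: str,
    txs: list[_Tx],
    spikes: list[tuple[_Tx, int, int, str, str, str, str]],
    proteome_extra: list[tuple[str, str]] | None = None,
) -> FixtureBundle:
    """Write FASTA/GTF/VCF/proteome/truth files for a set of transcripts+changes.

    ``spikes`` rows: (tx, start, end, ref, alt, filter_status, forced_consequence).
    """
    outdir.mkdir(parents=True, exist_ok=True)
    contigs: dict[str, str] = {}
    models: dict[str, TranscriptModel] = {}
    gtf_lines: list[str] = []
    proteins: list[tuple[str, str]] = list(proteome_extra or [])

    for tx in txs:
        seq, intervals = _genomic_layout(tx)
        if tx.chrom in contigs:
            raise ValueError(f"duplicate contig {tx.chrom}: one transcript per contig")
        contigs[tx.chrom] = seq
        model = _tx_model(tx, seq, intervals)
        models[tx.tid] = model
        gtf_lines.extend(_gtf_lines(tx, model))
        pep, _ = oracle_translate(tx.cds, polyk=0)
        proteins.append((tx.gene, pep))

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    for suffix in (".fai",):  # stale indices shadow regenerated sequence
        idx = genome_path.with_suffix(genome_path.suffix + suffix)
        idx.unlink(missing_ok=True)

    gtf_path = outdir / "annotation.gtf"
    gtf_path.write_text("#!genome-build toy\n" + "\n".join(gtf_lines) + "\n")

    proteome_path = outdir / "proteome.fa"
    with open(proteome_path, "w") as fh:
        for name, pep in proteins:
            fh.write(f">{name}\n{pep}\n")

    truth_rows = []
    vcf_records = []
    for tx, start, end, ref, alt, filter_status, forced in spikes:
        hgvs = _hgvs_of(tx, start, end, ref, alt)
        expect = oracle_expectations(tx, start, end, ref, alt, hgvs)
        pos, v_ref, v_alt = change_to_vcf(models[tx.tid], contigs[tx.chrom], start, end, ref, alt)
        consequence = forced or _CONSEQUENCE_BY_CLASS[expect["expected_class"]]
        csq = f"{v_alt}|{consequence}|{tx.tid}.1|{tx.tid}.1:{hgvs}"
        vcf_records.append((tx.chrom, pos, v_ref, v_alt, filter_status, csq))
        if filter_status == "PASS":
            truth_rows.append(
                {"sample": sample, "transcript_id": tx.tid, "hgvs_c": hgvs, **expect}
            )

    vcf_path = outdir / "variants.vcf"
    contig_header = "\n".join(
        f"##contig=<ID={name},length={len(seq)}>" for name, seq in contigs.items()
    )
    with open(vcf_path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contig_header))
        for chrom, pos, ref, alt, flt, csq in sorted(vcf_records, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{flt}\tCSQ={csq}\n")

    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    return FixtureBundle(
        outdir=outdir,
        genome=genome_path,
        gtf=gtf_path,
        vcf=vcf_path,
        proteome=proteome_path,
        truth=truth_path,
        sample=sample,
    )


# ---------------------------------------------------------------------------
# Builtin toy
# ---------------------------------------------------------------------------

T1_UTR5 = "GGCAGATCGAGTCCA"
T1_CDS = "ATGGCCAAGTAA"
T1_UTR3 = "GCTAGCATCA"


def toy_transcripts() -> list[_Tx]:
    t1 = _Tx("T1", "TOY1", "chrA", "+", T1_UTR5, T1_CDS, T1_UTR3, exon_breaks=[])
    t1m = _Tx("T1M", "TOY1M", "chrB", "-", T1_UTR5, T1_CDS, T1_UTR3, exon_breaks=[])
    t2 = _Tx(
        "T2",
        "TOY2",
        "chrC",
        "+",
        "TTGCA",
        "ATGAAACCCGGGTGA",
        "ACGTT",
        exon_breaks=[12],
    )
    return [t1, t1m, t2]


#: the spiked panel: every mutation class plus a stop->stop and a synonymous control
TOY_VARIANTS: list[tuple[int, int, str, str]] = [
    (7, 8, "C", "G"),  # c.-8C>G: start-gain, peptide MESNGQVS
    (1, 2, "G", "A"),  # c.-14G>A: 5'UTR variant, no uAUG
    (24, 25, "T", "C"),  # c.10T>C: stop-loss TAA->CAA
    (25, 26, "A", "G"),  # c.11A>G: stop->stop (TGA), class other
    (19, 20, "C", "T"),  # c.5C>T: missense GCC->GTC
    (21, 22, "A", ""),  # c.7del: frameshift
    (20, 21, "C", "T"),  # c.6C>T: synonymous (GCC->GCT)
]


def make_builtin_toy(outdir: str | Path, sample: str = "toy") -> FixtureBundle:
    """Write the builtin toy bundle (T1, its minus-strand mirror, spliced T2)."""
    txs = toy_transcripts()
    t1, t1m, _ = txs
    spikes: list[tuple[_Tx, int, int, str, str, str, str]] = []
    for start, end, ref, alt in TOY_VARIANTS:
        # the stop-loss SNV is deliberately mislabelled to exercise the override
        forced = "synonymous_variant" if (start, end) == (24, 25) else ""
        spikes.append((t1, start, end, ref, alt, "PASS", forced))
        spikes.append((t1m, start, end, ref, alt, "PASS", forced))
    spikes.append((t1, 7, 8, "C", "G", "LowQual", ""))  # non-PASS duplicate
    decoys = [("DECOY1", "MSTLWQPKR"), ("DECOY2", "MGGHHLLKNDRPEW")]
    return _write_bundle(Path(outdir), sample, txs, spikes, proteome_extra=decoys)


# ---------------------------------------------------------------------------
# Random references
# ---------------------------------------------------------------------------


def make_random_reference(
    seed: int,
    outdir: str | Path,
    n_transcripts: int = 10,
    utr5_len_range: tuple[int, int] = (25, 70),
    cds_codon_range: tuple[int, int] = (5, 25),
    utr3_len_range: tuple[int, int] = (12, 40),
    variants_per_transcript: int = 4,
    sample: str = "randsim",
) -> FixtureBundle:
    """Seeded random bundle with oracle-computed truth for spiked variants.

    Each transcript gets a random strand, 1-3 exons, a CDS beginning ATG
    and ending in a stop with no internal in-frame stop, and
    ``variants_per_transcript`` spiked changes drawn across the mutation
    classes (5'UTR substitutions biased towards uAUG-creating sites,
    stop-codon SNVs, CDS substitutions and small deletions/insertions).
    """
    rng = random.Random(seed)
    txs: list[_Tx] = []
    for i in range(n_transcripts):
        utr5 = "".join(rng.choice("ACGT") for _ in range(rng.randint(*utr5_len_range)))
        n_codons = rng.randint(*cds_codon_range)
        cds = "ATG" + "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
        cds += rng.choice(("TAA", "TAG", "TGA"))
        utr3 = "".join(rng.choice("ACGT") for _ in range(rng.randint(*utr3_len_range)))
        cdna_len = len(utr5) + len(cds) + len(utr3)
        n_exons = rng.randint(1, 3)
        breaks = sorted(rng.sample(range(5, cdna_len - 5), n_exons - 1)) if n_exons > 1 else []
        txs.append(
            _Tx(
                tid=f"RTX{i:03d}",
                gene=f"RG{i:03d}",
                chrom=f"chr_r{i:03d}",
                strand=rng.choice("+-"),
                utr5=utr5,
                cds=cds,
                utr3=utr3,
                exon_breaks=breaks,
            )
        )

    spikes: list[tuple[_Tx, int, int, str, str, str, str]] = []
    for tx in txs:
        spikes.extend(_spike_variants(tx, rng, variants_per_transcript))
    return _write_bundle(Path(outdir), sample, txs, spikes)


def make_mirrored_reference(
    seed: int,
    outdir: str | Path,
    n_pairs: int = 20,
    variants_per_transcript: int = 3,
    sample: str = "mirrorsim",
) -> FixtureBundle:
    """Bundle of plus/minus transcript twins carrying identical cdnas and spikes.

    Each pair shares utr5/cds/utr3 and the spiked variant set; the minus
    twin lives reverse-complemented on its own contig. Downstream calls
    must be identical between the twins of every pair.
    """
    rng = random.Random(seed)
    txs: list[_Tx] = []
    spikes: list[tuple[_Tx, int, int, str, str, str, str]] = []
    for i in range(n_pairs):
        utr5 = "".join(rng.choice("ACGT") for _ in range(rng.randint(25, 60)))
        n_codons = rng.randint(5, 20)
        cds = "ATG" + "".join(rng.choice(_SENSE_CODONS) for _ in range(n_codons - 2))
        cds += rng.choice(("TAA", "TAG", "TGA"))
        utr3 = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 30)))
        pair = [
            _Tx(f"MP{i:03d}", f"MGP{i:03d}", f"chr_p{i:03d}", "+", utr5, cds, utr3, []),
            _Tx(f"MM{i:03d}", f"MGM{i:03d}", f"chr_m{i:03d}", "-", utr5, cds, utr3, []),
        ]
        txs.extend(pair)
        picks = _spike_variants(pair[0], rng, variants_per_transcript)
        for _, start, end, ref, alt, flt, forced in picks:
            for tx in pair:
                spikes.append((tx, start, end, ref, alt, flt, forced))
    return _write_bundle(Path(outdir), sample, txs, spikes)


def _exon_of(tx: _Tx, index: int) -> int:
    bounds = [0] + sorted(tx.exon_breaks) + [len(tx.cdna)]
    for k, (a, b) in enumerate(zip(bounds, bounds[1:])):
        if a <= index < b:
            return k
    raise IndexError(index)


def _same_exon(tx: _Tx, start: int, end: int) -> bool:
    return _exon_of(tx, start) == _exon_of(tx, max(start, end - 1))


def _spike_variants(tx: _Tx, rng: random.Random, n: int) -> list:
    """Draw a class-balanced set of spiked changes for one transcript."""
    cdna = tx.cdna
    cs, ce = tx.cds_start, tx.cds_end
    picks: list[tuple[int, int, str, str]] = []

    # targeted uAUG-creating substitution, if any site admits one
    candidates = []
    for i in range(1, cs):
        for alt in "ACGT":
            if alt == cdna[i]:
                continue
            mut = cdna[:i] + alt + cdna[i + 1 :]
            for j in (i - 2, i - 1, i):
                if 0 <= j and j + 3 <= cs and mut[j : j + 3] == "ATG" and cdna[j : j + 3] != "ATG":
                    candidates.append((i, alt))
                    break
    if candidates:
        i, alt = rng.choice(candidates)
        picks.append((i, i + 1, cdna[i], alt))

    # random 5'UTR substitution (any outcome)
    i = rng.randrange(1, cs - 1)
    alt = rng.choice([b for b in "ACGT" if b != cdna[i]])
    picks.append((i, i + 1, cdna[i], alt))

    # 5'UTR insertion carrying an ATG
    if cs > 6:
        j = rng.randrange(2, cs - 2)
        while not _same_exon(tx, j - 1, j + 1):
            j = rng.randrange(2, cs - 2)
        picks.append((j, j, "", rng.choice(["ATG", "CATGA", "AATGT"])))

    # stop-codon SNV (sense or stop->stop)
    k = rng.randrange(ce - 3, ce)
    alt = rng.choice([b for b in "ACGT" if b != cdna[k]])
    picks.append((k, k + 1, cdna[k], alt))

    # CDS substitution (missense or synonymous)
    i = rng.randrange(cs + 3, ce - 3)
    alt = rng.choice([b for b in "ACGT" if b != cdna[i]])
    picks.append((i, i + 1, cdna[i], alt))

    # small CDS deletion: frameshift (1-2 nt) or in-frame (3 nt)
    for width in rng.sample([1, 2, 3], k=2):
        lo = rng.randrange(cs + 3, ce - 6)
        if _same_exon(tx, lo, lo + width):
            picks.append((lo, lo + width, cdna[lo : lo + width], ""))

    rng.shuffle(picks)
    seen_spans: set[tuple[int, int, str]] = set()
    out = []
    for start, end, ref, alt in picks:
        key = (start, end, alt)
        if key in seen_spans:
            continue
        seen_spans.add(key)
        out.append((tx, start, end, ref, alt, "PASS", ""))
        if len(out) >= n:
            break
    return out
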