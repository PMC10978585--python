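"""Strand-aware transcript models and coordinate arithmetic.

Loads a reference genome (FASTA) plus an Ensembl-dialect GTF into
:class:`TranscriptModel` objects holding the spliced cDNA, and converts
between genomic, cDNA and HGVS c. coordinates.

Coordinate conventions
----------------------
Internal coordinates are 0-based half-open. GTF coordinates (1-based,
closed) and VCF POS (1-based) are converted at the boundary of this module
and nowhere else. HGVS c. positions follow the standard convention:
``c.-N`` counts backwards from the base 5' of the start codon, ``c.N``
(N >= 1) counts CDS bases from the A of the start codon, and ``c.*N``
counts 3'UTR bases from the first base after the stop codon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(transcript_id: str) -> str:
    """Remove a trailing Ensembl version suffix (``ENST...​.3`` -> ``ENST...``)."""
    return _VERSION_RE.sub("", transcript_id)


class CoordinateError(ValueError):
    """An HGVS/cDNA position falls outside the transcript bounds."""


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced protein-coding transcript with its 5'UTR/CDS/3'UTR partition.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation (descending genomic start for minus-strand
    transcripts). ``cdna`` is the sense-strand spliced sequence; the CDS,
    including the annotated stop codon, occupies ``cdna[cds_start:cds_end]``.
    """

    transcript_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cdna: str
    cds_start: int
    cds_end: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.cds_start < self.cds_end <= len(self.cdna)):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                f"outside cdna of length {len(self.cdna)}"
            )
        if self.cds_end - self.cds_start < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than one codon")

    # -- sequence partition -------------------------------------------------

    @property
    def utr5(self) -> str:
        return self.cdna[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.cdna[self.cds_end :]

    def spliced_regions(self) -> tuple[str, str, str]:
        """Return ``(utr5, cds, utr3)``; their concatenation equals ``cdna``."""
        return self.utr5, self.cds, self.utr3

    # -- HGVS c. arithmetic -------------------------------------------------

    def cpos_to_index(self, cpos: str) -> int:
        """Convert an HGVS c. position string (``-N``, ``N`` or ``*N``) to a cdna index."""
        text = cpos.strip()
        if text.startswith("c."):
            text = text[2:]
        m = re.fullmatch(r"(\*?-?\d+)([+-]\d+)?", text)
        if m is None:
            raise CoordinateError(f"unsupported HGVS position {cpos!r}")
        if m.group(2) is not None:
            raise CoordinateError(
                f"intronic offset in {cpos!r} unsupported: positions must lie on the spliced cDNA"
            )
        body = m.group(1)
        if body.startswith("*"):
            n = int(body[1:])
            if n < 1:
                raise CoordinateError(f"invalid 3'UTR position {cpos!r}")
            idx = self.cds_end + n - 1
        else:
            n = int(body)
            if n == 0:
                raise CoordinateError("HGVS c. has no position 0")
            idx = self.cds_start + n - 1 if n > 0 else self.cds_start + n
        if not 0 <= idx < len(self.cdna):
            raise CoordinateError(
                f"{self.transcript_id}: position {cpos} beyond transcript bounds"
            )
        return idx

    def index_to_cpos(self, index: int) -> str:
        """Inverse of :meth:`cpos_to_index` for any index within the cdna."""
        if not 0 <= index < len(self.cdna):
            raise CoordinateError(
                f"{self.transcript_id}: index {index} beyond transcript bounds"
            )
        if index < self.cds_start:
            return str(index - self.cds_start)
        if index < self.cds_end:
            return str(index - self.cds_start + 1)
        return f"*{index - self.cds_end + 1}"

    # -- genomic mapping ----------------------------------------------------

    def genomic_to_cdna(self, gpos: int) -> int:
        """Map a genomic 0-based position to a cdna index (exonic positions only)."""
        offset = 0
        for start, end in self.exons:
            if start <= gpos < end:
                if self.strand == "+":
                    return offset + (gpos - start)
                return offset + (end - 1 - gpos)
            offset += end - start
        raise CoordinateError(
            f"{self.transcript_id}: genomic position {gpos} not exonic"
        )

    def cdna_to_genomic(self, index: int) -> int:
        """Map a cdna index back to its genomic 0-based position."""
        if not 0 <= index < len(self.cdna):
            raise CoordinateError(
                f"{self.transcript_id}: index {index} beyond transcript bounds"
            )
        offset = 0
        for start, end in self.exons:
            length = end - start
            if index < offset + length:
                within = index - offset
                if self.strand == "+":
                    return start + within
                return end - 1 - within
            offset += length
        raise AssertionError("unreachable: exon lengths must cover the cdna")


@dataclass
class TranscriptSet:
    """A keyed collection of transcript models plus the genome-build label."""

    models: dict[str, TranscriptModel]
    genome_build: str = "unspecified"

    def __len__(self) -> int:
        return len(self.models)

    def __contains__(self, transcript_id: str) -> bool:
        return strip_version(transcript_id) in self.models

    def get(self, transcript_id: str) -> TranscriptModel | None:
        return self.models.get(strip_version(transcript_id))

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        model = self.get(transcript_id)
        if model is None:
            raise KeyError(f"transcript {transcript_id} not in reference")
        return model

    def __iter__(self) -> Iterable[TranscriptModel]:
        return iter(self.models.values())


# ---------------------------------------------------------------------------
# GTF + FASTA loading
# ---------------------------------------------------------------------------

_GTF_FIELDS = 9


def _clean_gtf_lines(path: Path) -> str:
    """Return GTF text with malformed data lines dropped (each logged)."""
    kept: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                kept.append(line)
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != _GTF_FIELDS or not (
                parts[3].isdigit() and parts[4].isdigit()
            ):
                logger.warning("%s:%d: malformed GTF line skipped", path, lineno)
                continue
            kept.append(line)
    return "".join(kept)


def load_reference(
    genome_fasta: str | Path,
    annotation: str | Path,
    genome_build: str = "unspecified",
) -> TranscriptSet:
    """Build a :class:`TranscriptSet` from an indexed genome FASTA and a GTF.

    Every transcript with at least one ``CDS`` feature yields a model; the
    annotated stop codon (Ensembl keeps it in separate ``stop_codon``
    features) is merged into the CDS span. Transcripts whose CDS length is
    not a multiple of 3, or whose CDS does not begin with ATG, are loaded
    but flagged rather than dropped.
    """
    genome_fasta = Path(genome_fasta)
    annotation = Path(annotation)
    if not annotation.exists():
        raise FileNotFoundError(f"annotation not found: {annotation}")
    genome = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        _clean_gtf_lines(annotation),
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in {"exon", "CDS", "stop_codon"}:
            continue
        tid_attr = feat.attributes.get("transcript_id")
        if not tid_attr:
            logger.warning("%s feature without transcript_id skipped", feat.featuretype)
            continue
        tid = strip_version(tid_attr[0])
        gene = (feat.attributes.get("gene_name") or feat.attributes.get("gene_id") or [""])[0]
        meta[tid] = (feat.seqid, feat.strand, gene)
        # gffutils keeps GFF 1-based closed coordinates; convert here once
        interval = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(interval)
        else:
            cds.setdefault(tid, []).append(interval)

    models: dict[str, TranscriptModel] = {}
    for tid, exon_list in sorted(exons.items()):
        if tid not in cds:
            logger.warning("transcript %s has no CDS features; skipped", tid)
            continue
        chrom, strand, gene = meta[tid]
        if chrom not in genome:
            raise KeyError(
                f"contig {chrom!r} required by transcript {tid} missing from {genome_fasta}"
            )
        exon_list = sorted(set(exon_list))
        for (s1, e1), (s2, _) in zip(exon_list, exon_list[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {tid}: overlapping exons")
        pieces = [str(genome[chrom][s:e]) for s, e in exon_list]
        if strand == "-":
            exon_order = tuple(reversed(exon_list))
            cdna = str(Seq("".join(pieces)).reverse_complement())
        else:
            exon_order = tuple(exon_list)
            cdna = "".join(pieces)

        cds_intervals = sorted(set(cds[tid]))
        cds_len = sum(e - s for s, e in cds_intervals)
        cds_gmin, cds_gmax = cds_intervals[0][0], cds_intervals[-1][1]
        first_cds_g = cds_gmin if strand == "+" else cds_gmax - 1
        model_stub = TranscriptModel(
            transcript_id=tid,
            gene_symbol=gene,
            chromosome=chrom,
            strand=strand,
            exons=exon_order,
            cdna=cdna,
            cds_start=0,
            cds_end=len(cdna),
        )
        try:
            cds_start = model_stub.genomic_to_cdna(first_cds_g)
        except CoordinateError as exc:
            logger.warning("transcript %s: CDS outside exons (%s); skipped", tid, exc)
            continue
        cds_end = cds_start + cds_len
        if cds_end > len(cdna):
            logger.warning("transcript %s: CDS extends past cdna; skipped", tid)
            continue

        flags = []
        if cds_len % 3 != 0:
            flags.append("cds_length_not_multiple_of_3")
        if not cdna[cds_start : cds_start + 3] == "ATG":
            flags.append("cds_not_starting_atg")
        models[tid] = TranscriptModel(
            transcript_id=tid,
            gene_symbol=gene,
            chromosome=chrom,
            strand=strand,
            exons=exon_order,
            cdna=cdna,
            cds_start=cds_start,
            cds_end=cds_end,
            flags=tuple(flags),
        )
    logger.info("loaded %d transcript models from %s", len(models), annotation)
    return TranscriptSet(models=models, genome_build=genome_build)
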