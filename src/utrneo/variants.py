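"""Somatic variant ingestion, HGVS c. parsing and mutation-class calls.

Reads PASS-filtered VCF records carrying VEP ``CSQ`` (or ``ANN``)
per-transcript annotations, resolves each HGVS c. string against a
:class:`~utrneo.refmodel.TranscriptModel`, and assigns one of the four
mutation classes the caller operates on: ``missense``, ``frameshift``,
``utr5_variant`` and ``stop_loss`` (everything else is ``other``).

Classification is recomputed from the transcript sequence and the parsed
change; VEP consequence terms are only used as a cross-check, so a
mislabelled final-codon SNV is still called stop-loss.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from cyvcf2 import VCF

from utrneo.refmodel import CoordinateError, TranscriptModel, strip_version

logger = logging.getLogger(__name__)

MAX_INDEL_NT = 50  # interprets "short insertion-deletion"; longer changes are skipped

STOP_CODONS = {"TAA", "TAG", "TGA"}

VALID_BASES = set("ACGT")


class HgvsError(ValueError):
    """Raised when an HGVS c. string cannot be resolved on a transcript."""


class UnsupportedHgvs(HgvsError):
    """Grammar outside the supported subset (introns, inversions, ...)."""


@dataclass(frozen=True)
class AnnotatedVariant:
    """One (decomposed) somatic variant with its per-transcript annotations."""

    chromosome: str
    position: int  # 1-based genomic POS
    ref_allele: str
    alt_allele: str
    filter_status: str
    annotations: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)
    # each annotation: (transcript_id, consequence_terms, hgvs_c_string)
    sample: str = ""


@dataclass(frozen=True)
class CodingChange:
    """A parsed HGVS c. change anchored in cdna coordinates.

    ``start_index``/``end_index`` delimit the half-open span of replaced
    reference bases (zero-length at the insertion point for insertions);
    ``region`` locates the span in the transcript partition.
    """

    kind: str  # sub | del | ins | dup | delins
    start_index: int
    end_index: int
    ref_seq: str
    alt_seq: str
    region: str  # utr5 | cds | utr3 | spanning
    hgvs_c: str = ""

    @property
    def shift(self) -> int:
        return len(self.alt_seq) - len(self.ref_seq)


# ---------------------------------------------------------------------------
# HGVS c. grammar
# ---------------------------------------------------------------------------

_POS = r"(?:\*?-?\d+(?:[+-]\d+)?)"
_SUB_RE = re.compile(rf"c\.({_POS})([ACGT])>([ACGT])$")
_DEL_RE = re.compile(rf"c\.({_POS})(?:_({_POS}))?del([ACGT]*)$")
_INS_RE = re.compile(rf"c\.({_POS})_({_POS})ins([ACGT]+)$")
_DUP_RE = re.compile(rf"c\.({_POS})(?:_({_POS}))?dup([ACGT]*)$")
_DELINS_RE = re.compile(rf"c\.({_POS})(?:_({_POS}))?delins([ACGT]+)$")


def _region_of(t: TranscriptModel, start: int, end: int) -> str:
    """Locate a half-open cdna span in the transcript partition.

    An insertion point is judged by both its flanking bases, so an
    insertion exactly at a region boundary comes out ``spanning`` (and is
    classified ``other`` downstream rather than guessed).
    """
    if end <= start:
        start, end = max(start - 1, 0), start + 1
    regions = set()
    if start < t.cds_start:
        regions.add("utr5")
    if end > t.cds_end:
        regions.add("utr3")
    if start < t.cds_end and end > t.cds_start:
        regions.add("cds")
    return regions.pop() if len(regions) == 1 else "spanning"


def parse_hgvs_c(text: str, t: TranscriptModel) -> CodingChange:
    """Parse an HGVS c. string and verify it against the transcript cdna.

    Supports substitutions, del, ins, dup and delins on the spliced cDNA.
    Intronic offsets (``c.76+5``) and other syntax raise
    :class:`UnsupportedHgvs`; a stated reference base that disagrees with
    the transcript raises :class:`HgvsError`.
    """
    text = text.strip()
    if ":" in text:  # tolerate "ENST...:c.-94G>A" as emitted by VEP
        text = text.rsplit(":", 1)[1]

    def resolve(cpos: str) -> int:
        try:
            return t.cpos_to_index(cpos)
        except CoordinateError as exc:
            if "+" in cpos.lstrip("-*") or re.search(r"\d[+-]\d", cpos):
                raise UnsupportedHgvs(str(exc)) from exc
            raise HgvsError(str(exc)) from exc

    if m := _SUB_RE.match(text):
        cpos, ref, alt = m.groups()
        idx = resolve(cpos)
        if t.cdna[idx] != ref:
            raise HgvsError(
                f"reference mismatch at c.{cpos}: HGVS states {ref}, transcript has {t.cdna[idx]}"
            )
        if ref == alt:
            raise HgvsError(f"{text}: reference and alternate allele identical")
        return CodingChange("sub", idx, idx + 1, ref, alt, _region_of(t, idx, idx + 1), text)

    if m := _DELINS_RE.match(text):
        p1, p2, alt = m.groups()
        start = resolve(p1)
        end = resolve(p2) + 1 if p2 else start + 1
        ref = t.cdna[start:end]
        if ref == alt:
            raise HgvsError(f"{text}: delins leaves sequence unchanged")
        return CodingChange("delins", start, end, ref, alt, _region_of(t, start, end), text)

    if m := _DEL_RE.match(text):
        p1, p2, stated = m.groups()
        start = resolve(p1)
        end = resolve(p2) + 1 if p2 else start + 1
        ref = t.cdna[start:end]
        if stated and stated != ref:
            raise HgvsError(
                f"reference mismatch in {text}: HGVS states {stated}, transcript has {ref}"
            )
        return CodingChange("del", start, end, ref, "", _region_of(t, start, end), text)

    if m := _INS_RE.match(text):
        p1, p2, alt = m.groups()
        left = resolve(p1)
        right = resolve(p2)
        if right != left + 1:
            raise HgvsError(f"{text}: ins positions must be adjacent")
        return CodingChange("ins", right, right, "", alt, _region_of(t, right, right), text)

    if m := _DUP_RE.match(text):
        p1, p2, stated = m.groups()
        start = resolve(p1)
        end = resolve(p2) + 1 if p2 else start + 1
        dup = t.cdna[start:end]
        if stated and stated != dup:
            raise HgvsError(
                f"reference mismatch in {text}: HGVS states {stated}, transcript has {dup}"
            )
        # modelled as an insertion of the duplicated bases after the span
        return CodingChange("dup", end, end, "", dup, _region_of(t, start, end), text)

    if re.search(r"\d[+-]\d", text):
        raise UnsupportedHgvs(f"intronic offsets unsupported: {text}")
    raise UnsupportedHgvs(f"unsupported HGVS syntax: {text}")


# ---------------------------------------------------------------------------
# Mutation classes
# ---------------------------------------------------------------------------


def classify_consequence(
    v: AnnotatedVariant | None,
    t: TranscriptModel,
    change: CodingChange,
    vep_terms: str | None = None,
) -> str:
    """Assign the mutation class for a resolved change on one transcript.

    The decision depends only on ``(cdna, change)``: 5'UTR changes are
    ``utr5_variant`` (all are later scanned for uAUG formation);
    substitutions inside the annotated stop codon that yield a sense codon
    are ``stop_loss`` regardless of the annotated consequence; CDS indels
    with a length shift not divisible by 3 are ``frameshift``; remaining
    CDS subs/DNVs/in-frame indels are ``missense``. Everything else falls
    through to ``other``.
    """
    if max(len(change.ref_seq), len(change.alt_seq)) > MAX_INDEL_NT:
        logger.warning("%s: change longer than %d nt classified other", change.hgvs_c, MAX_INDEL_NT)
        return "other"

    stop_codon_sub = (
        change.kind == "sub"
        and t.cds_end - 3 <= change.start_index < t.cds_end
        and t.cdna[t.cds_end - 3 : t.cds_end] in STOP_CODONS
    )
    if change.region == "utr5":
        cls = "utr5_variant"
    elif stop_codon_sub:
        # a stop->stop exchange alters no residue; a stop->sense is stop_loss
        cls = "stop_loss" if _is_stop_loss_sub(t, change) else "other"
    elif change.region == "cds":
        if change.shift % 3 != 0:
            cls = "frameshift"
        else:
            cls = "missense"
    else:
        cls = "other"

    if vep_terms and cls == "stop_loss" and "stop_lost" not in vep_terms:
        logger.info(
            "%s: called stop_loss although VEP annotated %r (final-codon override)",
            change.hgvs_c,
            vep_terms,
        )
    return cls


def _is_stop_loss_sub(t: TranscriptModel, change: CodingChange) -> bool:
    """True iff a substitution inside the annotated stop codon yields a sense codon."""
    stop_span = (t.cds_end - 3, t.cds_end)
    if change.kind != "sub":
        return False
    if not (stop_span[0] <= change.start_index < stop_span[1]):
        return False
    ref_codon = t.cdna[stop_span[0] : stop_span[1]]
    if ref_codon not in STOP_CODONS:
        return False
    offset = change.start_index - stop_span[0]
    mut_codon = ref_codon[:offset] + change.alt_seq + ref_codon[offset + 1 :]
    return mut_codon not in STOP_CODONS


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _csq_spec(vcf: VCF) -> tuple[str, dict[str, int]]:
    """Locate the CSQ/ANN INFO definition and map its Format field names to indices."""
    for key in ("CSQ", "ANN"):
        try:
            desc = vcf.get_header_type(key)["Description"]
        except KeyError:
            continue
        m = re.search(r"Format:\s*([^\"]+)", desc)
        if not m:
            continue
        names = [n.strip() for n in m.group(1).strip("'\" ").split("|")]
        return key, {name: i for i, name in enumerate(names)}
    raise ValueError(
        "VCF lacks a CSQ/ANN INFO definition: annotate the calls with VEP "
        "(--vcf --hgvs) before running the scan"
    )


def read_annotated_vcf(
    path: str | Path,
    pass_only: bool = True,
    sample: str | None = None,
) -> list[AnnotatedVariant]:
    """Read VEP-annotated somatic variants, one record per (site, alt allele).

    Only ``FILTER=PASS`` (or missing-filter) records are kept unless
    ``pass_only=False``. Multi-allelic records are decomposed; CSQ blocks
    are matched to their alt allele via the ``Allele`` field when present.
    Records with non-ACGT alleles are dropped with a warning.
    """
    path = Path(path)
    if sample is None:
        sample = path.name.removesuffix(".gz").removesuffix(".vcf")
    vcf = VCF(str(path))
    key, fields = _csq_spec(vcf)
    required = {"Consequence", "Feature", "HGVSc"}
    missing = required - fields.keys()
    if missing:
        raise ValueError(f"{key} Format lacks required fields: {sorted(missing)}")

    out: list[AnnotatedVariant] = []
    for rec in vcf:
        filter_status = rec.FILTER or "PASS"  # cyvcf2 reports PASS as None
        if pass_only and filter_status not in {"PASS", "."}:
            continue
        raw = rec.INFO.get(key)
        blocks = raw.split(",") if raw else []
        for alt in rec.ALT:
            if set(rec.REF) - VALID_BASES or set(alt) - VALID_BASES:
                logger.warning(
                    "%s:%d %s>%s: non-ACGT allele dropped", rec.CHROM, rec.POS, rec.REF, alt
                )
                continue
            annotations = []
            for block in blocks:
                cols = block.split("|")
                allele = cols[fields["Allele"]] if "Allele" in fields else alt
                if allele and allele != alt:
                    continue
                tid = cols[fields["Feature"]]
                hgvs_c = cols[fields["HGVSc"]]
                terms = cols[fields["Consequence"]]
                if not hgvs_c or "c." not in hgvs_c:
                    logger.info(
                        "%s:%d transcript %s lacks HGVSc; annotation skipped",
                        rec.CHROM,
                        rec.POS,
                        tid,
                    )
                    continue
                annotations.append((strip_version(tid), terms, hgvs_c))
            out.append(
                AnnotatedVariant(
                    chromosome=rec.CHROM,
                    position=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    filter_status=filter_status,
                    annotations=tuple(annotations),
                    sample=sample,
                )
            )
    return out
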