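"""The neoORF engine: mutant transcripts, uAUG detection and translation.

Applies a parsed coding change to a transcript, finds tumour-specific new
upstream ATGs, translates the resulting open reading frames 5'->3' until
the first in-frame stop codon (TAA/TAG/TGA), and calls stop-loss,
frameshift and missense neopeptides under the same translation rules.
Reading frames that reach the transcript end without a stop codon are
read through to the mRNA poly-A tail, modelled as a configurable
poly-lysine tail (the event is always flagged so downstream consumers can
drop the tail).

Start-gain calls additionally carry a Kozak-context strength (positions
-3 and +4 around the new ATG), the nucleotide overlap of the neoORF with
the canonical CDS, an in-frame-overlap flag, and whether the neoORF
intersects any wild-type uORF already present in the reference 5'UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio.Data.CodonTable import standard_dna_table

from utrneo.refmodel import TranscriptModel
from utrneo.variants import STOP_CODONS, CodingChange

logger = logging.getLogger(__name__)

DEFAULT_POLYK_LEN = 12

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in standard_dna_table.stop_codons})
assert set(standard_dna_table.stop_codons) == STOP_CODONS


@dataclass(frozen=True)
class MutantTranscript:
    """A transcript cdna with one coding change applied.

    ``changed_span_mut`` is the half-open interval of replaced/inserted
    bases in mutant coordinates; positions outside it map 1:1 onto
    reference positions via :meth:`map_to_ref`.
    """

    base: TranscriptModel
    change: CodingChange
    mut_cdna: str
    shift: int
    changed_span_mut: tuple[int, int]

    @property
    def mut_cds_start(self) -> int:
        if self.change.end_index <= self.base.cds_start:
            return self.base.cds_start + self.shift
        return self.base.cds_start

    @property
    def mut_cds_end(self) -> int:
        if self.change.start_index < self.base.cds_end:
            return self.base.cds_end + self.shift
        return self.base.cds_end

    def map_to_ref(self, pos: int) -> int | None:
        """Reference cdna index for a mutant position, or None for novel bases."""
        lo, hi = self.changed_span_mut
        if pos < lo:
            return pos
        if pos >= hi:
            return pos - self.shift
        return None

    def numbering_pos(self, pos: int) -> int | None:
        """Reference index usable for HGVS numbering; substituted bases keep theirs."""
        mapped = self.map_to_ref(pos)
        if mapped is not None:
            return mapped
        if len(self.change.ref_seq) == len(self.change.alt_seq):
            return pos  # same-length replacement: positional identity retained
        return None


@dataclass(frozen=True)
class TranslationResult:
    peptide: str
    stop_found: bool
    orf_nt_span: tuple[int, int]
    polyA_readthrough: bool
    polyk_tail: int = 0  # number of appended poly-lysine residues (0 iff stop_found)


@dataclass(frozen=True)
class NeoOrf:
    """One predicted neo-open-reading-frame and its annotations."""

    orf_class: str  # start_gain | stop_loss | frameshift | missense
    transcript_id: str
    gene_symbol: str
    hgvs_c: str
    peptide: str
    novel_span: tuple[int, int]  # half-open residue interval of novel sequence
    stop_found: bool
    uaug_cpos: str = ""  # HGVS c. position of the new ATG (start_gain only)
    kozak: str = "NA"  # weak | moderate | strong | NA
    cds_overlap_fraction: float | None = None
    inframe_cds: bool | None = None
    wt_uorf_overlap: bool | None = None
    polyk_tail: int = 0
    orf_nt_span: tuple[int, int] | None = None  # mutant cdna coordinates

    def sort_key(self) -> tuple:
        return (self.transcript_id, self.hgvs_c, self.orf_class, self.uaug_cpos)


# ---------------------------------------------------------------------------
# Mutant construction and translation
# ---------------------------------------------------------------------------


def apply_change(t: TranscriptModel, change: CodingChange) -> MutantTranscript:
    """Apply ``change`` to the transcript cdna."""
    if change.end_index > len(t.cdna):
        raise ValueError(f"{change.hgvs_c}: change span exceeds transcript")
    ref = t.cdna[change.start_index : change.end_index]
    if ref != change.ref_seq:
        raise ValueError(
            f"{change.hgvs_c}: reference mismatch ({change.ref_seq!r} vs cdna {ref!r})"
        )
    mut = t.cdna[: change.start_index] + change.alt_seq + t.cdna[change.end_index :]
    return MutantTranscript(
        base=t,
        change=change,
        mut_cdna=mut,
        shift=change.shift,
        changed_span_mut=(change.start_index, change.start_index + len(change.alt_seq)),
    )


def find_new_uaugs(mt: MutantTranscript) -> list[int]:
    """Mutant-5'UTR positions where the change created a net-new ATG.

    A triplet counts as new when it does not map base-for-base onto three
    consecutive reference positions (i.e. at least one base is substituted
    or inserted, or the triplet straddles a deletion junction). Reference
    ATGs merely shifted by an upstream indel are therefore excluded: they
    already exist in the wild-type mRNA.
    """
    cds_start = mt.mut_cds_start
    hits: list[int] = []
    for p in range(0, max(cds_start - 2, 0)):
        if mt.mut_cdna[p : p + 3] != "ATG" or p + 3 > cds_start:
            continue
        mapped = [mt.map_to_ref(p + k) for k in range(3)]
        preexisting = (
            None not in mapped
            and mapped[1] == mapped[0] + 1
            and mapped[2] == mapped[1] + 1
        )
        if not preexisting:
            hits.append(p)
    return hits


def translate_from(
    mt: MutantTranscript | str,
    start: int,
    polyk_len: int = DEFAULT_POLYK_LEN,
) -> TranslationResult:
    """Translate codon-by-codon from ``start`` until the first in-frame stop.

    Accepts a mutant transcript or a bare nucleotide string. If no stop is
    reached within the sequence the frame is treated as reading through to
    the poly-A tail: ``polyk_len`` lysines are appended and the event
    flagged. A trailing 1-2 nt partial codon is discarded (logged at debug
    level).
    """
    seq = mt if isinstance(mt, str) else mt.mut_cdna
    if start < 0 or start + 3 > len(seq):
        raise ValueError(f"translation start {start} leaves no full codon")
    residues: list[str] = []
    pos = start
    stop_found = False
    while pos + 3 <= len(seq):
        aa = _CODON_TO_AA[seq[pos : pos + 3]]
        pos += 3
        if aa == "*":
            stop_found = True
            break
        residues.append(aa)
    if not stop_found and pos < len(seq):
        logger.debug("partial codon of %d nt discarded at transcript end", len(seq) - pos)
    peptide = "".join(residues)
    tail = 0
    if not stop_found:
        tail = polyk_len
        peptide += "K" * tail
    return TranslationResult(
        peptide=peptide,
        stop_found=stop_found,
        orf_nt_span=(start, pos),
        polyA_readthrough=not stop_found,
        polyk_tail=tail,
    )


# ---------------------------------------------------------------------------
# Start-gain annotations
# ---------------------------------------------------------------------------


def kozak_strength(mt: MutantTranscript, uaug_pos: int) -> str:
    """Kozak context class of an ATG at ``uaug_pos`` on the mutant cdna.

    strong: purine at -3 AND G at +4; moderate: exactly one criterion;
    weak: neither. A position falling outside the transcript counts as an
    unmet criterion (no evidence, conservatively not strong).
    """
    seq = mt.mut_cdna
    minus3 = seq[uaug_pos - 3] if uaug_pos - 3 >= 0 else ""
    plus4 = seq[uaug_pos + 3] if uaug_pos + 3 < len(seq) else ""
    met = (minus3 in {"A", "G"}) + (plus4 == "G")
    return ("weak", "moderate", "strong")[met]


def _reference_uorf_spans(t: TranscriptModel) -> list[tuple[int, int]]:
    """ORF spans (ref cdna coords) opened by every wild-type 5'UTR ATG."""
    spans = []
    for q in range(0, max(t.cds_start - 2, 0)):
        if t.cdna[q : q + 3] == "ATG":
            tr = translate_from(t.cdna, q, polyk_len=0)
            spans.append(tr.orf_nt_span)
    return spans


def wt_orf_overlap(
    t: TranscriptModel, mt: MutantTranscript, orf_nt_span: tuple[int, int]
) -> tuple[float, bool, bool]:
    """Overlap of a neoORF with the canonical CDS and with wild-type uORFs.

    Returns ``(cds_overlap_fraction, inframe_cds, wt_uorf_overlap)``:
    nucleotides of the neoORF span (stop included) inside the canonical
    CDS divided by the neoORF length; whether the neoORF frame is
    congruent with the CDS frame where they overlap; and whether the span
    intersects any ORF opened by a reference 5'UTR ATG.
    """
    start, end = orf_nt_span
    length = end - start
    cds_lo, cds_hi = mt.mut_cds_start, mt.mut_cds_end
    overlap = max(0, min(end, cds_hi) - max(start, cds_lo))
    fraction = overlap / length if length else 0.0
    inframe = overlap > 0 and (cds_lo - start) % 3 == 0

    wt_hit = False
    ref_points = [r for r in (mt.map_to_ref(p) for p in range(start, end)) if r is not None]
    if ref_points:
        ref_lo, ref_hi = min(ref_points), max(ref_points) + 1
        for u_lo, u_hi in _reference_uorf_spans(t):
            if min(ref_hi, u_hi) > max(ref_lo, u_lo):
                wt_hit = True
                break
    return fraction, inframe, wt_hit


# ---------------------------------------------------------------------------
# Per-class callers
# ---------------------------------------------------------------------------


def call_start_gain(
    t: TranscriptModel, change: CodingChange, polyk_len: int = DEFAULT_POLYK_LEN
) -> list[NeoOrf]:
    """One NeoOrf per net-new uAUG created by a 5'UTR change."""
    mt = apply_change(t, change)
    orfs: list[NeoOrf] = []
    for p in find_new_uaugs(mt):
        tr = translate_from(mt, p, polyk_len=polyk_len)
        fraction, inframe, wt_hit = wt_orf_overlap(t, mt, tr.orf_nt_span)
        ref_pos = mt.numbering_pos(p)
        uaug_cpos = (
            "c." + t.index_to_cpos(ref_pos) if ref_pos is not None else "inserted"
        )
        orfs.append(
            NeoOrf(
                orf_class="start_gain",
                transcript_id=t.transcript_id,
                gene_symbol=t.gene_symbol,
                hgvs_c=change.hgvs_c,
                peptide=tr.peptide,
                novel_span=(0, len(tr.peptide)),
                stop_found=tr.stop_found,
                uaug_cpos=uaug_cpos,
                kozak=kozak_strength(mt, p),
                cds_overlap_fraction=fraction,
                inframe_cds=inframe,
                wt_uorf_overlap=wt_hit,
                polyk_tail=tr.polyk_tail,
                orf_nt_span=tr.orf_nt_span,
            )
        )
    return orfs


def call_stop_loss(
    t: TranscriptModel, change: CodingChange, polyk_len: int = DEFAULT_POLYK_LEN
) -> NeoOrf | None:
    """Read-through peptide for a stop-codon substitution to a sense codon.

    The peptide is the canonical protein followed by the new residue at
    the former stop position and the 3'UTR translation; the novel span
    runs from the new residue to the peptide end.
    """
    mt = apply_change(t, change)
    stop_lo = mt.mut_cds_end - 3
    if mt.mut_cdna[stop_lo : stop_lo + 3] in STOP_CODONS:
        return None
    tr = translate_from(mt, mt.mut_cds_start, polyk_len=polyk_len)
    canonical_len = (t.cds_end - t.cds_start) // 3 - 1
    if len(tr.peptide) <= canonical_len:
        logger.warning("%s: read-through produced no novel residue", change.hgvs_c)
        return None
    return NeoOrf(
        orf_class="stop_loss",
        transcript_id=t.transcript_id,
        gene_symbol=t.gene_symbol,
        hgvs_c=change.hgvs_c,
        peptide=tr.peptide,
        novel_span=(canonical_len, len(tr.peptide)),
        stop_found=tr.stop_found,
        polyk_tail=tr.polyk_tail,
        orf_nt_span=tr.orf_nt_span,
    )


def call_coding(
    t: TranscriptModel, change: CodingChange, polyk_len: int = DEFAULT_POLYK_LEN
) -> NeoOrf | None:
    """Missense or frameshift peptide from a CDS change.

    Missense: the full mutant protein with the changed residue positions
    as novel span (None for synonymous changes or pure truncations).
    Frameshift: translation proceeds in the shifted frame from the first
    codon containing a changed base until a stop or the poly-A rule;
    preceding canonical residues stay in the peptide (tryptic context)
    but outside the novel span.
    """
    mt = apply_change(t, change)
    tr = translate_from(mt, mt.mut_cds_start, polyk_len=polyk_len)
    if change.shift % 3 != 0:
        first_codon = (change.start_index - t.cds_start) // 3
        if len(tr.peptide) <= first_codon:
            logger.info("%s: frameshift truncates before any novel residue", change.hgvs_c)
            return None
        return NeoOrf(
            orf_class="frameshift",
            transcript_id=t.transcript_id,
            gene_symbol=t.gene_symbol,
            hgvs_c=change.hgvs_c,
            peptide=tr.peptide,
            novel_span=(first_codon, len(tr.peptide)),
            stop_found=tr.stop_found,
            polyk_tail=tr.polyk_tail,
            orf_nt_span=tr.orf_nt_span,
        )

    ref_pep = translate_from(t.cdna, t.cds_start, polyk_len=0).peptide
    mut_pep = tr.peptide
    if mut_pep == ref_pep:
        logger.info("%s: synonymous change, no neoORF", change.hgvs_c)
        return None
    lo = 0
    while lo < min(len(ref_pep), len(mut_pep)) and ref_pep[lo] == mut_pep[lo]:
        lo += 1
    hi = 0
    while (
        hi < min(len(ref_pep), len(mut_pep)) - lo
        and ref_pep[len(ref_pep) - 1 - hi] == mut_pep[len(mut_pep) - 1 - hi]
    ):
        hi += 1
    novel = (lo, len(mut_pep) - hi)
    if novel[0] >= novel[1]:
        if len(mut_pep) < len(ref_pep) and mut_pep == ref_pep[: len(mut_pep)]:
            logger.info("%s: pure truncation, no novel residue", change.hgvs_c)
            return None
        # clean in-frame deletion: mark the junction residue as novel context
        junction = min(novel[0], len(mut_pep) - 1)
        novel = (junction, junction + 1)
    return NeoOrf(
        orf_class="missense",
        transcript_id=t.transcript_id,
        gene_symbol=t.gene_symbol,
        hgvs_c=change.hgvs_c,
        peptide=mut_pep,
        novel_span=novel,
        stop_found=tr.stop_found,
        polyk_tail=tr.polyk_tail,
        orf_nt_span=tr.orf_nt_span,
    )


def call_neoorfs(
    t: TranscriptModel,
    change: CodingChange,
    mutation_class: str,
    polyk_len: int = DEFAULT_POLYK_LEN,
    indel_stoploss: bool = False,
) -> list[NeoOrf]:
    """Dispatch a classified change to the matching caller.

    ``stop_loss`` is SNV-only by default; ``indel_stoploss`` has no effect
    yet because the classifier only emits stop_loss for substitutions.
    """
    if mutation_class == "utr5_variant":
        return call_start_gain(t, change, polyk_len=polyk_len)
    if mutation_class == "stop_loss":
        orf = call_stop_loss(t, change, polyk_len=polyk_len)
        return [orf] if orf else []
    if mutation_class in {"missense", "frameshift"}:
        orf = call_coding(t, change, polyk_len=polyk_len)
        return [orf] if orf else []
    return []
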