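"""The neoORF engine: uAUG detection, translation rules, per-class callers."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from utrneo.neoorf import (
    apply_change,
    call_coding,
    call_start_gain,
    call_stop_loss,
    find_new_uaugs,
    kozak_strength,
    translate_from,
    wt_orf_overlap,
)
from utrneo.variants import parse_hgvs_c

STOPS = {"TAA", "TAG", "TGA"}

dna = st.text(alphabet="ACGT", min_size=3, max_size=120)


def _mt(t1, hgvs):
    return apply_change(t1, parse_hgvs_c(hgvs, t1))


# ---------------------------------------------------------------------------
# apply_change / find_new_uaugs
# ---------------------------------------------------------------------------


def test_apply_single_base_edit(t1):
    mt = _mt(t1, "c.-8C>G")
    assert mt.mut_cdna[:15] == "GGCAGATGGAGTCCA"
    assert mt.shift == 0 and len(mt.mut_cdna) == len(t1.cdna)


def test_apply_deletion_shrinks_cdna(t1):
    mt = _mt(t1, "c.7del")
    assert len(mt.mut_cdna) == 36


def test_uaug_created_by_substitution(t1):
    mt = _mt(t1, "c.-8C>G")
    assert find_new_uaugs(mt) == [5]  # c.-10
    assert t1.index_to_cpos(5) == "-10"


def test_no_uaug_when_no_atg_appears(t1):
    mt = _mt(t1, "c.-14G>A")
    assert mt.mut_cdna[:15] == "GACAGATCGAGTCCA"
    assert find_new_uaugs(mt) == []


def test_uaug_inside_inserted_bases(t1):
    mt = _mt(t1, "c.-5_-4insATG")
    assert len(find_new_uaugs(mt)) == 1


def test_preexisting_atg_shifted_by_indel_is_not_new():
    """A reference uATG moved by an upstream insertion exists in the wild type."""
    from utrneo.refmodel import TranscriptModel
    from utrneo.variants import CodingChange

    cdna = "CCATGCC" + "ATGAAATAA" + "GGG"  # reference uATG at 2
    t = TranscriptModel("TX", "G", "c", "+", ((0, len(cdna)),), cdna, 7, 16)
    change = CodingChange("ins", 1, 1, "", "TT", "utr5", "c.-7_-6insTT")
    mt = apply_change(t, change)
    assert mt.mut_cdna[4:7] == "ATG"  # still there, shifted
    assert find_new_uaugs(mt) == []


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def test_translate_direct_codons():
    tr = translate_from("ATGAAATAA", 0)
    assert (tr.peptide, tr.stop_found, tr.polyA_readthrough) == ("MK", True, False)
    assert tr.orf_nt_span == (0, 9)


def test_translate_toy_start_gain(t1):
    mt = _mt(t1, "c.-8C>G")
    tr = translate_from(mt, 5)
    assert tr.peptide == "MESNGQVS"
    assert tr.stop_found


def test_translate_polya_readthrough():
    tr = translate_from("ATGAAA", 0)
    assert tr.peptide == "MK" + "K" * 12
    assert not tr.stop_found and tr.polyA_readthrough and tr.polyk_tail == 12


def test_polyk_length_configurable():
    tr = translate_from("ATGAAA", 0, polyk_len=3)
    assert tr.peptide == "MKKKK" and tr.polyk_tail == 3


@settings(max_examples=300, derandomize=True)
@given(dna)
def test_first_stop_property(seq):
    """Translation stops exactly at the first in-frame stop codon."""
    tr = translate_from(seq, 0)
    n_coding = len(tr.peptide) - tr.polyk_tail
    codons = [seq[i : i + 3] for i in range(0, 3 * n_coding, 3)]
    assert all(c not in STOPS for c in codons)
    if tr.stop_found:
        assert seq[3 * n_coding : 3 * n_coding + 3] in STOPS
    else:
        assert all(
            seq[i : i + 3] not in STOPS for i in range(0, len(seq) - 2, 3)
        )
    assert tr.stop_found == (tr.polyk_tail == 0)
    assert tr.stop_found != tr.polyA_readthrough


# ---------------------------------------------------------------------------
# per-class callers on the toy transcript
# ---------------------------------------------------------------------------


def test_call_start_gain_toy(t1):
    (orf,) = call_start_gain(t1, parse_hgvs_c("c.-8C>G", t1))
    assert orf.peptide == "MESNGQVS"
    assert orf.novel_span == (0, 8)
    assert orf.stop_found
    assert orf.uaug_cpos == "c.-10"
    assert orf.kozak == "moderate"
    assert orf.cds_overlap_fraction == pytest.approx(12 / 27)
    assert orf.inframe_cds is False
    assert orf.wt_uorf_overlap is False


def test_call_start_gain_empty(t1):
    assert call_start_gain(t1, parse_hgvs_c("c.-14G>A", t1)) == []


def test_call_stop_loss_toy(t1):
    orf = call_stop_loss(t1, parse_hgvs_c("c.10T>C", t1))
    assert orf.peptide == "MAKQASI" + "K" * 12
    assert orf.novel_span == (3, 19)
    assert not orf.stop_found


def test_call_stop_loss_stop_to_stop_is_none(t1):
    assert call_stop_loss(t1, parse_hgvs_c("c.11A>G", t1)) is None


def test_stop_loss_immediate_stop_gives_one_residue():
    from utrneo.refmodel import TranscriptModel
    from utrneo.variants import parse_hgvs_c as parse

    cdna = "GG" + "ATGAAATAA" + "TAAGGCC"  # 3'UTR starts with in-frame TAA
    t = TranscriptModel("TX", "G", "c", "+", ((0, len(cdna)),), cdna, 2, 11)
    orf = call_stop_loss(t, parse("c.7T>C", t))
    assert orf.peptide == "MKQ"
    assert orf.novel_span == (2, 3)
    assert orf.stop_found


def test_call_missense_toy(t1):
    orf = call_coding(t1, parse_hgvs_c("c.5C>T", t1))
    assert orf.orf_class == "missense"
    assert orf.peptide == "MVK"
    assert orf.novel_span == (1, 2)


def test_call_frameshift_toy(t1):
    orf = call_coding(t1, parse_hgvs_c("c.7del", t1))
    assert orf.orf_class == "frameshift"
    assert orf.peptide == "MASKLAS" + "K" * 12
    assert orf.novel_span == (2, 19)
    assert not orf.stop_found


def test_synonymous_returns_none(t1):
    assert call_coding(t1, parse_hgvs_c("c.6C>T", t1)) is None


# ---------------------------------------------------------------------------
# Kozak and overlap annotations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "context, expected",
    [
        ("GCCACCATGG", "strong"),  # A at -3, G at +4
        ("GCCTCCATGA", "weak"),
        ("GCCTCCATGG", "moderate"),
        ("GCCGCCATGA", "moderate"),
    ],
)
def test_kozak_rule(context, expected):
    from utrneo.refmodel import TranscriptModel
    from utrneo.variants import CodingChange

    cdna = context + "ATGAAATAA"
    t = TranscriptModel("TX", "G", "c", "+", ((0, len(cdna)),), cdna, len(context), len(cdna))
    mt = apply_change(t, CodingChange("sub", 0, 1, cdna[0], "T" if cdna[0] != "T" else "C", "utr5"))
    assert kozak_strength(mt, 6) == expected


def test_kozak_moderate_on_toy(t1):
    mt = _mt(t1, "c.-8C>G")
    assert kozak_strength(mt, 5) == "moderate"


def test_kozak_missing_context_counts_unmet():
    from utrneo.refmodel import TranscriptModel
    from utrneo.variants import CodingChange

    cdna = "ATGGAAATGAAATAA"  # uATG at 0: no -3 base, +4 is G
    t = TranscriptModel("TX", "G", "c", "+", ((0, len(cdna)),), cdna, 6, 15)
    mt = apply_change(t, CodingChange("sub", 4, 5, "A", "C", "utr5"))
    assert kozak_strength(mt, 0) == "moderate"


def test_inframe_cds_overlap():
    """A neoORF starting a multiple of 3 upstream of the CDS reads in frame."""
    from utrneo.refmodel import TranscriptModel
    from utrneo.variants import parse_hgvs_c as parse

    cdna = "CCCATTGGG" + "ATGAAATAA" + "CC"
    t = TranscriptModel("TX", "G", "c", "+", ((0, len(cdna)),), cdna, 9, 18)
    (orf,) = call_start_gain(t, parse("c.-4T>G", t))  # ATT -> ATG, uATG at -6
    assert orf.uaug_cpos == "c.-6"
    assert orf.inframe_cds is True
    assert orf.cds_overlap_fraction == pytest.approx(9 / 15)


def test_wt_uorf_overlap_flag():
    from utrneo.refmodel import TranscriptModel
    from utrneo.variants import parse_hgvs_c as parse

    # reference uORF opened at utr5 position 0 runs into the CDS; the new
    # uAUG at -9 falls inside that span, so the flag must be set
    cdna = "ATGCCCTTGCCACCA" + "ATGAAATAA" + "CC"
    t = TranscriptModel("TX", "G", "c", "+", ((0, len(cdna)),), cdna, 15, 24)
    (orf,) = call_start_gain(t, parse("c.-9T>A", t))  # TTG -> ATG at utr5 index 6
    assert orf.uaug_cpos == "c.-9"
    assert orf.wt_uorf_overlap is True


def test_wt_uorf_false_when_reference_has_no_atg(t1):
    (orf,) = call_start_gain(t1, parse_hgvs_c("c.-8C>G", t1))
    assert orf.wt_uorf_overlap is False


# ---------------------------------------------------------------------------
# engine-wide properties
# ---------------------------------------------------------------------------


def test_start_gain_peptides_begin_with_m(random_bundle, toy_scan):
    for orf in toy_scan["neoorfs"]:
        if orf.orf_class == "start_gain":
            assert orf.peptide.startswith("M")
            assert orf.novel_span == (0, len(orf.peptide))


def test_strand_mirror_records_identical(toy_scan):
    """Mirrored minus-strand fixtures give identical records bar the ids."""
    plus = [o for o in toy_scan["neoorfs"] if o.transcript_id == "T1"]
    minus = [o for o in toy_scan["neoorfs"] if o.transcript_id == "T1M"]
    strip = lambda o: (o.orf_class, o.hgvs_c, o.uaug_cpos, o.peptide, o.novel_span,
                       o.stop_found, o.kozak, o.cds_overlap_fraction, o.inframe_cds,
                       o.wt_uorf_overlap)
    assert [strip(o) for o in plus] == [strip(o) for o in minus]


def test_output_ordering_deterministic(toy_bundle, tmp_path):
    from utrneo.cli import RunConfig, run_scan

    runs = []
    for i in range(2):
        res = run_scan(toy_bundle.vcf, toy_bundle.genome, toy_bundle.gtf,
                       toy_bundle.proteome, tmp_path / f"o{i}", RunConfig(), sample="s")
        runs.append([(n.sort_key(), n.peptide) for n in res["neoorfs"]])
    assert runs[0] == runs[1]
    assert runs[0] == sorted(runs[0])
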