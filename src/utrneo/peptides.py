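"""Neopeptide post-processing: MHC-input k-mers, tryptic peptides, filters, output files.

Each neoORF is expanded by a sliding window into 9-, 10- and 11-mers that
contain at least one mutated/frameshifted residue; these are the inputs
for an external MHC class I binding predictor (netMHCpan via pVACbind or
similar). Binding output is filtered at IC50 < 500 nM (strict), and
start-gain k-mers with exact matches in the canonical proteome are
removed to exclude in-frame overlap with coding isoforms. Fully tryptic
peptides with up to one missed cleavage are emitted for proteogenomic MS
searches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from utrneo.neoorf import NeoOrf

logger = logging.getLogger(__name__)

DEFAULT_KMER_LENGTHS = (9, 10, 11)
DEFAULT_IC50_NM = 500.0

TSV_COLUMNS = [
    "sample",
    "class",
    "gene",
    "transcript",
    "hgvs_c",
    "uaug_cpos",
    "peptide",
    "novel_span",
    "stop_found",
    "kozak",
    "cds_overlap_fraction",
    "inframe_cds",
    "wt_uorf_overlap",
]


@dataclass(frozen=True)
class KmerRecord:
    sequence: str
    source: NeoOrf
    window_offset: int  # residue index in the parent peptide
    header_id: str


@dataclass(frozen=True)
class BindingRecord:
    kmer: str
    allele: str
    ic50: float


# ---------------------------------------------------------------------------
# k-mer windows
# ---------------------------------------------------------------------------


def kmer_windows(
    n: NeoOrf,
    lengths: tuple[int, ...] = DEFAULT_KMER_LENGTHS,
    sample: str = "",
    include_polyk: bool = False,
) -> list[KmerRecord]:
    """Sliding-window k-mers of the neoORF overlapping its novel span.

    The poly-lysine read-through tail is excluded by default: its length is
    an artefact parameter, not sequence evidence. K-mers are deduplicated
    by sequence within one neoORF.
    """
    effective_len = len(n.peptide) - (0 if include_polyk else n.polyk_tail)
    novel_lo, novel_hi = n.novel_span
    novel_hi = min(novel_hi, effective_len)
    records: list[KmerRecord] = []
    seen: set[str] = set()
    for L in sorted(lengths):
        for start in range(0, effective_len - L + 1):
            end = start + L
            if end <= novel_lo or start >= novel_hi:
                continue
            seq = n.peptide[start:end]
            if seq in seen:
                continue
            seen.add(seq)
            header = f"{sample}|{n.orf_class}|{n.transcript_id}|{n.hgvs_c}|{start}|{L}"
            records.append(KmerRecord(sequence=seq, source=n, window_offset=start, header_id=header))
    return records


def proteome_filter(
    kmers: list[KmerRecord], proteome: list[str] | set[str]
) -> list[KmerRecord]:
    """Drop k-mers occurring verbatim inside any canonical protein."""
    proteins = [p for p in proteome if p]
    if not proteins:
        logger.warning("empty canonical proteome: filter is a no-op")
        return list(kmers)
    blob = "\x00".join(proteins)  # NUL separators prevent cross-protein matches
    return [k for k in kmers if k.sequence not in blob]


def load_proteome_fasta(path: str | Path) -> list[str]:
    """Protein sequences from a FASTA file (stops stripped)."""
    from Bio import SeqIO

    return [str(rec.seq).rstrip("*") for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Tryptic peptides
# ---------------------------------------------------------------------------


def _cleavage_sites(seq: str) -> list[int]:
    """Indices after which trypsin cleaves (after K/R, not before P)."""
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]


def tryptic_peptides(n: NeoOrf, include_polyk: bool = False) -> list[str]:
    """Fully tryptic peptides (0 or 1 missed cleavage) covering the novel span.

    For classes with canonical flanking residues the flanks in
    ``n.peptide`` give the proteogenomic search context; a start-gain
    neoORF has no canonical flank, so its own digest is returned.
    """
    seq = n.peptide if include_polyk else n.peptide[: len(n.peptide) - n.polyk_tail]
    if not seq:
        return []
    novel_lo, novel_hi = n.novel_span
    novel_hi = min(novel_hi, len(seq))
    bounds = [0] + _cleavage_sites(seq) + [len(seq)]
    out: list[str] = []
    for missed in (0, 1):
        for i in range(len(bounds) - 1 - missed):
            lo, hi = bounds[i], bounds[i + 1 + missed]
            if hi > novel_lo and lo < novel_hi:
                pep = seq[lo:hi]
                if pep not in out:
                    out.append(pep)
    return out


# ---------------------------------------------------------------------------
# Binding-output filtering (external predictor results)
# ---------------------------------------------------------------------------


def read_binding_tsv(
    path: str | Path,
    kmer_col: str = "Epitope Seq",
    allele_col: str = "HLA Allele",
    ic50_col: str = "IC50",
) -> list[BindingRecord]:
    """Parse an externally produced binding-prediction table (pVACbind-style)."""
    df = pd.read_csv(path, sep="\t")
    lowered = {c.lower(): c for c in df.columns}

    def pick(preferred: str, *fallbacks: str) -> str:
        for cand in (preferred, *fallbacks):
            if cand in df.columns:
                return cand
            if cand.lower() in lowered:
                return lowered[cand.lower()]
        raise ValueError(f"binding TSV lacks a {preferred!r} column (have {list(df.columns)})")

    kc = pick(kmer_col, "peptide", "kmer")
    ac = pick(allele_col, "allele", "hla")
    ic = pick(ic50_col, "ic50 mt", "ic50_nm")
    records = []
    for _, row in df.iterrows():
        try:
            ic50 = float(row[ic])
        except (TypeError, ValueError):
            logger.warning("non-numeric IC50 %r skipped", row[ic])
            continue
        records.append(BindingRecord(kmer=str(row[kc]), allele=str(row[ac]), ic50=ic50))
    return records


def binding_filter(
    records: list[BindingRecord], threshold: float = DEFAULT_IC50_NM
) -> list[BindingRecord]:
    """Keep predicted binders with IC50 strictly below ``threshold`` nM."""
    return [r for r in records if r.ic50 < threshold]


# ---------------------------------------------------------------------------
# Burden summary
# ---------------------------------------------------------------------------


def summarize_burden(
    neoantigens_by_class: dict[str, int], mutations_by_class: dict[str, int]
) -> pd.DataFrame:
    """Per-class mutation count, neoantigen count and neoantigens/mutation."""
    classes = sorted(set(neoantigens_by_class) | set(mutations_by_class))
    rows = []
    for cls in classes:
        n_mut = mutations_by_class.get(cls, 0)
        n_neo = neoantigens_by_class.get(cls, 0)
        rows.append(
            {
                "class": cls,
                "n_mut": n_mut,
                "n_neo": n_neo,
                "neo_per_mut": n_neo / n_mut if n_mut else 0.0,
                "undefined_ratio": n_mut == 0,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_mut", "n_neo", "neo_per_mut", "undefined_ratio"])


# ---------------------------------------------------------------------------
# Output streams
# ---------------------------------------------------------------------------


def _tsv_row(sample: str, n: NeoOrf) -> dict:
    return {
        "sample": sample,
        "class": n.orf_class,
        "gene": n.gene_symbol,
        "transcript": n.transcript_id,
        "hgvs_c": n.hgvs_c,
        "uaug_cpos": n.uaug_cpos or "NA",
        "peptide": n.peptide,
        "novel_span": f"{n.novel_span[0] + 1}-{n.novel_span[1]}",
        "stop_found": n.stop_found,
        "kozak": n.kozak,
        "cds_overlap_fraction": (
            "NA" if n.cds_overlap_fraction is None else f"{n.cds_overlap_fraction:.4f}"
        ),
        "inframe_cds": "NA" if n.inframe_cds is None else n.inframe_cds,
        "wt_uorf_overlap": "NA" if n.wt_uorf_overlap is None else n.wt_uorf_overlap,
    }


def write_outputs(
    sample: str,
    neoorfs: list[NeoOrf],
    outdir: str | Path,
    lengths: tuple[int, ...] = DEFAULT_KMER_LENGTHS,
    proteome: list[str] | None = None,
    proteome_filter_all: bool = False,
    include_polyk: bool = False,
    log_lines: list[str] | None = None,
) -> dict[str, Path]:
    """Write the per-sample output streams.

    Per sample: one TSV per mutation class (header-only when empty), a
    k-mer FASTA for MHC-binding prediction, a tryptic-peptide FASTA for
    proteogenomic searches, and a log file. Returns the paths written.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / f".{sample}.write-test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    neoorfs = sorted(neoorfs, key=lambda n: n.sort_key())
    paths: dict[str, Path] = {}
    for cls in ("start_gain", "stop_loss", "frameshift", "missense"):
        rows = [_tsv_row(sample, n) for n in neoorfs if n.orf_class == cls]
        df = pd.DataFrame(rows, columns=TSV_COLUMNS)
        path = outdir / f"{sample}.{cls}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[f"tsv_{cls}"] = path

    kmer_path = outdir / f"{sample}.kmers.fasta"
    seen_kmers: set[tuple[str, str]] = set()  # unique per (class, sequence) per sample
    with open(kmer_path, "w") as fh:
        for n in neoorfs:
            kmers = kmer_windows(n, lengths=lengths, sample=sample, include_polyk=include_polyk)
            if proteome is not None and (n.orf_class == "start_gain" or proteome_filter_all):
                kmers = proteome_filter(kmers, proteome)
            for k in kmers:
                key = (n.orf_class, k.sequence)
                if key in seen_kmers:
                    continue
                seen_kmers.add(key)
                fh.write(f">{k.header_id}\n{k.sequence}\n")
    paths["kmers"] = kmer_path

    tryptic_path = outdir / f"{sample}.tryptic.fasta"
    with open(tryptic_path, "w") as fh:
        for n in neoorfs:
            for i, pep in enumerate(tryptic_peptides(n, include_polyk=include_polyk)):
                fh.write(f">{sample}|{n.orf_class}|{n.transcript_id}|{n.hgvs_c}|tryptic{i}\n{pep}\n")
    paths["tryptic"] = tryptic_path

    log_path = outdir / f"{sample}.log"
    counts = pd.Series([n.orf_class for n in neoorfs]).value_counts() if neoorfs else {}
    with open(log_path, "w") as fh:
        fh.write(f"sample\t{sample}\n")
        for cls in ("start_gain", "stop_loss", "frameshift", "missense"):
            fh.write(f"neoorfs_{cls}\t{counts.get(cls, 0) if len(counts) else 0}\n")
        fh.write(f"kmers_emitted\t{len(seen_kmers)}\n")
        for line in log_lines or []:
            fh.write(line.rstrip("\n") + "\n")
    paths["log"] = log_path
    return paths
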