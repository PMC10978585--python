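"""Probability of start-gain formation per mutational signature.

For a single-base-substitution (SBS) signature giving probabilities over
the 96 pyrimidine-centred trinucleotide classes, the probability that a
substitution drawn from the signature creates a new uAUG in a 5'UTR
collection is

    P(start-gain | signature) = sum_s p(s) * n_gain(s) / n_total(s)

where, over every 5'UTR site and every possible single-base change,
``n_total(s)`` counts sites carrying class ``s`` and ``n_gain(s)`` counts
those where that change creates an ATG triplet that was not there before.
Classes absent from the collection contribute zero. The neutral baseline
uses the uniform signature p(s) = 1/96.

The 5'UTR collection should be genomically merged (overlapping transcript
UTRs unioned) so each genomic site counts once. Trinucleotide context is
taken from the transcript sequence itself; boundary positions without a
one-base flank are skipped (counted and logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 classes in COSMIC order: substitution-major, context alphabetical
SBS96_CLASSES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)
_CLASS_SET = set(SBS96_CLASSES)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sbs_class_of(tri: str, alt: str) -> str | None:
    """COSMIC SBS-96 class of a substitution given its trinucleotide context.

    ``tri`` is the 3-mer centred on the mutated base. Purine-centred
    contexts are reverse-complemented (together with ``alt``) onto the
    pyrimidine strand. Returns None when any base is not ACGT.
    """
    if len(tri) != 3 or set(tri + alt) - set("ACGT"):
        return None
    centre = tri[1]
    if centre == alt:
        return None
    if centre in "AG":
        tri = _revcomp(tri)
        alt = _revcomp(alt)
        centre = tri[1]
    return f"{tri[0]}[{centre}>{alt}]{tri[2]}"


@dataclass(frozen=True)
class SignatureProfile:
    """A named probability distribution over the 96 SBS classes."""

    name: str
    p: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.p) - _CLASS_SET
        if unknown:
            raise ValueError(f"unknown SBS classes in signature {self.name}: {sorted(unknown)[:3]}")
        total = sum(self.p.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signature {self.name} probabilities sum to {total}, expected 1")
        if any(v < 0 for v in self.p.values()):
            raise ValueError(f"signature {self.name} has negative probabilities")

    @classmethod
    def uniform(cls, name: str = "neutral") -> "SignatureProfile":
        return cls(name=name, p={s: 1.0 / 96 for s in SBS96_CLASSES})


@dataclass
class SbsTally:
    """Per-class counts of uAUG-creating vs. all possible 5'UTR substitutions."""

    n_gain: dict[str, int]
    n_total: dict[str, int]
    skipped_boundary_positions: int = 0

    def __post_init__(self) -> None:
        for s, g in self.n_gain.items():
            if g > self.n_total.get(s, 0):
                raise ValueError(f"class {s}: n_gain {g} exceeds n_total {self.n_total.get(s, 0)}")


def tally_uaug_sites(utr5_collection: Iterable[str]) -> SbsTally:
    """Enumerate every possible single-base substitution over the collection.

    For each interior position (both flanking bases present) and each of
    the three alternative bases: the site's SBS class total is
    incremented, and its gain count too when any of the three triplets
    containing the position becomes exactly ATG without having been ATG
    before the change.
    """
    n_gain = {s: 0 for s in SBS96_CLASSES}
    n_total = {s: 0 for s in SBS96_CLASSES}
    skipped = 0
    for seq in utr5_collection:
        seq = seq.upper()
        length = len(seq)
        skipped += min(length, 2)  # first and last base lack a flank
        for i in range(1, length - 1):
            tri = seq[i - 1 : i + 2]
            ref = seq[i]
            for alt in "ACGT":
                if alt == ref:
                    continue
                cls = sbs_class_of(tri, alt)
                if cls is None:
                    continue
                n_total[cls] += 1
                if _creates_atg(seq, i, alt):
                    n_gain[cls] += 1
    if skipped:
        logger.debug("%d boundary positions lacked a flank and were skipped", skipped)
    return SbsTally(n_gain=n_gain, n_total=n_total, skipped_boundary_positions=skipped)


def _creates_atg(seq: str, i: int, alt: str) -> bool:
    """True iff substituting seq[i] -> alt turns any covering triplet into a new ATG."""
    for j in (i - 2, i - 1, i):
        if j < 0 or j + 3 > len(seq):
            continue
        before = seq[j : j + 3]
        after = before[: i - j] + alt + before[i - j + 1 :]
        if after == "ATG" and before != "ATG":
            return True
    return False


def startgain_probability(sig: SignatureProfile, tally: SbsTally) -> float:
    """Signature-weighted average of per-class uAUG-creation rates."""
    total = 0.0
    for s in SBS96_CLASSES:
        n_tot = tally.n_total.get(s, 0)
        if n_tot == 0:
            continue
        total += sig.p.get(s, 0.0) * tally.n_gain.get(s, 0) / n_tot
    return total


def neutral_baseline(tally: SbsTally) -> float:
    """Start-gain probability under the uniform (neutral) signature."""
    return startgain_probability(SignatureProfile.uniform(), tally)


# ---------------------------------------------------------------------------
# Signature matrix I/O
# ---------------------------------------------------------------------------


def read_signature_matrix(path: str | Path) -> list[SignatureProfile]:
    """Read signatures from a 96-row TSV.

    Accepts the COSMIC v1 layout (``Substitution Type`` /
    ``Trinucleotide`` / ``Somatic Mutation Type`` label columns followed
    by one column per signature) or any TSV with one column of
    ``X[R>A]Y`` labels; a single unlabelled numeric column is taken in
    canonical class order. Columns are renormalised to sum exactly to 1
    (logged if off by more than 1e-6).
    """
    df = pd.read_csv(path, sep="\t")
    label_col = None
    for col in df.columns:
        values = df[col].astype(str)
        if values.isin(_CLASS_SET).all():
            label_col = col
            break
    if label_col is None and {"Substitution Type", "Trinucleotide"} <= set(df.columns):
        df["_label"] = [
            f"{tri[0]}[{sub}]{tri[2]}"
            for sub, tri in zip(df["Substitution Type"], df["Trinucleotide"])
        ]
        label_col = "_label"
    if label_col is None:
        numeric = df.select_dtypes("number")
        if len(df) == 96 and numeric.shape[1] >= 1:
            df["_label"] = list(SBS96_CLASSES)
            label_col = "_label"
        else:
            raise ValueError(f"{path}: cannot locate SBS-96 class labels")
    if len(df) != 96 or df[label_col].nunique() != 96:
        raise ValueError(f"{path}: expected 96 unique SBS classes, found {df[label_col].nunique()}")

    profiles = []
    for col in df.columns:
        if col == label_col or not pd.api.types.is_numeric_dtype(df[col]):
            continue
        p = dict(zip(df[label_col], df[col].astype(float)))
        total = sum(p.values())
        if total <= 0:
            logger.warning("signature column %r sums to %s; skipped", col, total)
            continue
        if abs(total - 1.0) > 1e-6:
            logger.info("signature column %r renormalised from sum %.6f", col, total)
        p = {k: v / total for k, v in p.items()}
        profiles.append(SignatureProfile(name=str(col), p=p))
    if not profiles:
        raise ValueError(f"{path}: no numeric signature columns found")
    return profiles
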