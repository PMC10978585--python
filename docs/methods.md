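# Methods

## Scope and model

`utrneo` predicts candidate neopeptides created by somatic mutations in
and around the untranslated regions of protein-coding transcripts. The
biological premise: a 5'UTR substitution or short indel can create a new
upstream ATG (uAUG) that opens a novel reading frame absent from the
wild-type proteome, and a stop-codon substitution to a sense codon makes
the ribosome read through into the 3'UTR. Both produce peptides that are
tumour-specific by construction, making them attractive immunotherapy
targets alongside classical missense/frameshift neoantigens.

The package does not model whether translation actually initiates at a
new uAUG — that depends on initiation context and is delegated to
external translation-initiation-site predictors. It reports the Kozak
context and overlap annotations needed to prioritise candidates, and
emits predictor-ready inputs; MHC binding prediction itself is external,
and only its output table is filtered here.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open; GTF (1-based closed) and
VCF POS (1-based) are converted only at the I/O boundary in `refmodel`.
Transcript models are strand-aware: the cDNA is the sense-strand spliced
sequence, so all downstream logic is strand-free and mirrored
minus-strand genes give byte-identical calls (asserted in the tests).
Ensembl GTFs keep the stop codon in separate `stop_codon` features; the
loader merges them into the CDS span so `cds_end` sits 3' of the stop,
which the stop-loss caller requires. Transcript version suffixes are
stripped on load and lookup. Transcripts whose CDS is not a multiple of
3 or does not begin ATG are loaded but flagged, since public annotation
contains such models.

HGVS c. support covers substitutions, del, ins, dup and delins on the
spliced cDNA; intronic offsets are rejected explicitly because the
method operates on mature mRNA. A stated reference base is always
verified against the transcript; mismatches are hard errors rather than
silent re-anchoring. Duplications are applied as insertions of the
duplicated bases at the 3' end of the duplicated span — an equivalent
mutant sequence.

## Classification

Classes are recomputed from `(cdna, change)` alone; the VEP consequence
string is only a cross-check (logged when it disagrees). This makes the
final-codon override automatic: any SNV inside the annotated stop codon
that yields a sense codon is stop-loss, whatever the annotation said.
Stop→stop exchanges alter no residue and are classed `other`. CDS indels
shift-divisible-by-3 are missense (grouped with SNVs/DNVs), otherwise
frameshift. Changes spanning the UTR/CDS boundary — including insertions
exactly at the junction, which are judged by both flanking bases — are
classed `other` and logged rather than guessed. Indels longer than 50 nt
are outside the "short indel" scope and skipped with a warning.

## uAUG novelty

After applying a change, positions outside the replaced span map 1:1
onto reference positions. A mutant 5'UTR ATG is *new* iff its three
bases do not map onto three consecutive unchanged reference positions:
this covers substituted bases, inserted bases, and triplets straddling a
deletion junction, while excluding reference ATGs merely shifted by an
upstream indel (those exist in the wild-type mRNA and are not
tumour-specific). Each new uAUG yields an independent neoORF. An ATG
created at a locus whose previous ATG was destroyed still counts as a
gain at the created triplet.

## Translation rules

Translation is codon-by-codon with the standard nuclear code, stopping
before the first in-frame TAA/TAG/TGA. If the transcript end is reached
without a stop, the frame is treated as reading through to the poly-A
tail; a poly-lysine tail is appended (default 12 K, `--polyk-len`) and
the event flagged, so consumers can drop the artefactual tail — it is
excluded from k-mers and tryptic peptides by default. A trailing 1–2 nt
partial codon is discarded. TGA is always a stop (no selenocysteine
read-through). Stop-loss peptides retain the full canonical protein as
flanking context with the novel span starting at the former stop
position; frameshift peptides likewise retain the canonical prefix, with
the novel span starting at the first codon containing a changed base.

## Start-gain annotations

Kozak strength follows the two-criterion convention: purine at −3 and G
at +4 relative to the A of the ATG (+1). Both met → strong, one →
moderate, none → weak; a criterion whose position falls outside the
transcript counts as unmet (no evidence cannot be strong). CDS overlap
is reported as the nucleotide fraction of the neoORF span (stop
included) inside the canonical CDS — the overlap metric is a design
choice, documented as such — plus a frame-congruence flag and a flag for
intersection with any ORF opened by a reference 5'UTR ATG under the same
translation rules.

## Peptide emission and filters

Sliding windows of 9/10/11 residues overlapping the novel span by ≥1
residue are emitted per neoORF, deduplicated by sequence within a neoORF
and per (sample, class, sequence) in the FASTA output. Start-gain k-mers
with exact substring matches in the canonical proteome are removed
(other classes opt-in via `--proteome-filter-all`), excluding in-frame
overlap with coding isoforms. Tryptic peptides cleave after K/R not
followed by P, returning every fully tryptic peptide covering the novel
span with 0 or 1 missed cleavages. Externally produced binding tables
are filtered at IC50 strictly below 500 nM (configurable); burden
summaries report neoantigens-per-mutation per class.

## Signature probability

`P(start-gain | signature) = Σ_s p(s) · n_gain(s)/n_total(s)` over the
96 pyrimidine-centred SBS classes, with classes absent from the 5'UTR
collection contributing zero and the neutral baseline using the uniform
signature. The 5'UTR collection is assumed genomically merged so sites
count once. Trinucleotide context is taken from the transcript sequence;
boundary positions lacking a one-base flank are skipped and counted —
taking flanks from the genome instead would shift counts marginally and
is a documented divergence risk. Transcriptional strand asymmetry is
ignored, matching the use of stock COSMIC profiles.

## Synthetic fixtures and what they show

The fixture generator emits a mini-genome, Ensembl-dialect GTF,
VEP-style VCF, proteome and truth table. Expected outcomes come from an
embedded naive oracle (explicit provenance lists, Biopython whole-frame
translation) that shares no code with the engine, so the engine cannot
validate itself. Fixtures cover both strands, spliced transcripts, every
mutation class, deliberately mislabelled consequences and a non-PASS
record. They emulate the structural features of real data — not its
scale, UTR length distribution, GC content, multi-isoform overlap or
annotation noise — so passing tests demonstrate correctness of the
calling logic, not performance or recall on human genomes. Problem sizes
used by the default suite and the acceptance script (tens of transcripts,
a few hundred spiked variants, 1000 random translation sequences, 100k
Monte-Carlo draws) were chosen to give tight oracle comparisons at
desk scale.

## Numerical and degenerate-input choices

Output ordering is deterministic (transcript, HGVS, class, uAUG
position). The k-mer/window logic and tallies are exact integer
computations; the only stochastic check is the Monte-Carlo oracle,
compared within 3 standard errors. Degenerate inputs: empty VCFs produce
header-only outputs; an empty proteome makes the filter a pass-through
with a warning; synonymous changes and pure truncations return no
neoORF; a clean in-frame codon deletion with no residue substitution
marks the junction residue as novel context so the junction k-mers are
still emitted.

## Known limitations

No phasing (variants applied one at a time); no near-cognate (non-AUG)
start codons; no nonsense-mediated-decay or expression modelling;
stop-loss is SNV-only by default; VEP CSQ/ANN is the only annotation
dialect; GFF3 variants beyond Ensembl GTF are unsupported.
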