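# utrneo

Neoantigen discovery from the untranslated regions (UTRs) of tumour
genomes. `utrneo` calls four classes of neopeptide from VEP-annotated
somatic variant calls — **start-gain** (a 5'UTR mutation creating a new
upstream ATG and opening a novel upstream open reading frame, a neoORF),
**stop-loss** (the annotated stop codon mutated to a sense codon, reading
through into the 3'UTR), **frameshift** and **missense** — and emits the
inputs an MHC class I binding predictor (e.g. netMHCpan via pVACbind)
and a proteogenomic MS search pipeline need to screen them.

It is aimed at cancer-immunology bioinformaticians who already have
somatic VCFs annotated with Ensembl VEP (`--hgvs`) and want to extend
their neoantigen search beyond the coding sequence.

## Method

For each PASS variant and each annotated transcript, the HGVS c. string
is resolved on the spliced cDNA and the variant classified from the
sequence alone (VEP consequence terms are only cross-checked, so a
mislabelled final-codon SNV is still recovered as stop-loss):

- **start-gain** — every net-new ATG in the mutant 5'UTR is translated
  5'→3' until the first in-frame stop (TAA/TAG/TGA). Each neoORF carries
  a Kozak strength (strong: purine at −3 *and* G at +4; moderate: one;
  weak: neither), its nucleotide overlap fraction with the canonical
  CDS, an in-frame-overlap flag, and whether it intersects a wild-type
  uORF already present in the reference 5'UTR.
- **stop-loss** — translation continues from the new sense codon through
  the 3'UTR until a stop.
- **frameshift / missense** — mutant CDS translation in the shifted or
  preserved frame; in-frame SNVs/DNVs/indels are grouped as missense.
- Frames reaching the transcript end without a stop are read through to
  the poly-A tail, modelled as a flagged poly-lysine tail (default 12 K).

Every neopeptide is expanded into 9/10/11-mers containing ≥1 mutated
residue (the MHC-predictor input), plus fully tryptic peptides with ≤1
missed cleavage for MS searches. Start-gain k-mers with exact matches in
the canonical proteome are removed; externally produced binding tables
are filtered at IC50 < 500 nM.

Separately, for a COSMIC SBS-96 mutational-signature profile `p(s)` the
probability of start-gain formation over a 5'UTR collection is

    P = Σ_s p(s) · n_gain(s) / n_total(s)

where `n_total(s)` counts 5'UTR sites carrying class `s` and `n_gain(s)`
those where that substitution creates a new ATG; the neutral baseline
uses `p(s) = 1/96`.

## Worked example

```bash
utrneo fixtures --out demo            # write the builtin synthetic bundle
utrneo peptide --transcript T1 --hgvs 'c.-8C>G' \
    --genome demo/genome.fa --gtf demo/annotation.gtf
```

prints

```
start_gain	T1	c.-8C>G	c.-10	MESNGQVS	novel=1-8	stop_found=True	kozak=moderate
```

i.e. the substitution at c.-8 creates a new uATG at c.-10 in moderate
Kozak context, opening an 8-residue neoORF (`MESNGQVS`) that terminates
at an in-frame stop. The whole-VCF equivalent:

```bash
utrneo scan --vcf demo/variants.vcf --genome demo/genome.fa \
    --gtf demo/annotation.gtf --proteome demo/proteome.fa --out demo/out
```

writes, per sample, one TSV per mutation class, a k-mer FASTA
(`<sample>.kmers.fasta`) ready for MHC binding prediction, a tryptic
FASTA and a log, and prints the per-class burden table:

```
     class  n_mut  n_neo  neo_per_mut  undefined_ratio
frameshift      2      2          1.0            False
  missense      4      2          0.5            False
start_gain      4      2          0.5            False
 stop_loss      2      2          1.0            False
```

(the toy VCF spikes each variant on both a plus-strand transcript and
its minus-strand mirror, hence the even counts; the missense class
includes one synonymous control per strand that yields no neopeptide)

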