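# ambicode

Analysis toolkit for **ambiguous genetic codes** — nuclear codes, known from
heterotrich and karyorelict ciliates, in which all 64 codons are translated
as standard amino acids (UAA/UAG = glutamine, UGA = tryptophan) and yet the
same triplets terminate translation near mRNA 3′ ends. The package
reimplements, as a tested reusable pipeline, the computational analyses
behind such discoveries:

1. **Genetic-code inference** from profile-alignment evidence: transcripts
   are translated in all six frames with the standard code (stops recorded
   as `X`), protein-family profiles are aligned against the translations,
   and every well-conserved aligned column contributes one (consensus amino
   acid *j*, underlying codon *i*) pair. After filtering (conditional
   e-value < 10⁻¹⁰, column conservation ≥ 50%) the pairs form a count
   matrix *m*ᵢⱼ (64 codons × 20 amino acids). The per-amino-acid
   normalization *M*ᵢⱼ = *m*ᵢⱼ / Σᵢ *m*ᵢⱼ is exported for sequence logos;
   codon calls use per-codon shares, a codon's meaning being its
   maximal-share amino acid (with support and ambiguity-margin guards).
2. **Poly(A)-anchored transcript-end analysis**: terminal-tail detection,
   the *primary stop* (most 5′ in-frame candidate stop in the 60-nt window
   upstream of the poly(A) site), 3′UTR lengths excluding stop and tail,
   positional codon counts toward the tail (final codons may borrow 0/1/2
   tail adenosines), and a binomial proximal-vs-distal depletion test for
   candidate stop codons in the −90..−42 nt window.
3. **Ribosome-profiling termination evidence**: footprint filtering
   (25–32 nt, ≤1 mismatch, primary alignments), frame and length
   distributions, 3′-end metaprofiles around sense and stop codons, the
   11/12-nt termination signature, and per-transcript readthrough
   (footprints extending ≥13 nt past the primary stop over
   termination-signature footprints), with cohort mean/median summaries.
4. **Evolutionary checks**: pairwise Nei–Gojobori (1986) dN/dS with
   Jukes–Cantor correction, evaluated under any code table (so synonymy is
   reassignment-aware), stop-codon-usage summaries, and
   4-fold-degenerate-site composition with the UAA-usage regression.
5. **A ground-truth simulator** (`ambicode.simulate`) that emulates every
   data layer above — protein families with conserved columns, coding
   sequences under any variant code with rare sense-"stop" usage and
   configurable proximal suppression, AU-rich median-22-nt 3′UTRs
   (including 0-length ones), poly(A) tails, and footprints with the
   terminating/readthrough geometry — so the whole pipeline is testable
   without downloads.

Intended users: people analysing transcriptomes or ribo-seq from organisms
with (suspected) non-standard codes, and anyone needing a controlled
test-bed for stop-codon-reassignment methods.

## Worked example

Simulate an ambiguous-code cohort and infer its genetic code:

```bash
ambicode simulate --preset ambiguous-cmag --seed 3 --n-transcripts 400 --out sim
ambicode infer-code --records sim/alignment_records.tsv --out infer
ambicode ends  --fasta sim/transcripts.fasta --truth sim/ground_truth.json \
               --code ambiguous-cmag --out ends
ambicode riboseq --sam sim/rpfs.sam --fasta sim/transcripts.fasta \
               --truth sim/ground_truth.json --code ambiguous-cmag --out ribo
```

The same workflow as a scripted narrative lives under `analysis/`
(`01_simulate_cohorts.py` … `05_evolution_checks.py`). Running it prints,
among others:

```
ambiguous-cmag: retained 91933/128000 records; 64/64 codons correct
tails: 800/800; primary stops: 800; 3'UTR median 22 nt (IQR 19-25), 9.2% UTR-less
TAA: proximal/distal frequency ratio 0.26 (binomial p = 3.14e-04)
termination signature: modal 3'-end offsets (11, 12) nt past the stop 3' nt, 84.8% of 10128 profiled ends
readthrough over 799 covered transcripts: mean 1.73%, median 0.0%, 88.5% of transcripts show none
purifying pair (20000 codons): Nd=38.0 Sd=919.0 dN=0.0009 dS=0.0627 dN/dS=0.0136 (<1: purifying selection)
```

Reading: all 64 codons of the simulated ambiguous code were recovered
(TAA/TAG called Q, TGA called W); 3′UTRs are extremely short with a 22-nt
median and ~9% absent altogether; the three "stop" codons — and no other
codon — are depleted several-fold in the coding sequence just upstream of
the stops; terminating footprints end 11/12 nt past the stop's last base;
readthrough is rare (median 0%); and an ortholog pair evolved under strong
purifying selection yields dN/dS ≈ 0.01.

## Layout

```
src/ambicode/     library: codes, inference, ends, riboseq, evolution, simulate, cli
analysis/         numbered narrative drivers writing tables under results/
scripts/          acceptance.py (headline-quantity recomputation)
tests/            pytest suite, including end-to-end property checks
docs/methods.md   models, conventions, parameter choices, limitations
```
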