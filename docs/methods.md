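# Methods

## Scope and conventions

`ambicode` analyses transcriptomes whose genetic code may reassign stop
codons, up to the fully ambiguous case in which UAA/UAG encode glutamine
and UGA tryptophan while all three still terminate translation near
transcript ends. Throughout the package:

* codons are DNA triplets internally (`TGA`, not `UGA`); reports may print
  RNA-style;
* coordinates are 0-based, half-open; annotated CDS spans include the stop
  codon; `polya_site` is the index of the first untemplated adenosine;
* the stop marker `*` is distinct from `X`; recording stops as `X` ("any
  amino acid") is an explicit translation mode used to build six-frame
  search databases, not a property of the code table;
* codons containing `N` translate to `X` and are excluded from
  codon-usage denominators;
* a `GeneticCodeTable` separates the codon→symbol mapping from an
  `ambiguous_set` of context-dependent codons; its `termination_set`
  (unconditional stops ∪ ambiguous codons) is what the end analyses use.

## Genetic-code inference

One `ProfileAlignmentRecord` is an aligned (consensus amino acid, codon)
pair with the profile column's conservation and the domain's conditional
e-value. Filters: e-value strictly below 10⁻¹⁰, conservation at least 50%
(inclusive), codon a valid N-free triplet; everything rejected is counted
by reason. Retained pairs accumulate into the 64×20 count matrix `m`.

Two normalizations are kept deliberately. The per-amino-acid form
(`M = m_ij / Σ_i m_ij`) is the matrix a sequence-logo renderer expects and
is what `export_logo_matrix` writes. Calls, however, use per-codon shares:
per-amino-acid scaling makes codons of abundant amino acids incomparable,
whereas the per-codon share directly asks "what does this codon mean?".
A codon is called as its maximal-share amino acid when its support is at
least `min_support` (default 10) and the top share beats the runner-up by
at least `ambiguity_margin` (default 0.1); otherwise UNASSIGNED (ties
included). Both thresholds are package choices — the underlying counts are
noisy at low support, and the margin guards against calling codons whose
evidence is split — and both are exposed in the API and CLI.

Recovery is defined table-wise: a sense codon must be called as its table
amino acid, and a codon that is a true stop (hence never observed as
sense) must come back UNASSIGNED. Candidate-stop labelling beyond
UNASSIGNED is the transcript-end layer's job.

Column conservation is taken from the record stream (the simulator writes
it; the pyhmmer adapter uses the profile's maximal match-state emission as
a proxy for the seed-alignment modal-residue frequency). Recomputing it
from the original seed alignments would require those alignments, which
the pipeline does not assume.

## Poly(A)-anchored end analysis

`detect_polya` scans backward from the 3′ end, accepting up to
`max_mismatch` (default 1) non-A bases inside the run, then trims any
non-A prefix; a call needs `min_tail` (default 8) adenosines. Sequence-only
detection cannot distinguish templated terminal adenosines from the tail,
so a UAA stop adjacent to its tail is partially swallowed by the call.
`find_primary_stop` compensates: it searches in-frame positions in the
60-nt window up to (and overlapping) the called site, completing codons
with tail A's, and clamps UTR length at 0. The primary stop is the most 5′
in-frame `stop_set` codon in the window; later in-frame candidates before
the tail are reported as `downstream_stops`; a window with no candidate
yields an explicit absent result rather than a silent guess.

Positional codon counts walk in-frame codons backward from the poly(A)
site; the final codon may borrow 0/1/2 tail adenosines to complete a
triplet (recorded separately). Bins are 3-nt offsets: the final codon is
`d = −3`, the previous `d = −6`, …

The depletion statistic is a package construction (the source analyses
present positional counts graphically): the codon's frequency among all
codons in a proximal window (default −90..−42, the coding-side region just
upstream of the −39-nt boundary where 3′UTR "codons" and true stops take
over) is compared with a distal reference (default: everything below
−240), via a two-sided binomial test of the proximal count against the
distal frequency. The test assumes codon draws are exchangeable across
positions; gene-family structure violates this when few distinct coding
sequences dominate a cohort (see simulator notes).

`base_frequency_profile` reports per-offset A/C/G/T frequencies and a
flatness summary (max absolute deviation per base) over the −90..−42
region, the companion check that composition, unlike "stop"-codon
frequency, is stable there.

## Ribosome-profiling layer

Footprints are retained when primary, mapped, 25–32 nt, and within the
mismatch bound (edit distance from the NM tag, else recomputed against the
reference transcript). Metaprofiles count footprint 3′ ends around anchor
codons using the anchor-codon convention of stacked ribo-seq figures: the
anchor occupies offsets 1–3, so a footprint ending 11 nt past a stop's
last base sits at profile offset 14. `classify_termination` re-expresses
offsets relative to the stop's 3′ nt and reports the modal downstream
offsets (two, collapsed to one when a single offset holds the mode
outright) and the fraction of all profiled ends they capture; a
termination signature is flagged above a configurable threshold (default
0.5). Terminating ribosomes protect 11–12 nt downstream of the stop, so
the expected modal set is {11, 12}.

Readthrough per transcript is `n_downstream / (n_downstream + n_stop)`,
where `n_downstream` counts footprints whose 3′ end lies ≥13 nt past the
primary stop's last base and `n_stop` counts footprints bearing the
termination signature (ends at exactly +11/+12). This stop-anchored
denominator is one of several defensible choices; it is isolated in
`estimate_readthrough`, and a density-ratio alternative
(`readthrough_density_ratio`, equal-width end-density windows) is provided.
Because the 10–15% of terminating footprints that miss the exact +11/+12
offsets leave the denominator, the estimator has a small positive bias
(≈ rate/0.9 at low rates) — visible in recovery tests and documented here
rather than corrected, since the correction would presume the very
signature fraction being measured. Cohort summaries (mean, median,
fraction zero) are over covered transcripts only
(`n_stop + n_downstream > coverage_min`, default 20). P-/A-site positions
are reported descriptively from 3′-end geometry; no occupancy model is
fitted.

When trusted CDS annotations exist, primary stops for the ribo-seq layer
come from the annotation (`primary_stops_from_annotation`): under an
ambiguous code the sequence-only caller is occasionally preempted by an
upstream in-frame sense "stop", which would misattribute that transcript's
terminating footprints as readthrough.

## NG86 dN/dS

Sites: each codon position contributes one site, split by the synonymous
fraction of its non-stop single-nucleotide changes; site counts are
averaged over the two sequences, so N + S = 3 × codons. Differences:
averaged over the substitution pathways between each codon pair, excluding
pathways through stop codons (all pathways are used only if every one is
blocked). Proportions are Jukes–Cantor corrected
(d = −¾ ln(1 − 4p/3)); the ratio is flagged undefined when dS = 0 or a
correction saturates. Synonymy is always evaluated under the supplied code
table, so alignments containing sense UGA=W codons are handled without
discarding those codons. The package deliberately implements counting
(not a maximum-likelihood codon model); on strongly conserved orthologs
the qualitative conclusion — dN/dS ≪ 1, purifying selection — is the
output of interest, not a third decimal.

4-fold-degenerate sites are third positions whose four variants encode the
same amino acid under the supplied table (so reassignments move the set —
e.g. UAR=Y makes the TAN box 4-fold). Their base composition proxies
neutral AT bias; `taa_usage_vs_a_regression` fits per-species UAA stop
usage against the 4-fold A fraction with an ordinary least-squares slope
test.

## Simulator

Each transcript is `leader | ATG | family codons | stop | 3'UTR | tail`.
Families (default 200) have uniform-random consensus amino acids and
per-column conservation (conserved columns, default 80%, draw conservation
from U(0.55, 0.95), others from U(0.2, 0.45)); each transcript keeps the
consensus per column with probability equal to that conservation, else
substitutes uniformly. Each transcript applies a random cyclic offset to
its family's columns so that fixed distances from the transcript end
sample all columns uniformly, as they would across genes of varying
length; without this, windowed codon composition is cluster-confounded by
the consensus of the handful of columns pinned near every poly(A) site.
The family count is set high enough (≥100 in practice) that positional
windows see mostly distinct columns, matching a transcriptome-scale domain
screen.

Codons are drawn per amino acid: standard codons uniformly; a reassigned
codon with target overall usage *u* gets weight 20·u·k/(1 − 20T) among the
k standard codons of its amino acid (T = summed targets there), which
yields overall usage *u* under 20 equifrequent amino acids. Default
sense-"stop" usage is 0.15% per reassigned codon — the upper end of the
observed range for such codons, and the only part of that range at which
a 0.3× proximal suppression remains statistically detectable per codon in
a 2,000-transcript cohort. Proximal suppression resamples sense-"stop"
codons whose first base falls in the depletion window (default −90..−42
nt upstream of the tail) to a standard synonym with probability
1 − `depletion_factor`.

3′UTRs are AU-rich (70% A+T), zero-inflated (default 8% zero-length), with
nonzero lengths from a discretized lognormal calibrated so the mixture
median is 22 nt; sigma 0.18 keeps P(UTR > 39 nt) small, consistent with a
−39-nt boundary beyond which the region upstream of tails is almost
entirely coding. In-frame UTR codons are a terminating codon with
probability 1/6 (≈5 intervening codons between the primary and downstream
stops). The final two UTR bases are drawn non-A so the annotated poly(A)
site is recoverable from sequence alone; in the real assemblies that role
is played by untemplated adenosines mismatching the reference, an evidence
channel a sequence-only simulator cannot reproduce. Tails are Poisson
(mean 30, minimum 15) adenosines.

Footprints per transcript: Poisson(40) stop-situated events, of which each
is readthrough with the transcript's true rate (a configurable constant,
optionally zeroed for a fraction of transcripts); terminating events place
3′ ends at +11/+12 past the stop's last base with probability
`term_signal_prob` (default 0.9), otherwise short of +11 (queued/imprecise
protection — a 3′ end beyond +12 would mean the ribosome translated past
the stop); readthrough events terminate at the next downstream in-frame
terminating codon, or within the tail when none exists. Poisson(30)
elongating events tile the CDS with a frame-3 3′-end bias (default 0.8).
Lengths are drawn from a 25–32 nt distribution peaked at 30 nt. Reads are
emitted as SAM with NM tags; sequencing errors are substitutions at rate
0.001.

A single integer seed drives all stages through deterministically spawned
substreams; identical configs give byte-identical FASTA/TSV/SAM/JSON.

### What the simulator does not emulate

Assembly artifacts (chimeras, fused UTRs), rRNA contamination, ligation
and nuclease bias, non-uniform expression levels, codon-usage bias within
synonym families, genomically templated A-rich "false tails", and
real poly(A)-site heterogeneity. Passing recovery tests therefore shows
the estimators are correct under the stated generative model, not that
real-data preprocessing (assembly, mapping, frame inference) is solved —
those steps are upstream inputs here.

## Numerical and degenerate-input choices

Zero marginals normalize to zero rows/columns (never NaN); ties in code
calling yield UNASSIGNED; empty metaprofiles and empty UTR call lists
raise; depletion tests require disjoint, nonempty windows; dS = 0 flags
the dN/dS ratio undefined while returning all components; tail borrowing
prefers the fewest borrowed adenosines (0 over 1 over 2). Analysis
problem sizes (2,000-transcript cohorts for code recovery and end
analyses, 500 covered transcripts for readthrough recovery,
500-transcript null cohorts for the type-I check) were chosen to give the
estimators comfortable statistical resolution at interactive runtimes.

## Known limitations

* The depletion test is binomial, not cluster-robust; on cohorts dominated
  by few distinct genes it is anticonservative (the simulator's family
  rotation and family count address this for synthetic data; real cohorts
  should be deduplicated to single-gene, single-isoform transcripts).
* Readthrough uses the stop-anchored denominator described above; absolute
  rates shift slightly (upward) relative to a denominator counting all
  stop-situated footprints.
* Frame inference for real transcripts is expected from annotations or an
  upstream tool; the package does not infer frames from homology.
* The pyhmmer adapter derives column conservation from match-state
  emissions when the seed alignments are unavailable; emission maxima are
  a smoothed proxy and can differ from raw column frequencies.
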