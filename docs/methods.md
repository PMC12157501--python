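# Methods

This note documents the models, defaults, and numerical choices behind
`srnaclass`, and what the synthetic benchmark does and does not show.

## Coordinates and strand handling

All internal intervals are 0-based half-open on the genomic forward
strand; GFF3 (1-based closed) is converted at the I/O boundary. Every
per-locus sequence operation works on the sense (transcript) strand:
minus-strand loci are reverse-complemented at extraction, so a promoter
offset of −79 or a terminator offset of +4 means the same thing on both
strands. This removes all off-by-one and strand ambiguity from the
motif-offset arithmetic, which is the error-prone part of promoter
geometry work.

## Spike-in normalization and the NB Wald test

Size factors are `sf_j = spike_j / mean_k(spike_k)`; normalized count =
raw / sf. The mean of the factors is exactly 1 by construction. Spike-in
normalization is used instead of median-of-ratios because a biogenesis
factor depletion is expected to move most miRNAs in the same direction,
violating the "most features unchanged" assumption of compositional
normalizations. Note the absolute scale of normalized counts is only
defined up to the cross-sample spike mean; all between-sample ratios
(hence all fold changes) are invariant to per-sample technical scaling.

Fold changes are `log2((mean_norm_treat + pc) / (mean_norm_ctrl + pc))`
with pseudocount `pc = 0.5` (config), keeping estimates finite for
dropout features.

The test is a two-group NB Wald test, not a GLM re-implementation.
Per feature, dispersion `alpha` (Var = mu + alpha mu²) is estimated by
method of moments from the pooled *within*-group variance
(`alpha = max(0, (s² − m̄)/m̄²)`), then averaged 50:50 with the
across-feature median. The moderation matters: with 3 replicates a raw
per-feature plug-in makes the Wald z behave like a t variable with ~4
degrees of freedom read off a normal table (empirical type-I error
~0.12 at nominal 0.05); borrowing strength across features — the same
idea dispersion-shrinkage GLM packages use — restores calibration
(~0.08 measured under the null simulation of 500 features, n = 3, 50
Monte-Carlo repetitions; the acceptance script recomputes this).
The standard error is delta-method:
`Var(lfc) = [Var(m_t)/(m_t+pc)² + Var(m_c)/(m_c+pc)²] / ln2²` with
`Var(m_g) = (m_g + alpha m_g²)/n_g`, and p is two-sided normal.
Benjamini–Hochberg adjustment is the standard step-up (delegated to
statsmodels; verified in tests against the step-up definition).

baseMean is the mean of normalized counts over *all* samples; default
reporting filters are baseMean ≥ 10 (deep bulk runs) or ≥ 1 (shallow
runs), both configuration.

## Hairpin classification

"Stem length" is the count of base pairs whose partners both lie inside
the precursor span — not a nucleotide span. The short-hairpin call is
`stem_pairs < 32` (config), the boundary separating canonical ~35-pair
precursors (basal stem included) from Microprocessor-independent
substrates. Whether the threshold should count only the longest helix is
genuinely open; we count all precursor-internal pairs and expose the
threshold, which is the more conservative reading for hairpins with
small internal loops.

Structures normally come from dot-bracket files produced by any external
folder. The built-in fallback `fold_maxpair` is a Nussinov base-pair
maximisation (Watson–Crick + GU, T≡U, hairpin loop ≥ 3, ties broken
toward the smaller opening index), so the pipeline runs with zero
external tools and the folder is exhaustively checkable against
enumeration at small n. It is *not* a thermodynamic folder: pair counts
are an upper-bound proxy for helix content, which is sufficient for the
pair-count threshold but not for structure drawing or MFE comparisons.

## Pol III type-II promoter scan

Box A (`TRGCNNARYNNG`) and Box B (`GWTCRANNC`) defaults are the standard
eukaryotic tRNA-derived consensi with ≤ 1 mismatch; the organism-specific
consensus should replace them when available (they are plain IUPAC
strings in config). Scan windows are start offsets −95..−70 (Box A) and
−50..−28 (Box B), covering the expected −87..−79 and −42..−35 geometry
with margin. Among hits, the best is (fewest mismatches, closest to
window centre). Terminators are maximal sense-strand T runs ≥ 4
(flagged "strong" at ≥ 5, since a 5T-run mutation reduces but does not
abolish expression at such loci): the proximal run must start within 10
nt of the 3p-arm 3′ end, a distal run within 60 nt. The architecture
call requires Box A AND Box B AND a proximal terminator — each promoter
element is individually necessary in promoter-dissection data, and the
conjunction keeps the false-positive rate on random background below a
percent (measured in the acceptance script). The TSS estimate
(Box A offset − 15) is a flagged heuristic, not a RACE substitute.

## Tailing and isoforms

Reads are assigned to arms by a 16-nt anchored prefix match starting
within ±2 nt of the annotated arm 5′ end; reads matching k arms get
weight 1/k (the htseq nonunique-fraction convention), which matters for
paralogous arms sharing an identical reference sequence. The tail call
maximises the templated prefix against the genomic sense sequence
*extended past the annotated arm end*: a 3′ addition identical to the
next genomic base is therefore never called untemplated. This is
conservative — without molecular barcodes the ambiguity is undecidable —
and undercounts tails that mimic the genome. Trim offsets ≤ 0 are
trimming isoforms; templated extensions are reported capped at +3.
Tails longer than 5 nt are flagged low-confidence. Mixed-nucleotide
tails are binned as `other`; per-arm percentages are computed over
weighted reads, arms below 1 RPM average abundance are excluded, and
the top six isoforms per arm are surfaced.

The 3p-vs-5p asymmetry statistic is
`delta = mean(%tail over 3p arms) − mean(%tail over 5p arms)` with an
add-one-corrected permutation p over arm labels (default 10,000
permutations, seeded). A positive A-tail delta is the signature of an
adenylating enzyme acting on precursor species, whose only accessible 3′
end is the 3p arm's.

## Classification rules

Predicates (defaults, all config): `dicer_dependent` ⇔ lfc ≤ −1 and
p_adj < 0.05; `polIII_dependent` likewise; `MP-insensitive` ⇔ lfc ≥ −0.5
in **every** available MP dataset (two independent depletion datasets are
combined by conjunction; with one dataset the rule degrades to it and the
rationale says so). The −0.5 band rather than 0 reflects that
MP-independent loci are typically slightly *up* under MP loss, while
sampling noise at realistic depth can push estimates a few tenths
negative. Rules fire in priority order: misannotated piRNA (21 nt, 5′U,
not Dicer-dependent) > misannotated 26G (26 nt, 5′G) > Pol III
MP/Dicer-independent > Pol III noncanonical (MP-insensitive,
Dicer-dependent, Pol III-dependent OR architecture + ChIP overlap) >
mirtron-like (short hairpin, no Pol III evidence) > canonical
(MP-sensitive, Dicer-dependent) > unclassified. ChIP overlap is
corroborating, never required, when direct Pol III-depletion response is
available. "Pol III evidence" for the mirtron exclusion mirrors the
noncanonical rule's definition (dependence, or architecture corroborated
by ChIP), so an uncorroborated promoter-like background match cannot
eject a mirtron from its class. Classification is per-locus and
deterministic; input order cannot change any label.

## Synthetic study design

The generator emulates the structure of a multi-condition depletion
study: conditions control / MP_depleted / Dicer_depleted /
PolIII_depleted, 3 replicates, expected depth 2000 reads per expressed
arm (3p arms at 0.6× the 5p arm), NB dispersion 0.05 (typical for
well-replicated spike-in small-RNA-seq), spike-ins Poisson with mean
5000 split over 3 spike features, and a per-sample lognormal technical
scale (sd 0.15) applied to counts and spikes alike. Planted log₂ fold
changes encode the class logic: depleted conditions at −2, unaffected at
0, and MP-independent classes at +0.3 under MP loss (mild up-regulation).
Tail models: A-tails at rate 0.10 on Pol III-class 3p arms (near zero on
5p), U-tails at 0.05 on mirtron-like 3p arms; tail lengths 1–3
(mononucleotide only — tail categories are single-nucleotide classes);
trimming offsets 0/−1/−2/−3 at 0.70/0.20/0.07/0.03, with tailed reads
drawing trim from a distribution concentrated on the −1 isoform so
tailing marks a 1-nt-shortened intermediate. No quantitative literature
values exist for these rates; they are config-exposed defaults, not
constants.

Two construction choices are deliberate. First, planted Pol III loci are
verified after construction — the planted Box A/Box B must be the
best-scoring hits in their windows and the terminator runs must be found
— and the random flanks are resampled otherwise, so planted loci pass
detection by construction (background specificity is measured separately
on canonical loci, which carry no planted elements). Second, the three
terminal precursor bases and the first downstream flank base are drawn
from {C, G}: a planted A/U tail can then never coincide with the genomic
template at the trim offsets in use, so the manifest's planted rates are
exactly what a sequence-based caller can recover. Real genomes do not
offer this courtesy; on real data the templated-prefix convention
undercounts tails that mimic the genome (~¼ of them at random), and
recovered rates should be read as lower bounds.

The generator does not model sequencing error, adapter artifacts, or
ligation bias; passing benchmarks therefore demonstrate correctness of
the analysis logic under idealized reads, not robustness to library
chemistry. Background sequence is i.i.d. uniform ACGT — the simplest
null for motif specificity floors.

Problem sizes used by the test suite and acceptance script (chosen to
make each measurement statistically meaningful at desk scale): 10 loci
per class × 6 classes for the end-to-end benchmark; 500 null features ×
50 Monte-Carlo repetitions for test calibration; 5000 reads/arm for
tail-rate recovery (binomial s.e. ≈ 0.4 pp); 200 random 12-mers for the
folding oracle; 200 background loci for the promoter specificity floor.

## Determinism

Every stochastic component draws from `numpy.random.default_rng` seeded
from the single configured seed (generation, counts, reads, permutation
test). Output tables carry a provenance header (version, seed, config
hash) and no timestamps; re-running an identical configuration is
byte-identical.

## Known limitations

* The NB Wald test is an approximation; it does not shrink fold changes,
  fit GLM designs beyond two-group contrasts, or handle batch
  covariates. Exact numeric agreement with a full GLM analysis of real
  data is out of scope.
* `fold_maxpair` maximises pair count, not free energy; hairpins whose
  MFE structure differs substantially from the max-pair structure may be
  mis-counted. Supplying external dot-bracket files sidesteps this.
* TSS estimation is a heuristic offset from Box A; real start sites
  require 5′ RACE or equivalent.
* The classifier consumes arm-level depletion statistics from the most
  abundant arm per contrast; loci with strongly discordant arms deserve
  manual review of the evidence table.
* 5′-end heterogeneity, tailing-enzyme identity, and Argonaute-loading
  class are outside the computable evidence set.
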