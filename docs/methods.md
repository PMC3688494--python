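# Methods

This note documents the statistical model, the numerical and design choices
behind `orgedit`, what the simulator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

The unit of analysis is a pileup column: for one library and one position of
an amplicon template (transcript orientation), the multiset of
`(read_position, observed_base)` observations from accepted alignments.
Reads are preprocessed by removing the first 3 bases from the 5′ end,
truncating at the first base with Phred quality below 20, and discarding
reads shorter than 60 nt after both operations. Alignment records are kept
only if they are primary, have a unique top hit (MAPQ > 0, and an `X0` tag
of 1 when the aligner provides one), and contain no indels. Reverse-strand
alignments are complemented into template orientation (SAM already stores
them that way); their read positions are counted from the sequenced 5′ end,
i.e. `read_length − aligned_index`. The protocol is strand-specific, so
antisense reads are rare; counting them after complementing is our choice —
the alternative (discarding them) changes depths by well under a percent in
practice and none of the statistics' logic.

Ambiguous bases (N) are recorded in columns but excluded from all counts,
fractions and likelihoods.

## Empirical error model

For each library, `P_i(o|r)` is estimated from the alignments themselves:
counts of observed base `o` at read position `i` over template base `r`,
excluding masked columns. The off-diagonal rate is

    (n(i,r,o) + c) / (N(i,r) + 3c),   c = 0.5 by default,

with the diagonal taking the complementary mass, so each row is exactly
normalised and no rate is zero when `c > 0`. The pseudocount exists because
the likelihood ratio degenerates at a zero error rate; 0.5 (Jeffreys-style)
is small against any stratum that passes the coverage floor.

A read-position stratum is used only when it holds at least 1000
observations of its template base; thinner strata fall back to the
position-pooled rates. The floor is a variance-control choice: at 10³
observations a 10⁻³ rate still has a relative standard error of ~100%, and
anything thinner is noise.

Masking: before estimation, every template-C column whose pooled
(all-library) T fraction reaches 0.02 is excluded. Genuine editing inflates
the apparent C→T error rate, which biases the caller conservative; masking
at 2% keeps strongly and moderately edited sites out of the rate estimate
while leaving the mass of true error observations in. The threshold is a
formalisation of "mask the obvious editing sites" — there is no external
ground truth for it, and it is exposed as a parameter.

## Likelihood-ratio editing caller

At a template C with editing fraction θ, each sequenced molecule is edited
with probability θ; the observation likelihood is the two-component mixture

    L(θ) = Σ_(i,o) n(i,o) · log[(1−θ)·P_i(o|C) + θ·P_i(o|T)].

θ̂ maximises L on [0, 1] by bounded Brent iteration (absolute tolerance
1e-8; the likelihood is concave in θ, so the optimum is unique). The
statistic Λ = 2(L(θ̂) − L(0)) is referred to the χ²₁ upper tail.

*Boundary convention.* Under H₀, θ sits on the boundary of the parameter
space and the asymptotic null is the mixture ½χ²₀ + ½χ²₁; using the plain
χ²₁ tail instead roughly doubles p-values. We use the plain tail
deliberately: every choice in the calling chain (masking, this convention)
errs conservative. Consequence, computed by the calibration test: the null
rejection rate at p < 0.01 is about 0.0044 at depth 5500 — slightly *below*
half the nominal level, because the null T count is a discrete
Binomial(5500, ~10⁻³) variable and the rejection boundary (T ≥ 13) cannot
land exactly on the asymptotic quantile.

The per-observation mixture form (rather than a collapsed binomial on C/T
counts alone) is our reconstruction; bases other than C/T at a C site enter
the likelihood through `P_i(o|C)`/`P_i(o|T)` but are excluded from the
reported T fraction T/(C+T). A column with no T observations is returned as
the null call directly (the mixture is decreasing in θ there).

Candidate filters across libraries, all strict inequalities: p < 10⁻⁶ in at
least one library; max T fraction > 0.05; mean depth over *all* libraries
(zero where uncovered) > 100.

`call_counts_batch` is a vectorised implementation for position-uniform
rate tables (golden-section search, 60 iterations, bracket < 10⁻¹²), used
by the large calibration studies; it agrees with the per-column caller to
optimiser tolerance and is tested for that agreement.

## Differential editing

Replicates are pooled by summing C and T counts; extents and ΔEE =
(EE_wt − EE_mut)/EE_wt are computed from pooled counts (not averaged
per-replicate extents). The two-genotype comparison is the Pearson χ² on
the 2×2 table with expected cells from the marginals, one degree of
freedom, and no Yates correction — matching the plain Σ(O−E)²/E form. The
per-test threshold is α/n (Bonferroni), with n the number of sites analyzed
in the organelle partition. Classification: dependent iff p below the
nominal threshold *and* ΔEE ≥ 0.1; everything else independent. Negative
ΔEE (an editing increase) is reported but never classified dependent. Sites
with zero wild-type extent or a degenerate table are excluded with a reason
code rather than silently dropped.

Silenced genotypes are compared against two controls. A site is first
checked in the GFP-silenced control against the uninoculated control: if
the control itself is significantly reduced there (same rule), the site is
excluded from the silenced universe — virus inoculation can unspecifically
depress editing. Otherwise the site is dependent only if the rule holds
against both controls; reported extents, ΔEE and the test are anchored on
the uninoculated control, which is the natural baseline since the nominal
thresholds are derived against it.

Summary percentages are integers, rounded half up.

## Overlap analysis

Factor classifications form a sites × factors label matrix. For a chosen
factor set (≤3), sites excluded for any factor are dropped listwise, and
the 2^k dependent-membership regions are counted (they partition the
analyzed set — a tested invariant). Pairwise factor independence is the
same Pearson χ² applied to the joint dependent/independent 2×2 table,
reported together with observed and expected-under-independence cell
counts so an excess of doubly-controlled sites is visible directly.

## Cis-element similarity

The window is 20 nt upstream through 5 nt downstream of the candidate C
(≤26 nt, truncated and flagged at template edges), transcript orientation
only. Similarity to a known site's window is a gapped local alignment with
match +1, mismatch −1, gap −2; the reported identity is the number of
identical aligned positions, maximised over **all** score-optimal local
alignments. That last clause matters: co-optimal local alignments can carry
zero-score flanks that add identities (TTT/TAT scores the same as its last
match alone but aligns two identities), and plain Smith-Waterman traceback
silently trims them. The implementation therefore tracks, per DP cell, the
maximum match count for every achievable non-negative running score;
optimal alignments never pass through negative running scores, so the
per-cell maps are small and the computation is exact. It is validated
against a brute-force enumeration of every local alignment on short
strings. Hits require ≥10 identities. The original by-eye gap placement
this formalises is not an algorithm; a reproducible criterion necessarily
differs from it in borderline cases, so hand-curated hit counts are not a
validation target.

## Simulator

`simulate_truth_set` draws templates with the requested GC fraction (G and
C equiprobable) and places editing sites only on template Cs, rejecting
configurations that put θ elsewhere. `simulate_reads` draws read start
positions per the coverage shape (flat by default; `mid_dip` and
`end_peak` options mimic the shearing artefacts of amplicons longer than
the shear cutoff), applies molecule-level editing (base becomes T with
probability θ), then passes every base through the substitution channel. A
scalar error ε means every off-diagonal substitution occurs at rate ε per
base — so the total mismatch rate is 3ε, of the right order for PCR/RT-PCR
material at ε = 10⁻³ and plasmid-like spikes at 10⁻⁴. Reads are emitted
with their true alignments as plain-text SAM, making an external aligner
unnecessary for testing; FASTQ is emitted alongside.

Defaults mirror the sequencing regime the method targets: 97-nt processed
reads and per-site depth 5500 (the mean per-site depth of a 24-plex
amplicon pool).

What the simulator does *not* emulate: indels, quality-score decay along
the read (qualities are constant), paired-end structure, PCR duplicates,
antisense contamination, and position-dependent error profiles unless
explicitly configured. Passing closed-loop tests therefore demonstrates
correctness of the statistical machinery under the stated error model, not
robustness to artefacts outside it.

`simulate_site_counts` draws per-site base counts directly from the
equivalent multinomial — statistically identical to sequencing that many
molecules — and is used for calibration studies of 10⁵ sites where
per-read simulation would be pointless bookkeeping. Problem sizes used in
the shipped tests and acceptance script: 10⁵ null sites at depth 5500 for
calibration, 400 sites per θ for recovery, 5000 null + 50 edited sites at
depth 2000 for the selection filters, 10⁷ observations for error-model
recovery, and a 4-library end-to-end study at depth 400 over two 300-nt
templates.

## Known limitations

* Error rates condition on read position only, not on quality scores or
  sequence context; the model inherits that simplification.
* The LRT's χ²₁ convention is conservative by design; at extreme depths the
  conservatism grows mildly through count discreteness (quantified above).
* The silenced-universe Bonferroni denominator is the organelle partition
  size before GFP-control exclusions; excluding first would shrink n by a
  few percent and loosen the nominal threshold accordingly — immaterial in
  the tested regimes, but a convention worth stating.
* Only C→T on the transcript strand is tested; other substitution classes
  inform the error model only.
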