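# Methods

This note documents the statistical models behind each stage of `clipdep`,
the defaults and why they were chosen, the numerical choices, what the
synthetic generator emulates, and the known limitations.

## RNA-dependency classification (`clipdep.rnadep`)

**Model.** The bait (Ago2) is immunoprecipitated from undigested
((−)RNase) and fully digested ((+)RNase) extracts, with label-free
abundance scores over replicates. Replicates are summed per condition; the
per-protein statistic is the bait-normalized log2 condition ratio (a
pseudo-abundance ε = 1 guards against zero sums). The normalization assumes
bait self-enrichment cannot be RNA-dependent, so the bait maps to exactly
0. Under the empirical-null assumptions — (i) any ratio above zero has a
true value of zero with the deviation due to noise, and (ii) the noise is
symmetric about zero — the positive ratios reflected about zero form a
null sample for RNA-*independent* association. Each protein's
LOD = log10(null density / empirical density) at its ratio; LOD < 0 (the
full distribution explains the point better than the null, i.e. excess
mass) together with a ratio on the depleted (negative) side classifies it
RNA-dependent.

**Why the extra guards.** Three refinements stabilize the density-ratio
classifier at interactome scale (a few hundred proteins):

- *One-sided calls.* The raw density ratio is slightly negative for every
  positive ratio whenever positives outnumber half the sample (the null
  places ~g(x)/2 there against an empirical ~(n₊/n)·g(x)). Dependency is a
  depletion, so only negative ratios are eligible; this also pins the null
  mode (ratio 0) to the independent class.
- *Noise re-centering.* The bait anchor is itself estimated from three
  replicates; an unlucky draw shifts the entire cloud and breaks the
  symmetric-about-zero assumption. The null construction therefore
  re-centers at the mode of the ratio distribution, refined by a trimmed
  symmetric mean (window = 2 robust SDs, iterated), which the well-separated
  dependent population cannot pull. Reported ratios stay bait-normalized.
- *Shared, inflated bandwidth.* Both densities are Gaussian KDEs with the
  Silverman factor of the mirrored sample × 1.5, applied to both fits. A
  bandwidth re-derived from the full distribution would be inflated by the
  dependent mode and oversmooth only one side of the comparison; and at
  n ≈ 300 the log-ratio of two independently tuned KDEs fluctuates by as
  much as the structural LOD margin near the center (~0.1). Densities are
  floored at 1e−12 to keep the LOD finite.

**Pre-filter.** One-way ANOVA across the three run groups ((−)RNase IP,
(+)RNase IP, IgG control) with p ≤ 0.05, plus a unique-peptide floor
(default 1). Precomputed p-values are honoured; otherwise the ANOVA is
computed from the control replicates. Replicate quality is summarized
descriptively (variance explained per principal component of the
replicate-by-protein matrix) and is deliberately not an automatic filter.

**Knobs.** `ratio_orientation` (default plus_over_minus, so dependent
proteins sit at negative ratios; the classifier direction follows the
flag), `lod_threshold` (0), `pseudo` (1.0), `bw_method`/`bw_scale`
(silverman × 1.5), `density_floor` (1e−12).

## Peak geometry and Sfpq dependency (`clipdep.intervals`, `clipdep.clip`)

Coordinates are 0-based half-open (BED native; GFF3 converted on read).
Distances are edge-to-edge gaps in nt — 0 when intervals overlap — which
matches the "within 500 nt" adjacency semantics; center-to-center was the
alternative and is not used. Distance classes partition: close d < 500,
far 500 ≤ d < 7000, very far d ≥ 7000 (peaks with no same-chromosome
reference are very far). Ties for the nearest reference resolve to the
smallest start, then name. The peak score filter keeps score ≥ 7,
including the boundary. Category assignment resolves multi-feature
overlaps by the precedence 3′UTR > 5′UTR > CDS > intron > TTS > promoter >
ncRNA, with intergenic as the total-function fallback; it is strand-aware
when both peak and transcript are stranded.

**Dual-filter dependency merge.** A peak of the full set is called
Sfpq-dependent when its best Jaccard against the control-vs-knockdown
enriched filter AND against the knockdown-unchanged double-check filter
both reach 0.10 (an `or` mode is available). AND is the default because
the second filter is a verification, not an alternative source of
evidence.

**Shuffle Z test.** Distances from each reduced Ago2 peak to its nearest
Sfpq peak are binned in 250-nt half-open bins over 0–1000 nt. The null
re-places each reduced peak uniformly at random within its own host 3′UTR
(length preserved, Sfpq fixed — the minimal randomization that preserves
Sfpq occupancy structure), 10,000 times by default; Z = (obs − null mean)/
null sd per bin, NaN when the null sd is 0. Peaks are processed in sorted
name order so results are invariant to input ordering, and the seeded
generator makes runs bit-reproducible. Peaks that do not fit inside any
host 3′UTR are reported by name as errors.

**Recruitment correlation.** For newly recruited peaks on 3′UTRs shared
with reduced peaks, per-bin percentages of nearest-reduced-peak distances
are compared against a uniform re-placement null; bins outside the central
95% permutation interval are flagged above/below chance.

**Group comparisons.** Fisher exact tests (two-sided) for in-region
membership of close vs far / very far peaks; one-sided Wilcoxon rank-sum
tests for 3′UTR length orderings (occupied > all, dependency-bearing >
occupied). Exact small-sample behaviour of both tests is verified against
enumeration oracles in the test suite.

## Motif and seed scanning (`clipdep.motifs`)

The two binding motifs are explicit word lists — motif 1 {CUGU, CUGA},
motif 2 {CUGUA, AUGUA, UUGUA, GUGUA} — scanned as exact matches on
uppercase RNA (T→U on read; N matches nothing). Non-overlapping counting
is greedy left-to-right with longest-word precedence at equal starts, so a
CUGUA is one site rather than a CUGU plus remainder; for these word sets
the greedy count provably attains the dynamic-programming maximum-disjoint
optimum, asserted on randomized sequences in the tests. A canonical seed
site is the reverse complement of miRNA nucleotides 2–7; all (possibly
overlapping) occurrences are reported. Enrichment between sequence groups
is a presence/absence Fisher exact test (meaningful on peak-sized
sequences; on multi-kilobase sequences presence saturates — use counts per
kilobase instead). PWM scoring, de novo discovery and secondary structure
are out of scope.

## RIP enrichment (`clipdep.rip`)

Counts are filtered at a 20-read floor in both IP and input (the both-arms
convention prevents infinite enrichments; an ip-only mode exists), CPM
normalized, and summarized as log2((ip + 1)/(input + 1)). A two-component
Gaussian mixture is fitted by EM with deterministic quantile-based
initialization (means at the 25%/75% quantiles, pooled SD, equal weights),
a variance floor of 1e−6, and convergence at |Δloglik| < 1e−6; components
are relabelled so component 0 has the lower mean (background). The
per-miRNA LOD is the posterior log-odds of the enriched component;
LOD > 0 calls enrichment. Note the sign convention is deliberately the
opposite of the proteomics stage: there the *null* density in the
numerator flags signal at negative LOD, here the *signal* component in the
numerator flags it at positive LOD. Fitting targets log-enrichment values
(a raw-log-count option would require a different background model and is
not provided); CPM shifts both components by the same library-ratio
constant, which cancels in the classification.

## Expression rescue (`clipdep.rescue`)

Transcripts are grouped by their strongest peak evidence:
canonical_direct (reduced close 3′UTR peak containing a seed site) >
direct_close > far > very_far > independent. The primary statistic is the
paired Wilcoxon signed-rank test of the miRNA fold-change with vs without
Sfpq knockdown within a group (exact null for n ≤ 25, continuity-corrected
normal above); the unpaired rank-sum of the group's deltas against the
independent group is also reported, since the experimental design supports
both readings. The effect direction is the median Δ = lfc(knockdown) −
lfc(control); positive Δ = rescue.

## Synthetic data (`clipdep.synth`)

The generator plants each stage's signal at the study conditions and emits
truth tables; each generator draws from its own RNG stream (master seed +
fixed offset), so regenerating one table never perturbs another.

- **Transcriptome**: 300 transcripts laid end-to-end on one chromosome,
  20 kb apart, all on the + strand (category assignment is still tested on
  both strands with hand-built annotations); promoter/5′UTR/CDS/intron/
  3′UTR/TTS features; 3′UTR lengths lognormal (median ≈ 1.6 kb), with
  Sfpq-occupied UTRs (one third of transcripts) drawn e^0.7-fold longer
  and motif-planted at 6 words/kb vs 1 word/kb.
- **Peaks**: ~8 Sfpq peaks per occupied 3′UTR — dense, aggregate-like
  occupancy of the kind reported for this protein (tens of sites on a
  single target UTR). This density also sets the shuffle test's operating
  regime: a uniform placement within an occupied UTR is usually within
  500 nt of some Sfpq peak, so only the short-range bins can be enriched.
  Direct (reduced) Ago2 peaks — 30% of 200 — are planted 0–200 nt from an
  Sfpq peak; a further 10% are planted close but not reduced
  (Sfpq-independent); the rest are placed > 500 nt from Sfpq, half in
  3′UTRs and half in CDS/intron/5′UTR. Twenty sub-threshold-score decoys
  exercise the score filter. The knockdown filter sets are ±5-nt jittered
  copies of the direct peaks, so the dual-filter merge should recover
  exactly the planted set. Canonical let-7a seed sites are written into
  60% of direct peaks.
- **IP-MS**: 300 proteins, 20% RNA-dependent with a −2 log2 (+)RNase
  effect, replicate noise sd 0.3 (log2, multiplicative), 3 replicates, IgG
  controls at 2% of the IP abundance. The bait is drawn with a third of
  the replicate noise — it is the most abundant, best-measured protein and
  the normalization anchor.
- **RIP**: 5000 log-enrichments from 0.7·N(0, 0.5²) + 0.3·N(3, 0.5²),
  back-computed into integer counts over lognormal input depths; a nested
  second IP shares the input and plants its enriched set as an 85% subset
  of the first.
- **Rescue**: directly controlled transcripts get lfc = −1.5 under the
  miRNA, rescued to −1.0 under knockdown (effect 0.5 log2, noise sd 0.2);
  all other groups show no rescue.

**What the generator does not emulate**: mapping/peak-calling noise,
overdispersed count noise beyond the planted mixture, dinucleotide
composition (sequences are i.i.d. uniform before planting — sufficient for
exact-word scanning, not for PWM or structure work), minus-strand
transcripts, overlapping genes, or batch effects in the proteomics.
Passing tests therefore demonstrate that each statistical procedure
recovers the structure it assumes, not that the upstream experimental
steps are robust.

## Problem sizes and determinism

Defaults were chosen so that a complete pipeline run takes ~1 s and the
full 20-seed validation suite a few tens of seconds: 300 transcripts,
~1000 peaks, 300 proteins, 5000 miRNAs, 1000–10,000 shuffles. Every
stochastic operation takes an explicit seed, records it in its output, and
is bit-reproducible; the EM mixture fit is deterministic outright. All
reported empirical numbers in the README are outputs of
`clipdep demo --seed 1` and the acceptance script, regenerated at run
time.

## Known limitations

- The LOD classifier assumes the dependent population is well separated
  from the noise (≳ 4 noise SDs here); heavily overlapping populations
  would need an explicit mixture treatment instead of the mirrored null.
- The shuffle test conditions on the host 3′UTR assignment; peaks spanning
  feature boundaries are rejected rather than clipped.
- Fisher presence/absence motif enrichment loses power on long sequences
  (presence saturates); the occurrence–length correlations are the
  complementary statistic.
- The two-filter merge treats the upstream differential peak callers as
  black boxes; no attempt is made to model their error structure.
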