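# clipdep

Statistical machinery for asking whether an RNA-binding protein (here:
**Sfpq**) locally controls miRNA targeting, built around four quantitative
questions:

1. **Which proteins interact with Ago2 through RNA?** Label-free IP-MS
   abundances from (−)RNase vs (+)RNase immunoprecipitations are summarized
   as bait-normalized log2 ratios; a mirrored null distribution and a
   log-of-odds (LOD) score classify each interactor as RNA-dependent or
   RNA-independent.
2. **Are Sfpq-dependent Ago2 CLIP peaks controlled locally?** Ago2 peaks
   reduced on Sfpq knockdown (selected by a dual-filter Jaccard merge of
   differential peak sets) are placed relative to the nearest Sfpq peak
   (close < 500 nt, far 500–7000 nt, very far ≥ 7000 nt), tested for 3′UTR
   enrichment by Fisher exact tests, and validated by a permutation test
   that re-places each peak uniformly within its host 3′UTR and computes a
   per-bin Z score over 250-nt distance bins.
3. **Where does Sfpq bind?** Exact-word scans for the two Sfpq motifs
   ({CUGU, CUGA} and {CUGUA, AUGUA, UUGUA, GUGUA}) with greedy
   non-overlapping counting, canonical miRNA seed-site scanning (reverse
   complement of miRNA nt 2–7, e.g. UACCUC for let-7a), and
   occurrence-vs-length correlation analyses.
4. **Which miRNAs are enriched in an RNA-IP?** Per-miRNA log2 IP/input
   enrichments (CPM normalized, ≥ 20-read floor) are modeled as a
   two-component Gaussian mixture fitted by EM; a miRNA is called enriched
   when the posterior log-odds of the high-mean component is positive
   (LOD > 0).

A fifth stage tests whether Sfpq knockdown *rescues* miRNA-mediated
downregulation for transcript groups defined by the peak analysis (paired
Wilcoxon signed-rank within group, rank-sum against the independent group).

Everything runs against a first-class synthetic-data generator
(`clipdep.synth`) that plants each stage's signal with known truth labels,
so the whole pipeline is exercised and validated without any external data.

## Core scores

For protein *p* with replicate-summed abundances S⁺ and S⁻:

    log2ratio(p) = log2((S⁺_p + ε)/(S⁻_p + ε)) − log2((S⁺_bait + ε)/(S⁻_bait + ε))
    LOD(p)       = log10( f₀(x_p) / f(x_p) )          dependent ⇔ LOD < 0 (x_p < 0)

where f₀ is the kernel density of the mirrored null {x > 0} ∪ {−x : x > 0}
and f the empirical density, estimated with a shared bandwidth.

For the shuffle test, bin b ∈ {[0,250), …, [750,1000)}:

    Z_b = (observed_b − mean_shuffle(null_b)) / sd_shuffle(null_b)

For RIP enrichment with mixture (w₀, μ₀, σ₀; w₁, μ₁, σ₁), μ₀ < μ₁:

    LOD(x) = log10( w₁ φ(x; μ₁, σ₁) / (w₀ φ(x; μ₀, σ₀)) )     enriched ⇔ LOD > 0

## Worked example

```python
from clipdep import synth, rnadep

cfg = synth.SynthConfig(seed=1)                  # 300 proteins, 20% dependent
records, truth = synth.make_ipms_table(cfg)
kept = rnadep.filter_candidates(records)         # ANOVA p <= 0.05 vs IgG IP
res = rnadep.RnaDependencyModel(kept, bait_id="Ago2").fit()
print(res.summary())
```

prints

```
RNA-dependency classification
==============================================
bait:                 Ago2
ratio orientation:    plus_over_minus
proteins classified:  301
  RNA-dependent:      60
  RNA-independent:    241
LOD threshold:        0.0
median dependent log2 ratio: -2.026
```

The 60 proteins called RNA-dependent are exactly the 60 planted with a −2
log2 RNase effect (the table's truth labels confirm sensitivity and
specificity of 1.0 at this seed), and their recovered median ratio −2.03
matches the planted effect. `res.table` holds the per-protein ratio, LOD
and class; `res.plot()` overlays the mirrored null (red) on the empirical
density (black), the same picture the classification is read from.

The one-command demo runs every stage on a seeded synthetic bundle and
prints a recovery report:

```bash
clipdep demo --seed 1 --n-shuffles 1000
```

```
End-to-end synthetic recovery report
==================================================
rnadep_n_classified                          301
rnadep_n_dependent                            60
rnadep_sensitivity                             1
direct_recovery                                1
shuffle_z_0_250                            4.514
shuffle_z_500_750                         -1.771
shuffle_z_750_1000                         -1.09
rip_sensitivity                           0.9973
rescue_p_canonical_direct              3.003e-06
rescue_p_independent                       0.736
```
(abridged; the full report also covers Fisher category enrichment, motif
statistics and 3′UTR length comparisons)

The shuffle Z is large only in the [0, 250) bin — the planted dependency is
short-range — and the rescue is significant only for transcripts whose
direct Sfpq-dependent peaks carry a canonical seed site.

Each stage is also a subcommand over files (BED/GFF3/FASTA/TSV in, TSV
out): `clipdep simulate | rnadep | dependency | motif-scan | seed-scan |
rip-enrich | rescue`.

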