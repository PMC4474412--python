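# Methods

## Model and procedure

shapemotif treats motif discovery as a word-ranking problem. Every k-mer
(default K = 9, suited to ~100–200 bp ChIP-seq peak regions; larger K
captures composite or gapped patterns at higher cost) is counted exactly
over the input regions. With `strand_mode="both"` (default) each position
also contributes a minus-strand occurrence filed under the
reverse-complement reading, so palindromes accumulate two counts per
position and both orientations of a binding word feed the same seeds.

**Background.** A 0th- or 1st-order Markov chain (default order 1; order 0
behaves almost identically on real data) is fitted to the target regions
with add-one smoothing. The expected count λ of each word is the average of
its counts over `n_simulations = 5` simulated sequence sets with the same
region-length multiset; λ for a word never seen in any simulation is
floored at 0.5 so the odds ratio stays finite. Word counts are modelled as
Poisson; the over-representation p-value is the upper tail `P(WC ≥ wc)`.
The exact Poisson tail is used for λ ≤ 50 and the Gaussian approximation
`1 − Φ((wc − λ)/√λ)` above. The switch point matters: the Gaussian tail is
classically quoted as usable above λ ≈ 10, but its absolute error only
drops below 0.02 near λ ≈ 50 (Poisson discreteness alone contributes
|Δp| ≈ 0.04 at λ = 10), and the exact tail costs nothing to compute, so
the approximation is reserved for the regime where it is accurate. No
multiple-testing correction is applied and self-overlapping words are not
corrected for; instead candidates are taken below a small p-value
threshold (default 1e-6).

**Shape scores.** For each candidate word (up to `max_scored_candidates`,
default 300, in S_W order) and each signal track, per-bp windows of
±`profile_halfwidth` (default 1000 bp, chosen so ±1 kb histone-mark
flanking structure is visible) around every occurrence midpoint are summed
— minus-strand windows reversed so profiles align in motif orientation —
and discretised into `bin_width` = 25 bp bins (B = 80). The aggregate
φ(X) yields:

* **intensity** S_I = Σφ(X)/wc, the mean window signal per occurrence;
* **kurtosis** S_K: φ is normalised to unit mass and smoothed by zeroing
  all but the lowest ⌈(3/8)·(B/2)⌉ non-negative DFT frequencies (the
  upper 5/8 removed; DC always kept), floored at 0 and renormalised; S_K
  is the excess kurtosis of the smoothed profile read as a probability
  mass over bin positions. A flat profile scores ≈ −1.2 (discrete-uniform
  limit), a sharp peak scores high; the zero-variance degenerate case is
  capped at 50;
* **asymmetry** S_A: symmetrised KL divergence between the left half and
  the *mirrored* right half of the smoothed profile (pseudo-mass 1e-6 per
  bin), so S_A = 0 means mirror symmetry about the motif centre. Mirroring
  is a design choice: binding-site profiles are approximately symmetric
  about the peak, repeat-driven profiles are not.

**Combination.** The four sub-scores live on incommensurable scales (S_I
track-dependent, S_K unitless, S_A in nats, S_W a ratio), so each is
z-normalised across the candidate set before the linear combination
S = β_I·S_I + β_K·S_K + β_A·S_A + S_W; shape features are normalised per
track and averaged across tracks, the asymmetry feature is negated so all
β stay ≥ 0, and S_W enters through its logarithm (a ratio is
location-scale only on the log axis; on the raw scale its heavy,
simulation-noisy upper tail swamps the O(1) shape terms). Default weights
β_I = 0.3, β_K = 0.5, β_A = 0.5 are a portable starting point; the grid
search (`grid_search_betas`) fits them per dataset on a validation split.
Sequence-only mode sets all β = 0, reducing the ranking to S_W.

**From seeds to motifs.** Each of the `top_seeds` (default 30) ranked
words is generalised to a primary PFM by counting all 4·K single-base
substitution variants; multi-mismatch instances are deliberately not
enumerated, which biases weak columns toward the seed base — the
parameter-recovery tolerance (0.05 per cell at 500 instances) accounts for
the conditional depth this implies. Pairwise dissimilarity is
1 − max-Pearson correlation of the flattened overlapping probability
columns over all offsets (overlap ≥ max(4, ⌈L/2⌉): correlations on fewer
than 4 columns are meaningless) and both orientations, with pseudocount
0.25 per cell; pairs with no admissible overlap get a sentinel distance of
2 and are never merged. In signal mode the symmetrised KL between the
motifs' smoothed profiles, rescaled to [0,1) as KL/(1+KL), is mixed in
with weight `beta_cluster` (default 0.2). Average-linkage agglomerative
clustering follows; the cluster count is the smallest k passing the gap
statistic's one-standard-error rule, with B = 20 reference datasets drawn
uniformly on the space of row-normalised L×4 matrices (Dirichlet(1,1,1,1)
rows) and compared by the sequence-only distance — reference matrices have
no signal profiles, so mixing marks into the reference dispersion would be
arbitrary. Setting `cluster_threshold > 0` instead cuts the dendrogram at
that dissimilarity (the "stringent clustering" escape hatch for large K).
Cluster members are star-aligned to the highest-scoring seed via their
stored best offsets/orientations, count matrices summed over the union
span, profiles support-weighted-averaged, and ends trimmed while column
information content < 0.3 bits or column support < 10% of the best column
(never below 4 columns). Output motifs are ranked by support × best member
score; consensus ties render as IUPAC codes.

**Site scanning and evaluation.** Motif PFMs are scanned as log2-odds
against order-0 background frequencies on both strands; same-motif
overlapping hits are greedily resolved to the best-scoring (cross-motif
overlaps are kept — co-factors co-occur). The default threshold is 70% of
each motif's maximum score. Evaluation flanks each summit by 650 bp
(13 bins of 100 bp, central bin centred on the summit): TP = summits with
a site midpoint < 50 bp away, FP = flanking bins containing ≥ 1 site
midpoint, FN/TN the complements (12 flanking bins per summit). The ROC
sweeps relative score thresholds (21 points), anchors (0,0) and (1,1) are
appended, and AUROC is the trapezoidal area. Cross-validation splits the
regions into 10 partitions — 8 train / 1 validation (β selection) / 1
test — and rotates the held-out pair; the top 3 motifs per fold are
evaluated.

## Synthetic data

The generator emulates the statistical structure of ChIP-seq inputs:
background regions from the Markov model; motif instances drawn
column-wise from a known PFM and planted at region centres at a controlled
rate; summits at instance midpoints (optionally jittered); and per-track
signal laid at step resolution (5 bp, keeping bedGraph output compact)
with controlled shape — Gaussian peaks (kurtotic), flat or noisy
baselines, or one-sided exponential (asymmetric) profiles. The standard
benchmark is 2000 regions × 200 bp, uniform order-0 background, one 9-bp
PFM (dominant base 0.85 per column, consensus TCAAGGTCA) planted in 40% of
regions, a DNase-like Gaussian track (σ = 75 bp, amplitude 10, baseline
0.5, noise 0.1) and a flat-noise decoy track. Regions are spaced 1300 bp
apart so the ±650 bp evaluation flanks of neighbouring summits do not
overlap adjacent regions' planted instances — real peaks are far sparser
than the evaluation window. The spurious-word variant plants a tandem
repeat (default CTCTCTCTC) in regions disjoint from the motif's, at the
expected count of the motif *consensus word* (planting rate × dominantᴷ,
discounted for the repeat's self-extension into random flanks), with no
signal peak — so both words are equally over-represented but only one sits
under shaped signal.

What the fixtures do **not** emulate: read-level noise and fragment-size
effects, non-stationary genomic background (CpG islands, repeats beyond
the planted decoy), correlated multi-mark structure, peak-width
heterogeneity, and indirect binding. Passing tests therefore demonstrate
the statistical machinery is correct and that shape information separates
matched-frequency words under controlled conditions — not that the default
β weights are optimal for any particular real dataset.

## Numerical choices and degenerate inputs

* k-mer windows containing N (or soft-masked bases when masking is on) are
  skipped; signal queries outside covered track intervals return 0.0.
* All-zero profiles fall back to uniform with a warning; words without
  occurrences are flagged unscorable.
* Pearson correlation over a constant matrix block is defined as 0.
* Grid-search ties break toward the smallest L1-norm β; cluster ordering
  and all random draws are seeded from the single run-config seed, so
  equal config + inputs give byte-identical outputs.
* Problem sizes in the test suite and acceptance script (20 replicates of
  the 2000×200 bp benchmark, 10^6 bases for background recovery, 1000
  random index fixtures) were chosen to estimate each quantity well inside
  its stated tolerance on a single core.

## Known limitations

* Only single-substitution variants feed a primary PFM, so columns with
  strong secondary bases are under-dispersed relative to the true PFM.
* Seeds of one K per run; composite patterns longer than K appear as
  offset seed clusters and rely on merging to assemble.
* The site scanner is a plain log-odds PWM scanner without p-value
  calibration of match scores; absolute site counts are therefore not
  comparable across motifs of different information content.
* The gap statistic on ~30 seeds of one planted family tends to report
  several fine-grained clusters (shifted variants of the same motif)
  rather than one; ranking by support × score still surfaces the planted
  motif first, and stringent-threshold cutting is available when a single
  merged cluster is wanted.
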