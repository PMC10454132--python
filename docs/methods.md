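# Methods

## Analysis model

The pipeline treats a drought time-course microarray experiment as a
probes × samples grid of non-negative summarized intensities with a
sample design (condition, day, replicate). The default design mirrors a
9-condition shoot series — watered day 2/4, drought day 2, 3, 4, 7, 10,
14, re-watered day 1 — with 3 biological replicates (27 samples).

**Preprocessing.** Replicate means are computed on raw intensities and
then transformed with log2(x + 1); the order matters only marginally
(log of the mean vs mean of logs differ by at most the within-group
log-variance), but the pipeline commits to mean-then-log for
reproducibility. Columns are ordered watered → drought → re-watered,
ascending day. For clustering, each probe's profile is z-scaled to mean 0,
sample sd 1 (n−1); constant rows carry no temporal information and are
dropped with a warning. For network correlations, replicate-level
log2(x + 1) values are used *unscaled*: Pearson r is invariant to per-row
affine maps, and replicate-level data (n = 27) gives the significance
test its degrees of freedom.

**Clustering.** Lloyd's k-means with k-means++ initialization, best of
`restarts` runs (default 50; tests and the acceptance script use 10–20,
which on ~500 × 9 data changes assignments only in pathological draws),
max 300 iterations, tolerance 1e-6, all seeded. Cluster labels are
canonicalized by descending size so reruns are comparable. k is chosen by
the Calinski–Harabasz index; the SSE trace is reported for the elbow
check but does not decide (a single primary criterion keeps selection
deterministic). CH ties prefer smaller k; a zero within-cluster SSE
(perfect separation) is treated as +inf and wins.

**Cluster score.** The membership filter "score ≥ 0.8" is implemented as
the Pearson correlation between a probe's scaled profile and its assigned
centroid — the natural reading of "expression closely matches the
cluster core" — with an alternative (1 − normalized Euclidean distance)
behind `method="distance"`. A constant centroid leaves the score
undefined (NaN), which always fails the filter.

**Anticorrelated pairs.** All unordered cluster pairs with centroid
correlation ≤ −0.8 are reported, most negative first. Because mirrored
temporal programs are common (gradually-up vs gradually-down, etc.),
several pairs typically qualify; the pipeline focuses on the pair whose
clusters contain the seed gene family (e.g. TALE-tagged probes), falling
back to the most anticorrelated pair.

**Network.** Candidate nodes are the score-filtered members of the focal
pair plus all seed-family probes regardless of score (the family of
interest is followed even when noisy). Edges require |r| ≥ 0.6 and
two-sided p ≤ 0.05 from the t transform on n−2 df; no multiple-testing
correction, matching the raw-threshold convention of the source workflow.
Candidates left without edges are dropped and logged (the analysis
surface where attrition like 145 → 140 genes becomes visible). Topology
follows common network-analyzer conventions: local clustering coefficient
2·T(v)/(deg(v)(deg(v)−1)), 0 for degree < 2, averaged over all nodes;
characteristic path length is the mean BFS distance over connected
ordered pairs (disconnected pairs ignored). Hubs are ranked by descending
degree, ties broken by probe id for determinism. Shared-neighbor counts
exclude the seeds from each other's neighborhoods ("shared connections"
read as common partners); the inclusive convention is reported alongside.

**Motif scanning.** IUPAC degenerate words are matched exactly via
character-class regular expressions with a capturing lookahead so
overlapping occurrences are all reported; `N` in the subject never
matches. Both strands are scanned by default (a flag restricts to the
gene-sense strand, since published totals can depend on this convention);
a palindromic site yields two hits at distinct (offset, strand) pairs.
Promoters are anchored at the annotated gene start (no TSS catalog is
assumed): for minus-strand genes the 3000 bp beyond the gene end,
reverse-complemented. Introns are the gaps between consecutive exons of
the chosen transcript (longest mRNA by default, selectable by id),
numbered 5'→3' in transcript orientation. Coordinates are 0-based
half-open internally, 1-based inclusive at GFF3 boundaries; hits export
as BED6 on forward-genome coordinates.

## Synthetic data generator

The generator emulates the study conditions rather than generic noise:

- **Design:** 9 conditions × 3 replicates as above; ~500 genes.
- **Archetypes:** ten temporal programs = five base shapes × (up, down)
  mirror — transient (peak at drought day 4), early (day 2), late
  (day 10–14), re-watering response, and sustained plateau. The base
  shapes were chosen mutually distinct (pairwise |r| ≤ 0.21 after
  centering) so that cluster recovery degrades gracefully as
  heterogeneity grows; the transient up/down mirror pair reproduces the
  anticorrelated cluster pair that drives the analysis.
- **Signal:** on the log2 scale, x = baseline (6.0) + amplitude ·
  (archetype + shape jitter) + N(0, noise_sd); amplitude ~ U(1, 3),
  noise_sd 0.25 (multiplicative on the intensity scale, the standard
  microarray noise model). Stored intensity is 2^x − 1 so log2(x + 1)
  recovers the signal; negative draws (possible only at extreme tails)
  are clipped at 0 and counted.
- **Within-cluster heterogeneity:** each gene deviates from its archetype
  by a fixed-across-replicates "shape jitter" (sd 0.4) drawn in the
  orthogonal complement of the archetype span. This decorrelates genes —
  making the score ≥ 0.8 filter and the |r| ≥ 0.6 edge filter genuinely
  selective (roughly half the focal-cluster members pass, network density
  well below 1) — without displacing any gene toward another centroid, so
  cluster assignments stay recoverable. Real data's heterogeneity is not
  confined to this complement; passing recovery tests therefore shows the
  pipeline recovers structure under realistic score/edge attrition, not
  that it would achieve ARI ≈ 1 on real arrays.
- **Hub:** one gene follows the transient-down archetype exactly (zero
  jitter) at top amplitude with reduced measurement noise (factor 0.2),
  and is measured by four probe rows, as array designs routinely do for
  one transcript. Its 26 "regulator" genes are ordinary transient-up
  genes tagged into the seed family. The hub's clean profile keeps edges
  to marginal partners that noisier peers lose, so one of its probes
  attains the maximum degree in ≈ 19 of 20 seeded runs — the analysis
  signature by which a repressor target surfaces as the main hub. This
  statistic remains stochastic: occasional seed blocks yield 18 or 17.
- **Sequences:** contigs are built from a CA-repeat background that
  cannot contain a motif match on either strand; planted concrete words
  (drawn from each motif's expansion, reverse-complemented for
  minus-strand plants) are flanked by a TT spacer because a word abutting
  the background can otherwise complete a spurious site (e.g. the
  TGATGGGA tail GGA + CA… forms GGACA, a KGACM word). Every placement is
  re-scanned locally, and the finished gene is scanned globally; any
  discrepancy from the planted truth aborts generation, so scanner tests
  compare against exact ground truth.

## Numerical and interface choices

- All randomness flows from explicit integer seeds; identical config +
  seed reproduces every artifact byte-identically (reports contain no
  timestamps).
- Expression TSVs round-trip bit-exactly (17 significant digits); `.` or
  an empty cell is missing, and probes with missing values in the
  selected sub-matrix are dropped (complete-case) with a warning.
- Degenerate guards: k = n−1 on distinct points gives CH = +inf
  (perfect separation wins); |r| = 1 gives p = 0 without evaluating the
  t transform; constant series are excluded from correlation rather than
  propagating NaN.
- Problem sizes in tests and the acceptance script (500 genes, 20 seeds,
  50 motif layouts, 10–20 k-means restarts) keep the full run in well
  under a minute while leaving every statistic's sampling behavior
  visible.

## Known limitations

- No probe-level Affymetrix modelling (RMA/MAS5), batch effects, or the
  full covariance structure of real arrays; the generator plants exactly
  one program per gene.
- Promoters anchor at the gene start, not a measured TSS.
- "Robust pairwise correlation" is implemented as plain Pearson on
  replicate-level values; no outlier down-weighting.
- No multiple-testing correction on edge p-values and no soft
  thresholding (WGCNA-style) — by design, to match the source workflow's
  conventions.
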