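# Methods

## The analysis model

The pipeline consumes two per-gene differential-expression contrasts for the
same gene universe — postdauer vs control after pheromone-induced dauer
(Phe) and after starvation-induced dauer (Stv) — and asks where, and how
strongly, genes respond in *opposite* directions to the two early-life
stresses, and how those genes are arranged along the chromosomes.

**Quadrants and seesaw calls.** Each gene's pair of log₂ fold changes
defines a quadrant: Q1 = Phe up / Stv down, Q2 = both down, Q3 = Phe down /
Stv up, Q4 = both up; a fold change of exactly 0 is labelled BOUNDARY and
excluded from quadrant tallies and trend sets (the exactly-zero case is not
addressed by the directional definitions, and exclusion is the conservative
choice; the count of such genes is always reported). *Significant* seesaw
genes must pass the FDR cutoff (Benjamini–Hochberg q < α, default 0.05)
independently in both contrasts with opposite fold-change signs — no
combined cross-condition test is used. A non-default `loose` variant
(significance in one contrast plus an opposite-signed change in the other)
is provided for sensitivity analysis. *Trend* seesaw genes need only an
inverse change of at least `min_fold` (default 2; threshold inclusive,
|log₂FC| ≥ 1), ignoring significance — this is the class used for the
spatial analyses, where power matters more than per-gene error control.
Reported percentages are rounded half-away-from-zero, which reproduces
conventional manuscript rounding (e.g. 249/441 → 56%).

**Overlap null.** The excess of seesaw genes over chance is quantified by
randomization: each of S replicates (default 10,000) re-draws *both* gene
sets, at their observed sizes, uniformly without replacement from the
universe and records the intersection. Re-drawing both sets rather than
fixing one is the procedure as described; the intersection size is
distributed hypergeometrically either way, which is why the analytic
moments (mean n₁n₂/N, hypergeometric variance) can serve as an exact oracle
for the simulation. The empirical p is the ≥-tail fraction with no +1
correction; zero exceedances are reported as "< 1/S" rather than 0. The
universe defaults to the genes quantified in both DE tables but is exposed
as a parameter: the published fold enrichments for this kind of analysis
are sensitive to the universe choice, and no single universe size
reconciles all printed values, so the package treats N as an explicit input
rather than a constant.

**Chromosomal bias.** For each chromosome, a 2×2 table (class genes on the
chromosome vs elsewhere, against non-class genes) is tested with a
Yates-corrected χ² (continuity correction clamped at zero, 1 df). A
one-sample variant against gene-count-proportional expectations is
available behind `method="proportional"`, since bias tests of this kind are
described both ways in the literature; the 2×2-vs-rest form is the default
because it is the more completely specified procedure. No multiple-testing
correction is applied across chromosomes by default (per-chromosome stars
are the convention being reproduced); `bh_fdr` can be applied to the
returned p-values.

**Sliding windows.** Windows of 2.5 Mb advance in 500 kb steps from
position 0 while the window start is inside the chromosome; terminal
windows are truncated and flagged. A gene belongs to a window iff its
midpoint lies in [start, end) — midpoint assignment avoids double counting
at window edges beyond the intended overlap. Enrichment is the in-window
class fraction over the genome-wide class fraction; windows with fewer than
`min_genes` (default 10) genes are NA rather than producing unstable
ratios.

**Attribute clustering (GLC-style).** A cluster is a maximal run of
attribute-flagged genes, within one chromosome, in which consecutive
attribute genes are separated by at most `max_gap` non-attribute genes, and
which contains at least `min_size` attribute genes. Cluster size counts
attribute genes only. The published description of this algorithm pins down
only the minimum cluster size (3) and the randomized-gene-order null; the
gap-tolerant maximal-run definition here is an explicit reconstruction, with
`max_gap` configurable (default 2, which at attribute densities around 20%
yields cluster-size spectra dominated by 3–10-gene clusters, the regime the
original analysis reports). Significance: each of S replicates permutes the
attribute labels uniformly over gene positions (gene order and chromosome
assignment fixed) and re-clusters; folds and empirical p are computed for
both the number of clusters and the number of clustered attribute genes.
The clustered-gene count is the more robust statistic: when planted or real
clusters are dense enough to merge across small gaps, the *cluster count*
can fall below its null mean even as clustering is overwhelming, so
enrichment claims should rest on the clustered-gene fold.

**Operons.** Operon membership of a gene set is a simple count plus
percentage. Per-operon direction is the quadrant of the *mean* member log₂
fold change in each condition (operons are co-transcribed, so the mean is
the natural operon-level effect); operons with no quantified member are
skipped and logged, and a mean of exactly 0 in either condition gives
BOUNDARY.

**QC.** Replicate agreement is Pearson r on log₂(count+1); raw-count mode
exists behind a flag because untransformed counts make r mean-dominated.
The p-value uses the t-transform with df = n−1 in "paper" mode (matching
the convention printed in the replicate panels being reproduced) or the
conventional df = n−2 in "standard" mode; both are available because the
n−1 convention, while printed, is nonstandard. PCA retention works on the
eigenvalues of the samples×samples correlation matrix of log₂(count+1)
expression (zero-variance genes dropped and counted): the Kaiser criterion
retains λ > 1 (strict, as defined for correlation matrices) and the
broken-stick model retains components whose variance share exceeds
b_k = (1/p)·Σ_{i=k..p} 1/i. Germline enrichment compares FPKM
(counts·10⁹/(length·total)) between a wild-type-like and a
germline-ablated-like strain: ratio = (FPKM_ablated + c)/(FPKM_wt + c) with
pseudocount c = 0.1; genes with ratio ≤ 0.5 are germline-enriched and genes
with FPKM_wt ≤ c are undetermined. The 0.5/0.1 pair is an explicit,
monotone surrogate for "substantially decreased", with both knobs exposed;
classification is monotone in the threshold, so enriched sets nest.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, at
the scale of the real experiment, with a per-gene truth table.

* **Genome**: six chromosomes named I–X with default lengths (Mb) 15.1,
  15.3, 13.8, 17.5, 20.9, 17.7 — realistic window counts without any
  download. Genes are non-overlapping intervals with lengths uniform in
  1–4 kb. (Mean 2.5 kb at the default 18,570 genes occupies ~46% of the
  100 Mb genome; a wider length range cannot be packed without overlap at
  this gene count, and only the ordering and midpoints of genes matter to
  any analysis.) Placement: a desired relative midpoint is drawn per gene —
  uniform for null/concordant classes, symmetric Beta(a, a) with
  a = 1 + 9·`central_concentration` for the planted seesaw classes (so 0 is
  exactly uniform) — on a chromosome drawn with probability ∝ class weight ×
  chromosome length; overlaps are resolved by a forward/backward sweep that
  preserves approximate positions, and infeasible packings raise.
  Default weights place the Phe-up::Stv-down class preferentially on
  chromosomes I and III and the inverse class on II, V and X, mirroring the
  chromosome-scale asymmetry the landscape analyses are designed to detect.
* **Classes**: 500/18,570 genes are planted significant seesaw genes (split
  evenly between the two orientations), 2% concordant, the rest null. Null
  genes receive zero-centered effects with |log₂FC| ~ |N(0, noise_sd)| and
  opposite signs across the two tables with probability
  `inverse_trend_fraction` (default 0.671), planting the genome-wide
  inverse-trend excess among non-significant genes.
* **Effects and p-values**: planted-class magnitudes are
  `location + scale·|N(0,1)|` (defaults 1.5 + 0.3·|N|) — a shifted
  half-normal whose minimum is the location parameter. Planted
  "significant" genes model genes a well-powered experiment calls at
  FDR < 5% in both contrasts, so their effects are kept unambiguously above
  the detection boundary; marginal effects belong to the null/trend layer.
  p = 2·Φ(−|log₂FC|/noise_sd) is a normal-tail surrogate (null p-values
  exactly uniform, monotone in effect size), not an edgeR replica — the
  pipeline consumes DE tables, so only those two properties matter. q is BH
  within each table.
* **Attribute genes** (CSR-1-target-like): 21% of genes, planted as runs of
  3–10 adjacent genes (gap 0 by default) with the overall budget
  apportioned to chromosomes ∝ weight × gene count (default 4× on I and
  III), so per-chromosome fractions hit their targets deterministically.
  Attribute genes double as the germline-enriched truth set, as the real
  attribute set is germline-defined.
* **Operons**: runs of adjacent same-strand genes; a renewal walk starts an
  operon with probability q = f/(E[s](1−f)+f) per gene, making the expected
  in-operon fraction equal the configured f (default 0.15, sizes 2–3).
* **Counts**: gamma-Poisson with variance μ + dispersion·μ² (dispersion
  0.05; 0 gives Poisson), gene means lognormal (ln-scale location 5, sd
  1.5 — a median count near 150, i.e. typical bulk RNA-seq depth, which is
  what makes replicate correlations Poisson-limited rather than
  depth-limited), replicates sharing means; the germline-ablated-like
  strain scales germline-gene means by 0.2. FPKM vectors are computed from
  replicate-summed counts.
* **Determinism**: one master seed spawns per-stage child seeds via
  `numpy.random.SeedSequence(seed).spawn()` in the fixed order placement,
  operons, attribute, DE, counts; identical configs give bit-identical
  artifacts, and each stage is reproducible in isolation.

What the generator does *not* emulate: mappability and GC biases, gene
families and correlated expression modules, length-dependent power,
unbalanced libraries, and any real linkage between operon membership and
expression class. Recovery tests on this fixture therefore demonstrate that
the estimators are correct and calibrated under the planted model, not that
the biological effect sizes of any real dataset are recoverable.

## Problem sizes and numerical choices

The shipped tests run the randomization machinery at S = 10,000 for the
single-oracle comparisons and S = 1,000 per run for the 200-run calibration
sweeps, and exercise recovery on the full 18,570-gene fixture; the
acceptance script uses S = 10,000 throughout (configurable via `--sims`).
Fisher two-sided tails aggregate point probabilities with a 1 + 1e−7
relative tolerance, the Yates correction clamps |O−E|−0.5 at zero, BH
q-values are clipped to 1, fold enrichments against a zero null mean are
NaN (flagged, never a crash), and empty windows or gene lists degrade to
NA/warnings rather than errors. Empirical p-values are never reported as 0:
zero exceedances print as "< 1/S".

## Known limitations

* The exact published clustering algorithm is unpublished; parameter
  choices other than min_size = 3 are reconstructions (see above).
* The 2×2-vs-rest and proportional chromosome-bias tests can disagree for
  small classes; only the former is default-reported.
* The overlap fold depends on the universe N, which must be supplied
  thoughtfully when reproducing published folds.
* Operon-level quadrants weight all quantified members equally; no
  expression-level weighting is attempted.
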