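# Methods

## The model

Each cell's expression over a small myosin panel is modelled as driven
by two correlated latent programs — fast-twitch and slow-twitch
authenticity. With z the z-scored `log2(RPM + 1)` expression of the
panel genes,

    z = Λ f + e,    Cov(f) = Φ,    Cov(e) = diag(u²),

so the panel correlation matrix decomposes as R = ΛΦΛᵀ + diag(u²).
Λ are oblique pattern loadings, Φ the factor correlation, h²ᵢ = [ΛΦΛᵀ]ᵢᵢ
the communality of gene i and u²ᵢ = 1 − h²ᵢ its uniqueness. The factors
are deliberately allowed to correlate: fast and slow identity are not
orthogonal in a mixed tissue (hybrid fibers express both programs,
non-myofiber cells neither), and the fitted Φ is indeed negative on
typical data.

Assumptions worth stating: linearity of the factor model on the log
scale, approximately continuous scores (the panel genes are expressed
broadly enough after normalization that z-scoring is meaningful), and a
panel small enough that every gene is interpretable. A two-indicator
factor (the slow program has only *Myh7*/*Myh7b* in the default panel)
is weakly identified on its own; identification here leans on the
cross-block correlations, and the split of communality between the two
slow genes is the least stable quantity of the fit.

## Pipeline stages and parameters

**QC** (`qc_filter`): removes cells with total counts ≥ `count_cutoff`
(default 5000, boundary inclusive) or mitochondrial fraction ≥
`mito_cutoff` (default 0.10). The count rule removes *high*-count cells
by default — probe-based fixed-cell chemistry puts doublet-like
artifacts at high totals; a `count_filter = "lt_removes"` switch inverts
the direction for reanalyses that want a depth floor instead. No lower
count bound is applied by default. Zero-total cells are always dropped.
Mitochondrial genes are recognized by the case-insensitive mouse prefix
`mt-` unless an explicit mask is given.

**Normalization** (`normalize_log_rpm`): v = log2(count / total × 10⁶
+ 1). The denominator is the per-cell total over all genes surviving
QC, before any panel subsetting — RPM is a library-size concept. Zero
counts map to exactly 0.

**Panel construction** (`rank_similar_genes`): candidate genes are
scored by the Jaccard index of their GO-term sets against the seed
markers, aggregated by `max` over seeds by default — a gene needs to
resemble only one seed to be a myosin relative worth including (`mean`
is available). All GO aspects and evidence codes count. Ties break
lexicographically so the ranking is a total order. Selection is by
`top_k` (default 3, which on the designed annotation fixture yields
exactly *Myh7b*, *Myh11*, *Myh3*) or by a `min_score` cutoff.

**Factor count** (`parallel_analysis`): Horn's method — observed
correlation eigenvalues are compared rank-by-rank against the 95th
percentile (configurable) of eigenvalues from 100 (configurable)
standard-normal datasets of the same shape; retention stops at the
first observed eigenvalue that fails to exceed its null quantile.

**Extraction** (`extract_factors`): minimum-residual — the off-diagonal
squared residual of R − ΛΛᵀ is minimized over the uniquenesses with
L-BFGS-B on [0, 1] bounds (allowing exact-boundary solutions for
noiseless data), loadings taken from the leading eigenpairs of
R − diag(ψ). Principal-axis iteration is available as `method="paf"`.
Maximum-likelihood extraction is deliberately not offered; minres is
the common default in psychometrics tooling and needs no normality
assumption.

**Rotation** (`rotate_quartimin`): quartimin, i.e. oblimin with γ = 0,
minimizing Q(Λ) = Σᵢ Σ_{k≠l} λ²ᵢₖ λ²ᵢₗ by oblique gradient projection
(Jennrich's algorithm: project the gradient onto the manifold of
unit-column oblique rotation matrices, backtracking line search).
Ten restarts from seeded random starting rotations guard against local
minima. The rotation preserves ΛΦΛᵀ and the communalities to < 1e-8 by
construction; tests assert it.

**Scores** (`score_factors`): regression (Thurstone) scores
F = Z R⁻¹ (ΛΦ); Bartlett scores are available by config. Factor columns
are ordered fast first, slow second (via the seed-loading mapping) and
oriented so seed loadings are positive.

**Classification** (`propose_thresholds`, `classify_cells`): the four
classes are the quadrants of (F_fast ≥ τ_fast, F_slow ≥ τ_slow), with
the boundary counting as positive — determinism needs a rule and the
choice is symmetric. Thresholds supplied in the config are used
verbatim and recorded as provenance "manual" (the reference workflow
for this analysis sets them by eye from the score histograms);
otherwise each score's Gaussian KDE is scanned for its two most
prominent modes and the threshold placed at the density minimum
between them, falling back to the 1-D 2-means midpoint with a warning
when the density is unimodal. Automatic proposal requires ≥ 20 cells.

**Profiling** (`cluster_subpopulation`, `find_sigups`, `name_clusters`,
`condition_proportions`, `combine_clusters`): clustering is PCA (≤ 30
components) → kNN graph (default 15 neighbors, clamped for tiny
inputs) → Leiden modularity optimization (RBConfiguration, resolution
default 1.0, fixed seed). Sigups are genes with one-sided one-vs-rest
Wilcoxon rank-sum BH-adjusted p < α (default 0.05) and log2
fold-change ≥ `min_lfc` (default 1.0) in the cluster. Names follow the
grammar: unique sigup set with top-fold-change gene G → `G+`; clusters
sharing a name → `G+(1)`, `G+(2)`, … indexed by descending size; empty
sigups → `Unknown`, indexed likewise. Clusters with *identical* sigup
sets share a base name by construction; clusters with different sets
whose top genes coincide are disambiguated by the same indexing, which
is required for names to be unique identifiers in the output tables.
Proportion tables normalize within condition; `combine_clusters` sums
designated clusters' fractions per condition (the slow-typical
summary). UMAP embeddings are presentation only; nothing downstream
depends on them and none is computed in the pipeline.

**Atrophy markers** (`compare_marker_expression`): *Fbxo32* and
*Trim63* are compared across condition pairs by two-sided rank-sum
tests with BH correction — a negative control in the default synthetic
conditions, where no condition effect is planted on them.

## The synthetic-data generator

The generator emulates a probe-based fixed-cell scRNA-seq experiment on
a predominantly fast-twitch muscle across three conditions (`Ctrl`,
`P`, `P_PG`). Per condition it draws cell classes from a mixture
(default fast 0.40, slow 0.25, hybrid 0.15, negative 0.20), with the
slow-class weight multiplied by `slow_depletion` (default 0.5) in the
diseased condition `P_PG` before renormalization — the planted effect
the profiling stage must recover. Hybrid cells express both programs at
full intensity, negative cells neither, giving unambiguous ground truth.

Counts are gamma-Poisson: gene means are base weights times
2^`program_mean_lfc` (default 4) when the gene's program is active,
scaled by a log-normal library-size factor (baseline ~800 counts for a
program-negative cell, sdlog 0.3), then drawn negative-binomially with
dispersion α = 0.5 (var = μ + αμ²). Because the library factor
multiplies all means, the program fold-change is preserved in
expectation and cells expressing programs simply have more RNA.
Mitochondrial expression is a dedicated `mt-` gene block sized to a
per-cell target fraction (normal cells: mean 0.03, sd 0.01 — kept well
clear of the 10% QC rule so that, even with count noise, essentially
only designated outliers cross it). A fraction `outlier_frac` (default
0.10) of cells is planted to violate QC, alternating high-count
(expected totals ~9000) and high-mito (fraction 0.15–0.35) flavors.
Default size: 750 cells per condition, ~2000 cells after QC.

All randomness flows from one seed through a single counter-based
Philox stream over cells in fixed order; two runs with the same config
are byte-identical on disk.

What the generator does **not** emulate: ambient RNA, doublets beyond
the hybrid class, batch effects, gene–gene correlation beyond the
class programs and library size, UMI saturation, or probe-level
chemistry. Passing tests therefore demonstrate that the pipeline's
logic and statistics behave correctly under the assumed generative
structure — not that real muscle data will show the same cluster
counts or effect sizes.

The GO-annotation fixture realizes designed term overlaps exactly
(each gene copies a fixed fraction of its anchor's terms and fills the
rest with fresh ids), so Jaccard values are exact set arithmetic; the
default design makes *Myh7b*, *Myh11*, *Myh3* the top three non-seed
candidates.

## Numerical choices and degenerate inputs

- Variables are z-scored per gene (ddof 1) before correlation and EFA;
  a constant gene raises an error naming the column.
- Singular correlation matrices: KMO accepts an optional ridge;
  without it, a singular matrix raises.
- minres communalities are clipped to [0, 1]; Heywood cases surface as
  exact 0/1 uniquenesses rather than being silently repaired.
- Parallel analysis with all observed eigenvalues above threshold
  retains p factors; with a leading failure retains 0 (the model fit
  then falls back to 1 factor with a warning).
- Empty QC output is a hard error advising config review, not an empty
  matrix propagated downstream.
- Problem sizes in the test suite (2,250 simulated cells, 100-seed
  calibration loops at 500×7, 200-permutation sigup nulls at 120×40)
  are chosen so the full suite completes in well under a minute while
  leaving binomial/Monte-Carlo margins comfortably wider than the
  effects being detected.

## Known limitations

- The slow factor rests on two indicator genes; its communality split
  is weakly identified (see above). A larger panel stabilizes it.
- Automatic thresholds assume the score distribution is at least
  bimodal per axis; heavily imbalanced mixtures may need manual τ.
- Leiden clustering of an essentially homogeneous subpopulation
  produces noise partitions (typically named `Unknown(k)` or after
  mitochondrial genes); cluster counts on such data are not
  biologically meaningful, and no attempt is made to reproduce any
  particular cluster count from real tissue.
- The proportion analysis is descriptive (tabulation and combination);
  no compositional significance testing is performed.
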