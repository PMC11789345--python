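# fiberfa

Factor-analysis fiber typing for skeletal-muscle single-cell RNA-seq.

Skeletal muscle mixes fast-twitch fibers (marked by *Myh1*, *Myh2*,
*Myh4*), slow-twitch fibers (*Myh7*), hybrid fibers expressing both
myosin programs, and non-myofiber cells. `fiberfa` implements a complete
workflow for quantifying this mixture from a gene-by-cell count matrix
and for tracking how the slow-twitch compartment shifts across
experimental conditions (e.g. a control group versus disease models):

1. **QC + normalization** — cells with ≥ 5000 total counts or ≥ 10%
   mitochondrial counts are removed, then counts become
   `log2(RPM + 1)` with RPM = count / cell total × 10⁶.
2. **Marker panel by GO similarity** — starting from the seed markers,
   other genes are ranked by the Jaccard index
   `J(A, B) = |A ∩ B| / |A ∪ B|` over their GO annotation sets; the top
   candidates (the myosin relatives *Myh7b*, *Myh11*, *Myh3*) join the
   panel.
3. **Exploratory factor analysis** — on the z-scored panel the model

   `z = Λ f + e,  Cov(f) = Φ,  R = Λ Φ Λᵀ + diag(u²)`

   is fitted by minimum-residual extraction with oblique **quartimin**
   rotation; the number of factors comes from Horn's **parallel
   analysis** and sampling adequacy is reported as **KMO/MSA**.
   Factors are mapped to fiber types by their seed-gene loadings, and
   regression (Thurstone) factor scores `F = Z R⁻¹ Λ Φ` give every cell
   a fast score and a slow score.
4. **Four-way classification** — thresholds τ_fast, τ_slow on the two
   scores (read off the score histograms, or proposed automatically at
   the density valley between modes) split cells into double-negative,
   fast, slow and double-positive.
5. **Subpopulation profiling** — within the fast and slow classes:
   Leiden clustering on a kNN graph over principal components,
   per-cluster significantly upregulated genes ("sigups", one-vs-rest
   rank-sum + Benjamini–Hochberg + fold-change floor), sigup-based
   cluster names (`Ckm+`, `Ckm+(1)`, `Unknown(2)`, …), per-condition
   cluster proportions and combined fractions of designated clusters.

A fully specified synthetic-data generator (negative-binomial counts,
four latent classes, mitochondrial block, planted slow-class depletion
in a diseased condition, QC outliers, per-cell ground truth) makes the
entire workflow testable without any deposited dataset.

## Worked example

```python
import fiberfa as ff

res = ff.run_pipeline(seed=3)        # simulates inputs, runs all stages
print(res.factors.summary())
```

```
Fiber-type factor analysis
============================================================
cells: 2031   panel genes: 7   factors: 2
overall KMO: 0.719

Pattern loadings (oblique), communalities, uniquenesses:
 gene   fast   slow    h2    u2   MSA
 Myh1  0.628 -0.019 0.406 0.594 0.766
 Myh2  0.614 -0.032 0.397 0.603 0.767
 Myh4  0.684  0.024 0.452 0.548 0.748
 Myh7 -0.077  0.610 0.424 0.576 0.661
Myh7b  0.028  0.806 0.629 0.371 0.654
Myh11 -0.214 -0.138 0.036 0.964 0.678
 Myh3 -0.238 -0.074 0.045 0.955 0.795

Factor correlations (Phi):
       fast   slow
fast  1.000 -0.483
slow -0.483  1.000
```

Parallel analysis retains exactly two factors (observed eigenvalues
2.33 and 1.19 against null 95th-percentile thresholds 1.11 and 1.07);
the fast seeds load on factor "fast", the slow program genes on
"slow", and the neutral myosins *Myh11*/*Myh3* on neither — their
communalities stay below 0.05. Classification and the per-condition
class balance:

```python
print(res.assignment.counts())
#  fast 888, slow 497, double_negative 428, double_positive 218
print(res.class_proportions.fractions.round(3))
```

```
label      double_negative  double_positive   fast   slow
condition
Ctrl                 0.192            0.120  0.419  0.269
P                    0.193            0.082  0.405  0.320
P_PG                 0.247            0.120  0.488  0.145
```

The slow-class fraction drops from 0.27 in `Ctrl` to 0.15 in the severe
condition `P_PG` — the generator plants exactly this depletion (the
slow-class weight is halved there), and the pipeline recovers its
direction. `res.write(out_dir)` writes `loadings.tsv`, `scores.tsv`,
`classes.tsv`, `clusters.tsv`, `sigups.tsv`, `proportions.tsv` and
`report.json` (the audit trail with thresholds and seeds).

The same workflow runs from the shell on real or simulated files:

```sh
fiberfa simulate --seed 5 --out sim/
fiberfa run --counts sim/matrix.mtx --features sim/features.tsv \
    --barcodes sim/barcodes.tsv --meta sim/meta.tsv --seed 5 --out results/
```

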