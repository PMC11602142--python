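# fragilib

Sequence-intrinsic DNA fragility analysis: where, and why, does genomic
DNA tend to break?

DNA double-strand breaks are not uniformly distributed — the local
sequence influences breakage across every breakage process, from
enzymatic cleavage and mechanical shearing to endogenous physiological
breaks and the slow decay of ancient DNA. `fragilib` provides the
machinery to quantify that influence from nothing but sequence:

* **Range of influence.** Breakpoints are aligned as strand-invariant
  inter-base *bonds*; canonical k-mer frequencies are profiled at every
  offset within a 1 kb window and adjacent offsets are compared by RMSD.
  A sequence-driven process shows a characteristic central peak, which
  is deconvolved into up to three zero-mean Gaussian components plus a
  baseline, `y(d) = c + Σⱼ aⱼ exp(−d² / 2σⱼ²)`. Each component's 95% CI
  width (3.92 σ) defines a short-, medium- or long-range span of
  influence; its peak fraction `aⱼ / Σa` defines its contribution.
* **Intrinsic k-meric susceptibility.** Broken k-mers are compared
  against control regions placed beyond the long-range span plus 1 kb,
  through the one-sample proportion z-score
  `zᵢ = (Xᵢ − n pᵢ) / √(n pᵢ (1 − pᵢ))`
  (Xᵢ the case count of canonical k-mer i, n the total case count, pᵢ
  the control proportion), with a Bayes posterior
  `P(break | kmer) = P(break) · P(kmer | break) / P(kmer)`.
  Strand symmetry collapses the 65,536 octamers to 32,896 canonical
  classes; sparse k-mers are imputed from their five nearest neighbours
  by sequence similarity.
* **Fragility classification.** Candidate bonds become feature vectors
  over nested windows — the centred octamer's susceptibility scores
  (short range), putative G-quadruplex density (medium range), and G+C
  content, GC-skew magnitude, raw and z-weighted k-mer counts (long
  range) — and feed an L2 logistic or LightGBM classifier tuned by
  seeded random search, evaluated by AUROC, and calibrated to target
  false positive rates. The trained model supports sliding-window
  genome scans, hot/cold fragility zoning (top/bottom 5% of binned
  break density), and before/after delta fragility of structural
  variants over a 1,960-base context.
* **Synthetic fixtures.** A seeded generator plants octamer-level
  breakage propensities with short/medium/long Gaussian placement
  envelopes in random genomes, so the entire pipeline is testable with
  known ground truth and no downloads.

## Worked example

```python
import fragilib as fl

# a 200 kb synthetic genome with planted octamer-level fragility
genome = fl.simulate_genome(200_000, gc=0.41, seed=1)
truth = fl.FragilityGroundTruth.random(1, effect_sd=2.5, sigmas=(0.0,),
                                       weights=(1.0,), baseline=0.1)
breaks = fl.simulate_breakpoints(genome, truth, 2000, seed=2)

# k-meric susceptibility scores from paired case/control counts
case, control = fl.simulate_count_tables(
    truth, 5_000_000, 50_000_000, seed=3,
    background=fl.background_octamer_frequencies(genome),
)
table = fl.impute_sparse_kmers(fl.fragility_zscores(case, control))
print("most susceptible octamer:", table.z.idxmax(), f"z = {table.z.max():.1f}")

# features -> gradient-boosted fragility classifier
extractor = fl.FeatureExtractor(score_tables={"planted": table})
matrix = fl.assemble_feature_matrix(genome, breaks, extractor, seed=4)
model = fl.train_classifier(matrix, kind="gbm", search_budget=3,
                            cv_folds=2, seed=1, extractor=extractor)
report = fl.evaluate(model, matrix.iloc[model.test_index])
print(f"held-out AUROC = {report.auroc:.3f}, accuracy = {report.accuracy:.3f}")

# scan a fresh sequence for fragile bonds
scan = fl.scan_sequence(model, genome.sequences["chrS"][:5000], stride=10)
print(f"scanned {scan.positions.size} bonds, mean P(break) = {scan.probabilities.mean():.3f}")
```

prints

```
most susceptible octamer: GTCTTTGA z = 37525.2
held-out AUROC = 0.965, accuracy = 0.903
scanned 500 bonds, mean P(break) = 0.199
```

The octamer z is huge because it is computed from 5×10⁶ case
observations against a planted 10²-fold propensity spread — on real
data, scores land in the familiar ±tens. The AUROC says the classifier
recovers the planted fragility from sequence alone; the scan shows the
per-bond probabilities a genome-wide fragility map is built from.

A CLI mirrors the library (`fragilib simulate | rmsd | fit-ranges |
score-kmers | features | train | scan | zones | sv-delta | network`,
plus `fragilib io merge|subtract`); run `fragilib --help`.

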