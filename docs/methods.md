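# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `inkms`, and what the synthetic benchmark does and does
not establish about real manuscript data.

## Data model

One sample = one direct-infusion acquisition: a short series of MS1 scans
of the same extract, no chromatography. The unit of analysis is the
consolidated per-file peak list. Samples carry manifest metadata
(document, author, substrate `ink`/`paper`, replicate index, blank flag);
solvent blanks are extraction solvent processed without touching a
document and define the contamination background.

Input must be centroided; profile spectra are rejected rather than
peak-picked (vendor conversion is assumed upstream). MS2 scans are
ignored. The mzML reader is a compact spectrum-list parser
(64/32-bit float arrays, zlib or no compression, namespace-agnostic); the
matching minimal writer exists so synthetic corpora can round-trip
through the same path.

## Trace consolidation

A mass trace is an m/z value consistently present across the infusion.
Scans' centroids are pooled and clustered with the same greedy
running-mean rule used for cross-file alignment (scan index in place of
file id), each scan keeps its most intense member per trace, and traces
present in fewer than `min_scan_fraction` (default 0.5) of scans are
dropped. Trace intensity defaults to the mean over contributing scans;
`sum` and `max` are available. Using one fully specified clustering
algorithm for both consolidation and alignment keeps the whole pipeline
oracle-testable; a chromatography-style trace detector would add free
parameters without adding information to an infusion experiment.

## Normalization

Each file's intensities are divided by the file total and scaled by 1000
("total usable signal" normalization), making intensities per-mille
relative abundances. Normalization runs on the consolidated trace list —
after consolidation, before alignment — so the denominator is the usable
(trace-level) signal rather than raw centroid counts. Re-normalizing a
normalized file is an error, not a no-op: double division by 1000 would
silently corrupt scale. Empty files normalize to empty with a warning;
zero total with nonzero peaks is an error.

## Alignment

Pooled peaks are sorted by m/z (ties: sample id lexicographic, then
intensity descending — the pooled order is otherwise undefined and
determinism requires a convention) and scanned once. A peak joins the
open peakset iff it lies within `ppm_tol` (default 5) of the arithmetic
mean of already-admitted members; the mean is maintained as a running
sum/count so it is the exact arithmetic mean at every step. Deduplication
(most intense per file, ties to lower m/z) runs after all peaksets are
closed and recomputes the mean from survivors; it does not influence
admissions. Missingness is explicit (NaN), never zero, until imputation.

A consequence of the admission rule is that a deduped peakset's pairwise
spread stays within twice the tolerance — *provided clusters do not
chain*. When within-feature dispersion approaches the tolerance the
running mean drifts and spread can exceed that bound; at the 1 ppm jitter
regime the generator emulates, chaining is absent and the bound holds.

## Screening and differential statistics

Two rules with different jobs:

* **Inclusion rule** (classification): feature present in ≥ `min_present`
  (default 3) non-blank samples and absent from every blank. With no
  blanks in the manifest the blank clause is vacuous (warning, not
  error).
* **Differential analysis**: run on the *unfiltered* matrix so each
  feature keeps a meaningful blank-presence flag. Missing cells are
  imputed with 10⁻⁵ (far below any normalized intensity), values logged
  (base 10 by default; the t statistic is scale-invariant so the base
  only affects reported means), and each feature tested with Welch's
  two-sample t — chosen over the pooled-variance variant because group
  sizes and variances are not guaranteed equal; the choice is
  configurable in spirit by substituting `t_test_feature`. p-values are
  BH-corrected (step-up; missing p propagates missing q and does not
  count toward the number of tests). The diagnostic shortlist is
  q < `q_threshold` (default 0.05) ∧ blank-free, sorted by q.

Degenerate variance: both groups constant → t = 0, p = 1 when means
agree, |t| = ∞, p = 0 otherwise (avoids NaN propagation); groups smaller
than 2 are untestable (NaN t and p, flagged by the missing q).

Stratified comparisons (ink vs ink, paper vs paper) are available via the
`substrate` argument; the default pools substrates, mirroring the
combined analysis.

## Classification

Leave-one-document-out: each fold's test set is every sample of one
document, so technical replicates never straddle the split — the
evaluation imitates scoring a newly surfaced document. Folds with a
single author class in training are rejected (needs ≥ 2 documents per
author).

The classifier is an RBF-kernel SVM with C = 10⁸, emulating a hard
margin while remaining solvable when data are only quasi-separable.
"Automatic" kernel width is γ = 1/(p · Var(X_train)) (the standard scale
heuristic, deterministic); a fixed γ is available. Missing values
entering the classifier are imputed and logged exactly as in the
statistics stage.

By default the inclusion rule is recomputed per fold from training
samples only (blank columns, which belong to no fold, are used globally)
— this avoids test-set peeking. `global_filter=True` instead filters
once on the full matrix before CV, reproducing the study-style global
filter; both are tested.

**Pooled-score calibration.** Holding out one document unbalances the
training classes, and for a quasi-hard-margin fit on weakly informative
features every training point sits at the margin, so each fold's test
scores inherit an offset equal to the training class imbalance. Pooling
raw scores across folds then ranks samples by fold composition rather
than evidence — the leave-one-group-out "anti-learning" artifact, which
drives null-data AUC far below 0.5. `crossval` therefore centres each
fold's test scores by the fold model's mean decision value over its own
training samples (`calibrate_scores=True`). On signal-free corpora this
restores mean AUC ≈ 0.5; on signal corpora it leaves AUC unchanged.

ROC/AUC: scores pooled across folds (real-valued decision values, not
binary predictions — few-sample binary pooling cannot produce
intermediate AUCs), tied scores grouped, trapezoidal area; equals the
tie-corrected Mann–Whitney U/(n₁n₀), asserted against a rank-statistic
oracle.

## Annotation

Monoisotopic masses are pinned (C 12, H 1.0078250319, N 14.0030740052,
O 15.9949146221, P 30.97376151, S 31.97207069, K 38.9637069; electron
0.00054858 Da) so theoretical m/z values are bit-stable. Adducts are
[M+H]⁺ and [M+K]⁺ at charge +1, with the electron mass subtracted.
Formula matching returns the (peak, adduct) pair with the smallest
absolute ppm error within tolerance (default 5 ppm), independent of peak
order. The shipped diagnostic table carries 16 curated ions (8 per
author) plus one figure-quoted ion (272.0655) that is close to, but not
reconcilable with, the tabulated 273.0289 — both are retained
unannotated. The ivory-black marker 130.5259 has a fractional m/z
inconsistent with a small singly-charged organic ion and is treated as an
empirical marker, never assigned a formula.

## Synthetic corpora

The generator emulates the study geometry: 2 authors × 5 documents × 2
substrates × 3 replicates + 4 blanks = 64 infusions. Feature classes:

* 300 background ions (uniform m/z in the 70–700 scan range, lognormal
  base intensities) present in all real samples minus 10 % missingness;
  blanks carry a thinned subset (`blank_background_rate` 0.15 per blank),
  so roughly half the background survives the blank filter — a corpus
  whose blanks contained every background ion would leave the classifier
  nothing to work with, which real studies contradict;
* 8 diagnostic ions per author (defaults: the curated diagnostic m/z
  values, so annotation runs on synthetic output unchanged) present only
  in that author's samples at an 8-fold intensity effect;
* 20 blank contaminants, always in every blank; half also bleed into
  real samples (presence probability 0.3), so the blank filter faces
  non-trivial cases.

Noise: Gaussian m/z jitter (sd 1 ppm — well inside the 5 ppm alignment
tolerance; the jitter-sensitivity test raises it deliberately), lognormal
multiplicative intensity noise (sd 0.5 on the log scale), uniform 10 %
missingness. mzML output re-jitters each scan around the file-level peaks
(intensity wobble sd 0.2) so consolidation has real work.

Determinism: one seed per corpus; each sample draws from a substream
keyed by (seed, CRC32(sample id)), so adding a sample leaves all others
byte-identical. Null corpora reuse the identical m/z grid and noise
draws, removing only the fold-change and author-specific presence.

What passing the synthetic benchmark does **not** show: real ink spectra
have isotope envelopes, correlated ion suppression, instrument drift and
adduct families, none of which are modelled; absolute performance on real
manuscripts cannot be inferred from synthetic AUCs. What it does show:
the pipeline's operations implement their definitions, recover planted
effects at realistic noise, keep the FDR on null data, and do not leak
replicate information across CV folds.

## Problem sizes and runtime

Default corpora are 64 samples × ~340 features; a full pipeline run
(alignment through ROC and annotation) takes on the order of a second,
and the statistical acceptance properties average 10 generator seeds per
condition. Oracle equivalences (alignment, BH, AUC) run on 1000 random
instances each.

## Known limitations

* Greedy alignment is order-dependent by construction; features closer
  than the tolerance to each other can merge or chain (see above).
* The TSV dialect is deliberately minimal (two columns, `#` comments).
* No isotope-envelope grouping, adduct clustering, retention-time
  handling or probability calibration; single charge state throughout.
* The hard-margin emulation (C = 10⁸) can be slow or brittle on heavily
  overlapping classes; that regime is outside the intended use.
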