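# Methods

## Model and pipeline

The package implements sequence design as black-box multi-objective
optimization over fixed-length amino-acid strings.  The data model
assumes a single effective selection round: a variant's binding score is
the ratio of its read frequency in the target-eluted pool to its
frequency in the non-specifically-bound pool, computed from full-table
read totals *before* the minimum-read filter so that a record's score
does not depend on which other records survive filtering.  Variants with
`count > 3` in either pool (strict inequality) are retained; `Score ≥ 5`
labels positive, `Score < 1` negative, and the `1 ≤ Score < 5` band is
dropped from training as unlabeled — it is neither clearly enriched nor
clearly depleted.  A variant sequenced only in the eluted pool has
infinite enrichment and is labeled positive.

Prediction instability is estimated by ensembling: the negatives are
partitioned (seeded shuffle, contiguous slices, sizes within one) into
k = 5 subsets, each combined with every positive to train one
classifier.  The ensemble's mean probability is the activity objective;
its population standard deviation (divisor k — the ensemble is treated
as a complete finite set, not a sample; divisor k−1 is a flag), negated,
is the stability objective.  Class imbalance is left unweighted.

Search runs in a binary latent space.  A linear encoder/decoder pair
with a d-bit code is trained with a straight-through estimator (forward:
threshold sigmoid activations at 0.5; backward: identity through the
threshold).  Generation-time encoding and decoding are deterministic;
decoding takes the per-position argmax over residue logits with
lexicographic tie-break (the alphabet is stored sorted).  A
factorization machine of rank r is fitted by Adam to the squared loss
with L2 penalty λ on `w` and `V` (bias unpenalized); its quadratic form
is compiled into a QUBO with one sign flip, so annealing (minimizing)
maximizes the surrogate.  The compilation is exact, which the tests
verify by exhaustive enumeration.

## Acquisition target

The surrogate needs a scalar regression target per evaluated point.  Two
are implemented:

- **Non-domination rank (default).**  `y = 1 / (1 + c)` where `c` is the
  number of evaluated points dominating the point.  Every Pareto-front
  member scores 1 whichever trade-off it realizes, so the surrogate is
  rewarded across the whole spectrum, and the signal is dense.
- **Hypervolume improvement (`fm_target="hvi"`).**  HVI over the current
  front, with the exclusive hypervolume contribution for archived front
  members.  This is the textbook hypervolume-greedy choice, but at desk
  scale it proved unusable as a regression target: every dominated point
  (≈ 97 % of evaluations) has target exactly 0, the fit collapses toward
  the zero function, and the optimizer degenerates to random search.
  It is kept for experimentation, not as the default.

Each iteration anneals the compiled QUBO from multiple seeded restarts
through a geometric temperature ladder spanning the largest possible
single-flip energy change down to 10⁻³ of it.  Because the annealer
tends to collapse onto one (often already evaluated) optimum, the
proposal batch is completed from seeded 1–5-bit perturbations of the
lowest-energy samples, screened by surrogate energy, with uniform random
codes only as a last resort.  Duplicate decodes and previously evaluated
sequences never consume budget.

## Pareto accounting

The archive's reference point is fixed when a run's seed pool has been
evaluated: the per-objective minimum minus 10⁻⁶.  Fixing it once makes
the hypervolume history non-decreasing and comparable within a run.
Points later falling below the reference in some coordinate are clipped
to it for hypervolume accounting only.  Objectives are divided by their
seed-pool ranges inside the hypervolume computation; without this the
solubility scale (several units on the hydropathy scorer) swamps
activity and stability (ranges ≤ 1).  Dominance comparisons and stored
coordinates are never rescaled.  Duplicate objective vectors keep the
first-seen sequence on the front; later sequences go to a side list.
Exact hypervolume is implemented for up to three objectives (2-d sweep;
3-d slab decomposition over the third coordinate), with a seeded
Monte-Carlo estimate beyond three.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| read filter `min_reads` | 3 (strict >) | retention threshold on either pool |
| label thresholds | 5 (positive), 1 (negative) | enrichment-score units |
| splits k | 5 | negative subsets / ensemble members |
| predictor | logistic; `birnn` optional | hidden size 10, 25 epochs, lr 10⁻³ for the recurrent net |
| logistic `l2` | 0 (0.05 in desk-scale runs) | tempers saturated probabilities; see below |
| latent dim d | 64 (24 in desk-scale runs) | ≥ L·log₂\|alphabet\| bits needed for lossless coding |
| FM rank r / λ | 8 / 10⁻³ | surrogate capacity / shrinkage |
| batch per iteration | 20 | unique unseen sequences per refit |
| SA restarts × sweeps | 32 × 200 per iteration | 50 × 1000 for the exactness oracle |
| budget | 2000 × 10 runs (full scale); 400 (desk scale) | unique evaluations per run |

## The synthetic landscape

`synthetic` plants a motif: fitness = baseline + bonus × (matched motif
positions) + per-sequence Gaussian noise (a seeded lookup keyed on the
sequence, so fitness is a deterministic function).  Panning draws the
N.S. pool from a uniform multinomial and the eluted pool from weights
∝ exp(fitness) — exponential selection, making expected log-Score linear
in fitness.  The stock benchmark uses length 12 over a 4-letter
alphabet, motif on 10 of 12 positions, bonus 1.0, noise sd 0.1, 2000
variants, 2 × 10⁵ reads per pool.  Ten motif positions leave headroom:
random sequences match ~2.5 positions and even the best of 400 random
draws reaches ~6–7, so an optimizer must search to approach the optimum
of 10.  Desk-scale ensembles use the logistic architecture with
`l2 = 0.05`, chosen from a calibration profile (mean prediction vs motif
matches) so probabilities are not saturated over the top half of the
fitness range.

What the generator does *not* emulate: PCR and sequencing error,
multi-round panning dynamics, position epistasis, realistic CDR residue
composition, and real solubility physics (the shipped scorer is mean
negated Kyte–Doolittle hydropathy).  Passing tests therefore demonstrate
that the machinery is correct and that the optimizer exploits a
learnable landscape better than random sampling — not that designs
against a real antigen will bind.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-run and per-iteration seeds are
  derived arithmetically, and re-running a configuration reproduces
  archives byte-for-byte.
- The SA inner loop is numba-compiled; states are returned sorted by
  ascending energy with a stable sort, duplicates allowed.
- FM fitting on an empty design or non-finite targets raises; a
  constant target converges to the bias term under any λ > 0.
- `0/0` enrichment (absent from both pools) is an undefined sentinel and
  the record is excluded from labeling; negative frequencies raise.
- Wrong-length selection candidates fail the length rule rather than
  raising, so one malformed candidate cannot abort a funnel.
- "Repetitive amino acids" is read as a homopolymer run (≥ 5 identical
  consecutive residues); an adjacent-tandem-repeat detector is available
  via `homopolymer_mode="kmer"`.
- Strict inequalities for the score (> 0.6) and solubility (> 0.0)
  filters; thresholds configurable.

## Problem sizes used in the shipped checks

Tests and the acceptance script run the complete pipeline at desk scale:
2000-variant tables, five-member logistic ensembles, latent dimension
16–24, budgets 40–400, and ten paired optimizer-vs-random runs; the
exactness oracles enumerate up to 2¹⁶ assignments and 10⁶ Monte-Carlo
samples.  These sizes were chosen so the full suite completes in minutes
on one CPU while every oracle remains exhaustive.

## Known limitations

- The deposited training data of the original galectin-3 campaign are
  not bundled; novelty distances against that training set can only be
  recomputed after dropping the count table into `data/external/`.
- The recurrent predictor is a plain bidirectional RNN (not LSTM) with
  full-batch training; it is the slow path and not used in desk-scale
  defaults.
- Exact hypervolume stops at three objectives; the Monte-Carlo fallback
  is an estimate with seeded variance, not a bound.
- The autoencoder is linear; identity rates degrade when d is below the
  information content of the sequence space, and the decoder's image —
  not the full sequence space — bounds what the optimizer can reach.
- Solubility scorers are stand-ins behind an adapter; plugging in a real
  predictor (per-sequence score table) changes only `f_sol`.
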