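# wsbbo — whole-spectrum black-box optimization for antibody CDR design

`wsbbo` designs fixed-length antibody sequences (concatenated VHH
complementarity-determining regions) from phage-display deep mutational
screening data, for computational protein engineers who must hand a
short, trustworthy candidate list to a wet lab.  Because activity
predictors trained on a few thousand labeled variants are unreliable,
the package does not commit to a single acquisition strategy: it
maximizes the ensemble-mean predicted activity *and* the stability of
that prediction (low ensemble disagreement) *and* solubility as separate
objectives, and returns the Pareto front — the whole spectrum from
adventurous (high score, uncertain) to conservative (lower score,
stable) designs.

## The method

**Enrichment labels.** Two sequenced phage pools — non-specifically
bound (N.S.) and target-eluted — give each variant a binding score

```
Score = f_eluted / f_NS
```

where `f` is the read frequency of the variant in its pool.  Variants
with more than 3 reads in either pool are retained; `Score ≥ 5` is the
positive (binding) class and `Score < 1` the negative class.

**Prediction instability as an objective.**  The negatives are split
into k = 5 equal subsets; each subset plus all positives trains one
classifier p̂ᵢ(x) (one-hot encoding; a logistic model or a bidirectional
recurrent net with hidden size 10).  For a candidate sequence x the
ensemble yields

```
f_mean(x) = (1/k) Σᵢ p̂ᵢ(x)        (maximize)
f_stab(x) = − std{p̂₁(x), …, p̂ₖ(x)}  (maximize; 0 = perfectly stable)
f_sol(x)  = solubility score         (maximize; pluggable scorer)
```

**QUBO-surrogate search.**  A binary-latent autoencoder maps sequences
to d-bit codes.  A factorization machine
`ŷ(z) = w₀ + Σᵢ wᵢzᵢ + Σᵢ<ⱼ ⟨vᵢ,vⱼ⟩ zᵢzⱼ` is fitted to a scalar
acquisition value per evaluated point and compiled — exactly — into a
QUBO (`Q_ii = −wᵢ`, `Q_ij = −⟨vᵢ,vⱼ⟩`, offset `−w₀`), which a simulated
annealer minimizes; a quantum annealer could consume the same QUBO.
Sampled codes are decoded, evaluated on the three objectives, archived
in an incrementally maintained Pareto front with exact (d ≤ 3)
hypervolume tracking, and fed back into the surrogate.  A
random-generation baseline at equal evaluation budget is built in.

**Selection funnel.**  Candidates pass five filters: length 39; no
homopolymer run ≥ 5; mean score > 0.6; filter-solubility > 0; and ≥ 3
mutations from the wild-type in each CDR segment (CDR1 13 aa, CDR2
10 aa, CDR3 16 aa of scaffold 3DWT).  Novelty is reported as the Hamming
distance to the closest training sequence.

## Worked example

A fully synthetic end-to-end run (a motif-based fitness landscape stands
in for real binding data, so nothing needs downloading):

```
wsbbo synth    --variants 800 --reads 80000 --seed 1 --out fixtures
wsbbo score    --counts fixtures/counts.csv --seed 2 --out labeled
wsbbo train    --labeled labeled --seed 3 --epochs 200 --learning-rate 0.05 --out models
wsbbo optimize --labeled labeled --models models --runs 2 --budget 100 \
               --seed-base 100 --latent-dim 24 --out run
wsbbo select   --candidates run/merged.csv --wt-cdrs ACDE,ACDE,ACDE --out sel
wsbbo front    --archive run/archive_run0.csv
```

prints

```
wrote 800 variants to fixtures/counts.csv
800 loaded, 800 retained, 27 positive, 617 negative
trained 5 members; saved to models
run 0: 100 generated, front size 118
run 1: 100 generated, front size 118
200 unique generated sequences -> run/merged.csv
1 of 200 candidates pass all rules
118 non-dominated sequences
  f_mean: best 0.9999
  f_stab: best -0.0000
  f_sol: best 3.5000
```

Reading the numbers: of 800 simulated variants, 27 are enriched enough
to label positive and 617 depleted enough to label negative (the rest
fall in the unlabeled 1 ≤ Score < 5 band).  Each optimizer run evaluates
100 new sequences; after merging and deduplicating the two runs, the
selection funnel passes 1 of 200 candidates, and the final front spans
designs from perfectly stable (`f_stab = 0`) to maximally active
(`f_mean ≈ 1`).  Every stage writes a `manifest.yaml` with its seeds and
configuration, and re-running any stage with the same configuration
reproduces its outputs byte-for-byte.

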