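# Methods

## The prediction problem

Given a protein and a candidate lysine at 1-based position p, the model
scores whether the lysine is acetylated. Training data are (protein,
position, label) triples; negatives are non-annotated lysines sampled from
the same proteins as the positives at a configurable ratio (default 1:1),
because in real data non-acetylated lysines vastly outnumber acetylated
ones and balanced training keeps the SVM decision threshold meaningful.
Species differences are handled by data, not code: a per-species model is
simply a separate run over that species' site file.

## Window convention

All features are computed on a window of 2L+1 residues centred on the
candidate lysine (offsets j = −L…+L; default L = 6, window 13, configurable
5…19 for window-size sweeps). Windows crossing a terminus are padded with
the gap symbol `'-'` and a validity mask. Every encoder treats invalid
positions as contributing nothing: they are excluded from counts and
denominators where a count is defined (CKSAAP pairs, AAindex averages, ACC
and PC-PseAAC, which operate on the compressed valid subsequence) and emit
zeros where a fixed-length encoding is defined (per-position SS/RSA/
Disorder/HSE/PSSM/HH blocks). This preserves fixed dimensionality without
inventing residues. A window touching both termini is classed N-terminal —
an arbitrary but deterministic tie-break. `'X'` (unknown residue) behaves
like a gap inside encoders that need a concrete amino acid: no property
value, no pair membership, substitution similarity 0.

## Encoders and their parameters

Per-subtype dimensionalities at L = 6: LC 3, PWAA 20, EBGW 15, CKSAAP 400,
KNN 5, ACC 50, PC-PseAAC 22, AAindex 75, SS 39, RSA 39, Disorder 13, HSE
52, PSSM 533, HH 273 (1539 total). Feature names follow
`<SUBTYPE>.<channel>.<offset>[.<aa>]` so selection manifests are auditable.

- **PWAA** sums over the full window including the centre (whose weight is
  j + |j|/L = 0 at j = 0, so inclusion is harmless).
- **EBGW** uses K = 5 prefixes of length Int(N·k/K), with Int() as
  round-half-up; at N = 13 the prefix lengths are 3, 5, 8, 10, 13. The
  denominator of each feature is the prefix length, so features lie in
  [0, 1].
- **CKSAAP** defaults to spacing k = 0 (adjacent pairs); general k is
  implemented but untuned. A pair counts only when both endpoints are
  standard residues; the 400 frequencies then sum to 1.
- **KNN** scores use the BLOSUM62-normalized fragment distance. K per
  neighbour fraction f is max(1, round(f·n)) with n the (possibly
  self-excluded) reference size — K must be a positive integer. Distance
  ties are broken by reference insertion order via a stable sort. When
  encoding training sites the query's own fragment is excluded
  (leave-one-out) by default, to avoid leaking the site's label into its
  feature; set `knn_exclude_self=False` to disable.
- **ACC** uses the five Atchley factors with lags 1–2 (a window of 13
  bounds the useful lag range); both are configurable.
- **PC-PseAAC** uses λ = 2 sequence-order correlation factors and weight
  w = 0.05 (the conventional default of the encoder family), built from
  hydrophobicity, hydrophilicity and side-chain mass scales standardized
  over the 20 residues (population moments); the 20+λ components sum to 1.
- **AAindex** averages ten bundled property tables (Kyte–Doolittle
  hydropathy, Hopp–Woods hydrophilicity, Grantham polarity and volume,
  Zimmerman bulkiness, and the five Atchley factors) over the valid window
  positions, and additionally emits the five Atchley factors per position.
  Which specific indices to average is a genuinely open choice; the bundled
  set spans hydrophobicity, polarity, volume and flexibility-like axes and
  is easily replaced via `encode_aaindex`'s arguments.
- **ECS** (the conservation score inside PSSM/HH blocks) is Shannon entropy
  in bits of the 20-way occurrence-probability vector, with 0·log 0 = 0 by
  continuity; range [0, log2 20 ≈ 4.3219].
- Profile encoders are strictly per-position (consistent with the sliding-
  window design and the documented bit encodings); an encoder whose channel
  is absent raises a declared channel-missing error rather than silently
  emitting zeros.

Profile files are parsed from fixed dialects (PSI-BLAST ASCII PSSM with its
letter-header column order honoured; a tabular profile-HMM emission table in
alphabetical column order; PSIPRED .ss2; per-residue structure and disorder
TSVs). Probability rows are renormalized to sum to 1 within 1e-9; running
the external predictors themselves is out of scope.

## Feature selection

Within each subtype, features are ranked by |PCC| with the 0/1 labels —
a strong negative correlate is as informative as a positive one — with ties
broken by name, then original column order; constant features get PCC 0 and
sort last. A single greedy pass then accepts a candidate iff the 5-fold
cross-validated SVM accuracy strictly increases ("increased", hence ">"
not "≥"); the first-ranked feature is accepted unconditionally (the empty
set's baseline accuracy is defined as 0), which makes the procedure
well-founded and guarantees a non-empty selection per subtype. SVM
hyperparameters are tuned by grid search once per subtype on the full
subtype matrix and held fixed through the pass — re-tuning inside every
candidate evaluation would multiply the cost by the lattice size for little
benefit. One stratified, shuffled, seeded fold plan is fixed before
iteration and shared by all subtypes and all candidate evaluations, so
selection is fully deterministic given (matrix, seed, grid). An optional
`max_evaluations` cap guards runtime on the largest subtypes (PSSM has 533
candidates at L = 6). The accepted lists are concatenated in the fixed
subtype order LC, PWAA, EBGW, CKSAAP, KNN, ACC, PC-PseAAC, AAindex, SS,
RSA, Disorder, HSE, PSSM, HH.

## SVM training and evaluation

The classifier is an RBF-kernel SVM. Features are scaled to [−1, 1] by
training min/max (the libsvm convention); a feature constant in training
maps to 0 everywhere, including at test time. Scaling statistics are always
computed on training folds only. The cost/gamma lattice defaults to the
published grid-tool ranges (cost 2^−5…2^15, gamma 2^−15…2^3, steps of 2^2);
the model surface defaults to a 3×3 coarsening for desk-scale runs, and the
full lattice is one argument away. Grid ties break toward smaller cost,
then smaller gamma.

Evaluation reports MCC, ACC, SEN, SPE and PRE from exact integer confusion
counts (MCC is defined as 0 when any denominator factor vanishes; an
undefined precision is reported as 0 with a warning) plus ROC AUC computed
from SVM decision values — margins rather than probability estimates, which
keeps evaluation deterministic and threshold-free; tied scores are grouped
into diagonal ROC segments, so the AUC equals the Mann–Whitney statistic.

The cross-validated report returned by `AcetylationSiteModel.fit()` uses a
fold plan seeded differently from the selection fold plan. Stepwise
selection maximizes accuracy on its own folds, so re-using them would
overstate performance; a fresh plan removes that component of the bias. The
ranking and stepwise stages still see all training labels — the protocol
evaluates the selected model on the data that selected it, as is standard
for this family of predictors — so the report is a training-set CV figure,
not an independent-test estimate.

## Synthetic data

The generator emulates the statistical structure the method assumes, at
desk scale: 200 proteins (lengths uniform on [60, 180], SwissProt-like
residue frequencies), one planted acetylated lysine per protein, negatives
sampled 1:1 from the remaining lysines. Around planted sites the flanks are
re-drawn with log-odds boosts (+0.7 G, −0.7 E/D anywhere; +0.5 K upstream
only) within ±6 of the centre, mimicking the compositional biases observed
around real acetylation sites. Profile channels are drawn per residue:
Dirichlet rows concentrated on the true residue for PSSM/HH, Markov-chain
runs for secondary structure and disorder, Beta-distributed RSA and
plausible torsion ranges. The class signal lives in the HSE "up" channels
at the site centre: HSEAU ~ N(8.15, 3²) at positives vs N(9.21, 3²)
elsewhere, HSEBU ~ N(9.72, 3²) vs N(11.07, 3²), truncated at 0. The means
are structural averages measured on real acetylated vs non-acetylated
lysines; the sd of 3.0 is this package's choice of a realistic dispersion
(configurable). The "down" channels carry no class signal, matching the
mechanistic picture that it is upper-half-sphere crowding that hinders
acetyl transfer.

What passing tests on this data do and do not show: they verify that every
pipeline stage is wired correctly, that planted effects of realistic size
are recovered, and that the no-signal configuration yields chance AUC. They
do not certify real-data performance — real profiles have long-range
within-protein correlation, annotation noise, and inter-protein homology
that the generator (independent draws with short-range smoothing only) does
not model.

Simulation sizes used by the test suite and the acceptance script — 200
proteins / ~400 sites per run, 20 seeds, 500 proteins for mean-recovery
checks, and the {LC, PWAA, HSE} subtype subset with the 3×3 grid for the
repeated end-to-end runs — were chosen as the smallest configurations at
which the planted effects are comfortably resolvable.

## Numerical and degenerate-input conventions

- Round-half-up for EBGW prefix lengths and KNN's K (documented; Python's
  banker's rounding is avoided for reproducibility across conventions).
- CKSAAP with no valid pair returns all zeros rather than NaN.
- Feature matrices are written with `repr` precision and re-read with
  round-trip float parsing, so write→read is bit-exact.
- All randomness (sampling, fold shuffling, the generator) flows through
  seeded NumPy generators; two runs with the same configuration hash
  produce byte-identical matrices, manifests and predictions.
- Single-class inputs (fits, fold plans, AUC) raise contract errors rather
  than returning degenerate values.

## Known limitations

- The stepwise pass is one-shot greedy: it never revisits a rejected
  feature and never removes an accepted one.
- KNN features make the feature matrix depend on the training reference;
  models that use them must carry the reference along for prediction (the
  CLI bundles it).
- The AAindex subset and the profile-noise parameters are defensible
  defaults, not fitted quantities.
- Training-set CV with in-protocol feature selection retains a modest
  optimistic bias (see above); independent test data are required for an
  unbiased performance estimate.
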