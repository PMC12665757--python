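# Methods

This note documents the models, algorithms and numerical choices behind
`triagonist`, and what the synthetic experiments do and do not demonstrate.

## Sequence representation

Peptides are ordered lists of residue tokens. A token is a standard
amino-acid letter or a bracketed non-standard amino acid (NSAA) whose first
letter (after an optional lower-case `d` marking a D-enantiomer) names the
base residue: `[dS]` is D-serine, `[K (yE-C16)]` a γGlu-palmitoyl lysine.
Tokenization ignores whitespace outside brackets, preserves bracket payloads
verbatim, and folds the printed style `K [(yE-C16)]` into the single token
`[K (yE-C16)]`. `tokenize∘detokenize` is the identity on valid token lists
(property-tested). C-terminal amidation is carried as a record-level flag,
not a token.

NSAA property handling: every NSAA inherits its base residue's values
(hydropathy, charge, mass, pKa, DIWV weights) unless the packaged override
table (`data/nsaa_overrides.csv`, user-extensible) supplies explicit
increments. The shipped lipid-chain mass increments are chemistry-derived
estimates (e.g. +367.53 Da for γGlu-C16 on lysine); sequences containing such
tokens are therefore excluded from golden-value tests.

## Activity labels

Binary high-affinity labels derive from EC50 in pM with a 1000 pM threshold;
the positive class is strict `EC50 < 1000` (the evaluation convention; the
boundary and strictness are configurable). Missing EC50 propagates as a
missing label and is masked in every loss and metric.

## Physicochemical profile

Molecular weight (average masses), isoelectric point (Bjellqvist pKa set,
charge-balance bisection on [0, 14]), Guruprasad instability index
(10/L × Σ DIWV dipeptide weights) and Kyte-Doolittle GRAVY follow the
ProtParam conventions via Biopython's `ProteinAnalysis`, applied to the
base-letter sequence with NSAA mass increments added. Two deliberately
sequence-only estimates complete the profile: estimated logP is the
length-normalised Kyte-Doolittle sum (identical to GRAVY under the default
parameterization) and estimated PSA counts polar residues at 50 Å² each.
The polar set is {S, T, N, Q, D, E, H, K, R} — the unique set consistent with
the printed PSA values of the bundled reference panel (Y and C excluded,
H included). Note one subtlety: the Bjellqvist model assigns residue-specific
*terminal* pKa values, so the pI is invariant under internal residue
permutations but not under permutations that change the termini.

## Graph representation

A peptide of L tokens becomes a chain graph with L nodes and the 2(L−1)
directed backbone edges {(i,i+1),(i+1,i)}. Node features (7 channels):
z-scored hydropathy, side-chain charge at pH 7.4 (D,E −1; K,R +1; H +0.1;
configurable) and residue mass, the D-residue and lipidation flags, and the
positional encodings sin(πp/L), cos(πp/L) with p 0-based (so the N-terminus
anchors at (0, 1)). Normalization statistics are pooled over all residues of
the training set (std fallback 1.0 for degenerate channels), frozen at train
time, fingerprinted, and verified at prediction time.

## Classifier

Shared encoder: four GATv2-style multi-head attention layers (6 heads × 16
dims concatenated to 96, self-loops added, LeakyReLU(0.2) attention), each
followed by ReLU, batch normalization over nodes and dropout 0.2, with
identity residual connections after layers 2 and 4. Readout: Set2Set with
three processing steps (LSTM controller, content-based attention) giving a
192-dim embedding, then a 192→96 representation layer (ReLU, batch-norm,
dropout). Task heads: per receptor, 96→48→24→1 fully connected stacks with
ReLU/batch-norm/dropout between layers; sigmoid converts the logit to a
probability.

Loss: per-sample focal loss `−α_t (1−p_t)^γ log p_t` with α = 0.25, γ = 2.0
(γ = 0, α = 0.5 recovers a 0.5-weighted BCE); the multi-task objective is the
weighted sum over receptors of the masked mean, with equal weight 0.5 per
active receptor and zero weight for inactive ones.

The network runs on a compact in-repo reverse-mode autodiff engine
(`_autodiff.py`): broadcasted arithmetic, matmul, pointwise nonlinearities,
reductions, gather/segment-sum (the primitive pair behind attention softmax
and pooling). Gradients are verified against central finite differences for
every operation and through the full model.

### Numerical choices

* The engine computes in float32 (a module-level dtype switch; the
  gradient-check tests run it in float64). Probabilities are clipped to
  [1e−6, 1−1e−6] — float32-safe — before any log.
* Batch-norm uses batch statistics during training (running-stat updates with
  momentum 0.1) and running statistics in evaluation; a single-sample batch
  falls back to running statistics.
* Adam (β = 0.9/0.999, eps 1e−8) with global-norm gradient clipping at 1.0;
  no weight decay. Default batch size 32.
* Residual connections are identity additions (dimensions permit).
* Attention softmax subtracts the per-segment maximum as a constant shift
  (softmax-invariant, so the gradient is exact).

## Transfer learning and evaluation

Stage 1 trains the encoder and the GCGR/GLP1R heads on records labelled for
either receptor (default 80 epochs, lr 1e−3). Stage 2 freezes the encoder —
weights, batch-norm running statistics and dropout, and likewise the
non-GIPR heads — and trains only the GIPR head on GIPR-labelled records
(100 epochs, lr 1e−3); the freezing is bit-exact and tested. Stage 3
fine-tunes everything at lr 1e−4 (60 epochs). Each stage early-stops on
validation loss with patience 15 and restores the best weights; early
stopping engages after a warm-up (default 8 epochs per stage) because the
focal objective has a trivial predict-the-prior optimum at initialization
whose validation loss transiently beats a model that is still forming
features. The optimizer is re-initialized per stage.

Cross-validation is stratified 5-fold on activity-state keys — the joint
pattern of (high, low, missing) across the three receptors, e.g. `1|0|m` —
with per-key round-robin dealing so per-key counts differ by at most one
across folds; the inner 80/20 train/validation split uses the same keys.
Metrics per receptor over unmasked labels: AUC-ROC, AUC-PR (average
precision, i.e. step integration of the precision-recall curve), F1,
precision, recall and balanced accuracy at threshold 0.5; single-class
subsets report AUCs as missing. Ensembles average the probability outputs of
fold models, which must share one normalization-statistics fingerprint.
Validation sets can be split by token-level similarity to the training set
(exact matches dropped, "novel" = max similarity ≤ 80%).

## Design scoring and the genetic algorithm

Sequence similarity is 1 − Levenshtein/max(len) at the *token* level (an
NSAA token is one atomic symbol), computed with edlib over a token→codepoint
mapping and verified against a quadratic DP oracle. Novelty is
1 − max-similarity to the training set, minus 0.2 (floored at 0) above 80%
similarity — the penalty magnitude is a package choice. Diversity is the
mean dissimilarity to a sample of up to 20 population members.

Motif preservation scores candidates against a packaged YAML table of
literature-derived incretin binding motifs (critical GLP-1 activation
residues, ortholog- and paralog-conserved positions of GLP-1, glucagon and
GIP), each anchored in its native hormone's own coordinate frame from the N-
or C-terminus. Per motif: exact match 1.0, same conservative class 0.5
(classes {AVLIM}, {FWY}, {ST}, {DE}, {KRH}, {NQ}, {G}, {P}, {C}), one
wildcard mismatch forgiven (removed from the denominator); the overall score
is the mean over motifs. Plausibility combines chemical constraints (net
charge at pH 7 in [−6, +2], longest hydrophobic run ≤ 5, no residue > 30% of
composition), motif preservation, proteolytic stability (1 − cleavage-site
density; trypsin K/R and chymotrypsin F/Y/W sites, blocked by a following
proline) and composition similarity to the native hormones (1 − total
variation distance to their mean residue frequency vector) as
`B = 0.3 C + 0.35 M + 0.2 P + 0.15 A`, pass at B ≥ 0.3. The stability and
composition functionals are documented package defaults, not literature
formulas.

The GA evolves a fixed-size population (default 100, lengths 25–35):
fitness evaluation → elitism (top 10% copied unchanged) → tournament
selection (k = 3, ties to the earliest index) → single-point crossover with
independent cut points in each parent (80%) → adaptive mutation (10%,
doubled below mean diversity 0.2 and capped at 30%; 70% point, 20%
conservative-class, 10% modified-residue events introducing D-forms or a
lipidated lysine) → repair (C-terminal trim or donor-parent extension to the
length window, then up to five motif-anchor re-instatements; the fitter
parent as last resort). Fitness is evaluated once, when an individual enters
the population, and elites carry their score — the diversity term is
population-dependent, and this steady-state convention is what makes the
best-fitness trajectory non-decreasing. Termination: generation cap
(default 50), convergence (3-generation moving average of best-fitness
improvement < 0.1), diversity stagnation (|Δdiversity| < 1e−3 for 10
generations) or an optional fitness threshold.

Initialization draws residues from the native-hormone composition
distribution and keeps only plausibility-passing candidates; optionally the
population is seeded from point-mutated native scaffolds
(`initialize_population(..., templates=...)`). The published fitness scale
is not reproducible from the printed information (the component weighting is
not fully specified), so the package fixes unit default weights and treats
the *structure* of the fitness, not its absolute scale, as the contract.

## Synthetic data and the planted rule

The generator emulates the curated corpus shape: 234 sequences (configurable),
GCGR labels for 206 (49.0% positive), GLP1R for all (74.8%), GIPR for 56
(57.1%), lengths 25–40, occasional NSAA tokens, EC50 from label-conditional
log-normals (positive median 30 pM, negative 30,000 pM, truncated at the
1000 pM boundary so thresholding reproduces labels exactly; optional
label-flip noise is applied before EC50 sampling so the consistency holds at
any noise level).

Sequences are point-mutated, length-adjusted variants of the three native
scaffolds (the real corpus consists of incretin-scaffold analogues). The
planted rule scores: GLP1R — graded presence of the E-G-T-F core anywhere
plus C-terminally-weighted hydropathy; GCGR — His1, Asp9 and tail hydropathy;
GIPR — Tyr1 and centrally-weighted polarity. The smooth components are
weighted by the same sin/cos positional phases the graph features expose, so
the rule is an exact function of what the learner observes. Probabilities
are logistic in the rule score (scale 1.5 — shallow enough that partial rule
satisfaction moves the probability, which is what gives the GA a usable
selection gradient); per-receptor cutoffs are calibrated by quantile on the
generated pool so positive fractions land on the corpus targets (within the
±3% tie tolerance). To keep the classes separable by a correct learner, the
generator oversamples candidate variants (6×) and keeps, within each joint
label bucket, those farthest from the decision cutoffs.

**What passing these experiments shows — and does not.** The synthetic
experiments demonstrate that the training pipeline can recover a planted,
margin-separated rule from corpus-shaped data, that the freezing contract
holds, and that the optimizer improves its objective and enriches a rewarded
motif. They do not certify predictive performance on real assay data: real
EC50 corpora carry inter-laboratory noise, batch structure, unknown margins
and activity cliffs that the generator deliberately omits.

## Desk-scale experiment sizes

The packaged experiments use sizes chosen for a laptop-class single-CPU run:
rule-recovery cross-validation on n = 250 at hidden width 48 with stage
epochs 60/25/20 and three seeds (mean AUC-ROC 0.81–0.82 per receptor,
about 11 CPU-minutes); the GA demonstration uses 100 individuals for 25
generations under the planted oracle with scaffold-seeded initialization
(~15 s). The command-line smoke profile is smaller still (n = 120, hidden
24, epochs 6/5/3, 3 folds, GA 30 × 5). Paper-scale settings (hidden 96,
80/100/60 epochs, 5-fold ensembles) are the library defaults and run in
hours, not minutes.

## Known limitations

* Backbone-chain graphs only: no spatial or contact edges, no side-chain
  atoms, no 3D-derived PSA/logP.
* NSAA physicochemistry beyond the packaged overrides defaults to the base
  residue; published mass increments for complex lipidation chemistries are
  not derivable from sequence alone.
* The proteolytic-stability and composition scores are simple sequence
  heuristics, not digestion simulations.
* The classifier's calibration is untested outside the synthetic setting;
  ensemble probabilities should be treated as rankings, not potencies.

## Configuration schema (CLI)

`--config` accepts a JSON object with optional sections mapped onto the
dataclasses `ModelConfig` (`model`), `TrainConfig` (`train`), `GAConfig`
(`ga`) and `SynthConfig` (`synth`); unknown keys are rejected. Every command
takes `--seed` and writes `run_manifest.json` beside its outputs.
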