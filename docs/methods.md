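# Methods

## Model

`mtqsar` treats drug–enzyme interaction prediction as binary classification
over *(drug, EC subclass)* pairs. The target-awareness of the single shared
classifier comes entirely from the feature encoding: for each base
topological descriptor MD the model sees the triple (MD, ⟨MD⟩, DMD), where
⟨MD⟩ is the arithmetic mean of MD over the pairs of the pair's subclass and
DMD = MD − ⟨MD⟩. The underlying assumption is that drugs interacting with a
subclass cluster near that subclass's descriptor profile, so the deviation
DMD carries most of the discriminative signal while ⟨MD⟩ tells the network
*which* profile the pair is measured against.

Two modelling consequences follow and are enforced in the code:

- **Profile scope.** Class means are computed from training records only
  and then frozen. Computing them on all data would leak the validation
  partition into the features; with frozen profiles the 30% validation
  split is a genuine external test set. Whether all pairs of a subclass or
  only its interacting pairs define the mean is a config switch
  (`contributors`); the default uses all pairs.
- **Grouped selection.** Forward-stepwise selection operates on *base*
  descriptors (their DMD form, where the multi-target signal lives); the
  three feature forms of a selected descriptor always enter the network
  together. Thirteen selected descriptors therefore yield the 39-input
  reference topology.

## Descriptors

The registry holds 17 classic topological descriptors computed on the
hydrogen-suppressed graph: heavy-atom count, bond count, cyclomatic ring
count, Wiener index, first and second Zagreb indices, Randić connectivity
(identical to the Kier–Hall path χ of order 1, so exposed once), simple χ0
and χ2, Kier κ1–κ3 shape indices, Balaban J, eccentric connectivity,
diameter, radius, and the Petitjean shape index. Conventions:

- distances are unweighted bond counts; aromatic bond order (1.5) is kept
  on the graph but no default descriptor consumes it;
- χ indices use simple vertex degrees (valence-corrected variants would
  need element-specific oracles and are out of scope);
- multi-fragment molecules are reduced to their largest fragment, avoiding
  infinite distances;
- a descriptor that is undefined for a molecule (e.g. Petitjean of a single
  atom, κ3 of a 3-atom chain) contributes the fill value 0 with a warning
  flag rather than an exception.

Every registry entry carries a brute-force oracle (Floyd–Warshall
distances, exhaustive simple-path enumeration) that is algorithmically
independent of the fast networkx-based path; the suite asserts agreement to
1e-9 relative tolerance on hundreds of random graphs and on closed forms
(e.g. the Wiener index of the n-path, n(n²−1)/6).

## Selection

The stepwise procedure alternates forward entry and backward removal until
neither applies, with a hard cap (`max_features`, default 13) on the number
of selected descriptors. The criterion is a likelihood-ratio chi-square
test of an unpenalized logistic surrogate: a candidate enters if its
1-degree-of-freedom LR p-value is below `p_enter` (0.05), an included
feature leaves if its contribution given the others decays past `p_remove`
(0.10). `p_enter ≤ p_remove` prevents enter/remove cycling, a step budget
bounds pathological cases, and ties break lexicographically on the feature
name, so a selection log replays to the identical result. Candidates are
z-standardized with training statistics before scoring (the LR test is
scale-free; standardization only conditions the solver).

## Network and training protocol

The classifier is a single-hidden-layer perceptron, tanh hidden units,
probabilistic two-class output (pair sums to 1), trained with Adam
(cross-entropy loss) on features z-standardized inside the estimator.
Defaults: 50 hidden units (the search concentrates on 40–50, with 20–60
available), max 300 epochs, learning rate 1e-3. Early stopping is `"auto"`:
a 10% carve-out of the *training* partition monitors progress, but only
when the training set has at least 1,000 rows — on smaller sets a ~tens-of-
rows monitor split produces a noisy stopping signal that can freeze the
optimizer at a useless minimum, so small fits run to the epoch cap.

The split-and-repeat protocol draws, per candidate model, a fresh uniform
70/30 pair-level split (`round(0.7 n)` training rows exactly) and a fresh
weight initialization, then ranks candidates by overall accuracy. One
master seed derives all per-model seeds, so a search is reproducible
end-to-end. Fitted weights are extracted from the optimizer and all
predictions run through the package's own numpy forward pass; since the
JSON bundle stores floats at full round-trip precision, a reloaded model
reproduces predictions bit-for-bit.

MCC is defined as 0 (and flagged degenerate) when any confusion-matrix
margin is empty. ROC curves use the standard threshold sweep with
trapezoid-rule area; the suite cross-checks the area against the
Mann–Whitney pairwise-comparison statistic.

## Synthetic data: what it emulates and what it does not

The generator builds a pool of valence-correct random molecules (random
trees plus ring closures over C/N/O, 8–24 heavy atoms) and plants
multi-target structure *in computed descriptor space*: a subset of
`n_informative` registry descriptors defines a scalar structure score (mean
of their pool z-scores); each subclass receives a centroid along that axis
(spread over the pool's 15th–85th score percentiles) and samples its pairs
preferentially near its centroid (Gaussian niche, width 0.5); within a
subclass the label thresholds the latent `effect_size · z + noise_sd · ε`
at the quantile matching `label_balance`. Signal is therefore injected only
by *choosing* molecules by their actual computed descriptors — the
descriptor engine stays in the loop — and the per-class niches make class
profiles genuinely different, which is what the moving-average features
need.

Default conditions: 8 subclasses × 500 pairs = 4,000 pairs from a
2,000-molecule pool, 43% interacting, effect size 2, 4 informative
descriptors, `noise_sd = 0.25`. The noise scale was fixed once as modest
annotation noise — an eighth of the structural signal at the default effect
size, putting the Bayes accuracy near 0.96 — and `effect_size = 0` makes
labels exactly signal-free, the null case for leakage tests. A
`paper_shape` preset provides the 23-subclass, 43.3%-interacting shape of
the reference dataset at desk scale. Informative descriptors are drawn from
an identifiability-screened subset of the registry (ring count, Randić,
Wiener, Zagreb M1, κ2, Balaban J, eccentric connectivity, Petitjean):
topological descriptors are strongly inter-correlated, and recovery
experiments are only meaningful for planted signals that are statistically
attributable to a specific descriptor. Even so, a selection run may
occasionally substitute a collinear neighbour for one planted descriptor;
the recovery checks are therefore framed over seed majorities.

What passing these tests shows: the pipeline recovers planted descriptor
signal, generalizes across a held-out split, and does not hallucinate
accuracy when no signal exists. What it does not show: performance on real
medicinal-chemistry distributions — the generator has no pharmacophores, no
stereochemistry, no realistic negative-sampling structure, and its
subclasses are one-dimensional niches rather than biological families.

## Numerical and design choices

- Curation collapses records by (canonical SMILES after largest-fragment
  salt stripping and charge neutralization, subclass); the same compound
  under different subclasses is always retained. Conflicting labels for one
  key abort with an error — curated input should contain none.
- Batch prediction caps input at 100 data rows (header excluded) with a
  recorded truncation warning; `.txt`/`.tsv` extensions are required unless
  forced; malformed SMILES flag their row and never abort a batch.
- Confidences are raw network probabilities; export rounds to 6 decimals,
  and the "positive interaction" threshold is 0.5 (argmax of the pair).
- When no descriptor passes the entry criterion (e.g. null data) the
  estimator degrades to an explicit majority-class model rather than
  training a network on zero features; the bundle records this state.
- Test and acceptance problem sizes (480-pair fixtures; 4,000-pair,
  10-seed pipeline runs; 3-seed acceptance summary) are desk-scale choices
  that keep the full suite in the minutes range while leaving the planted
  effects comfortably detectable.

## Known limitations

- The descriptor pool is 17 descriptors, not the hundreds of a full
  cheminformatics toolkit; the registry is extensible but oracle-backed
  extension is on the implementer.
- One global descriptor selection serves all subclasses (as in the
  reference design); per-class feature sets are a non-goal.
- Stepwise selection with a logistic surrogate measures *linear* marginal
  signal; purely non-monotone descriptor effects would be invisible to
  selection even though the MLP could model them.
- No applicability-domain estimation: predictions for molecules far outside
  the training distribution are extrapolations (the README example shows
  this deliberately).
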