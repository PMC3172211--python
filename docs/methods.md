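# Methods

## Problem and model

The task is residue-level binary classification: given a protein chain,
decide for every residue whether it interacts with mannose. The classifier
never sees structure; structural information enters only through the
training labels, which are defined geometrically (any residue heavy atom
within 4.0 Å, inclusive, of any mannose heavy atom). The modelling
assumptions are those of every sliding-window residue predictor: the local
sequence neighbourhood carries the signal, every residue is a candidate
(no surface filtering), and windows can be treated as i.i.d. examples even
though neighbouring windows overlap.

A window of odd length L (17 by default; 17–25 supported) is centred on
each residue after padding the chain with (L−1)/2 dummy `X` residues per
terminus, so pattern count always equals chain length and terminal
residues get full-length windows. Three encodings are provided; all use
the fixed alphabet order `ACDEFGHIKLMNPQRSTVWYX`:

* binary (BPP): L one-hot blocks of 21; order-sensitive, sparse,
  dimension 17×21 = 357 at the default window;
* PSSM (PPP): the window's rows of a per-chain evolutionary profile,
  normalised to [0, 1]; padded positions contribute a pure-X row;
* composition (CPP): the 21-vector of letter fractions, unit-sum,
  order-invariant, dimension 21 for every L.

The classifier is a support-vector machine with RBF kernel
K(a,b) = exp(−g·‖a−b‖²), error/margin trade-off c, and cost factor j that
multiplies the penalty of errors on positive training examples
(implemented as a class weight; this is the standard contract of the `-j`
switch in margin-based SVM packages). Decision scores are signed margins;
a residue is called interacting at threshold t when score ≥ t.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| window L | 17 | shortest window that covers the ±8 neighbourhood; larger windows (19–25) trade context for dilution |
| cutoff | 4.0 Å | inclusive heavy-atom contact distance defining a MIR |
| ligand names | MAN, BMA | α- and β-D-mannose PDB component codes; configurable for other hexoses |
| g | 0.01 | RBF width as conventionally reported for one-hot-scale features |
| c | 2 | error/margin trade-off |
| j | 2 | positive-class cost; >1 counteracts class imbalance |
| threshold sweep | −1…+1 step 0.1 | covers the useful operating range of the margin |
| dataset ratio | 1 (main) / 10 (realistic) | balanced training vs. near-natural imbalance |

Reported g/c/j conventions attach to the feature scale they were tuned on:
one-hot vectors (squared distances O(10)) suit g ≈ 0.01, whereas unit-sum
composition vectors live at squared distances O(0.01–0.1) and need g of
order 1–100 for the kernel to resolve them. Rather than hard-coding a
second constant, `model.grid_search` selects (g, c, j) from a small grid
(g ∈ {0.01, 0.1, 1, 2, 5} × c ∈ {1, 2} × j ∈ {1, 2}) by five-fold
cross-validated MCC at threshold 0 — the same per-window selection
protocol such studies use. Selection and reporting share folds, so scores
are mildly optimistic for unseen chains; the held-out chain set the
fixture provides can quantify that gap.

## PSSM normalisation

Raw PSI-BLAST log-odds scores are mapped into [0, 1] with the logistic
function 1/(1+e^(−x)) (default), which is strictly monotone, maps 0 to
0.5, and is robust to extreme scores. Matrix-wide min–max scaling
(x−min)/(max−min) is available as a configuration alternative; the choice
is recorded in the profile object. The 21st (X) column of a real residue
row carries raw score 0 by definition; fully padded window positions are
encoded as a literal one-hot X row instead.

## Evaluation

Five-fold cross-validation is stratified (class proportions preserved per
fold, fold sizes differing by at most one per class); each fold is scored
once by a model trained on the other four. The per-threshold table is the
arithmetic mean of the five per-fold tables; a pooled-score table and a
pooled ROC/AUC are reported alongside. MCC is defined as 0 whenever a
denominator factor vanishes; an empty class makes the affected rate NaN
with an explicit warning rather than silently 0. Confusion counts are
allowed to be fractional so that accuracy and MCC can be reconstructed
exactly from percentages that were rounded for display; display rounding
is half-up to two decimals. Because printed Sen/Spe are themselves rounded
to two decimals, a reconstructed accuracy can legitimately differ from its
printed counterpart by up to ~0.02 percentage points; reconstructed MCC is
stable at two decimals across all 47 reference rows shipped in
`mannosite.reference`.

AUC is computed by the trapezoidal rule over all distinct score cutoffs
and agrees with the Mann–Whitney U statistic divided by n₊·n₋ to
floating-point accuracy (asserted to 1e−9 in tests, dually cross-checked
against scikit-learn).

## Contact annotation

The annotator uses heavy atoms only (crystal structures rarely resolve
hydrogens and contact practice is heavy-atom based), model 1 of
multi-model files, the highest-occupancy altloc conformer (ties broken by
altloc identifier), and never counts waters. The production path queries a
KD-tree of ligand atoms; an O(atoms²) double loop is kept in the package
as an independent oracle and the two are asserted equal on randomized toy
complexes. Unknown residue names map to `X` with a warning. The toy
complex generator builds an extended single-atom-per-residue chain with
residue spacing > cutoff and places one pseudo-mannose atom exactly
`offset` Å from each requested contact, which makes the expected label set
known by construction.

## Synthetic data

The generator emulates the two compositional signals seen in real
mannose-contact data: interacting residues enriched in D/E/N/Q/R/S/T/W/Y
and flanking residues (±3 by default) enriched in S/T/G, on a uniform
background (a custom background distribution can be supplied). Interacting
positions are placed in clusters of 1–4 consecutive residues by default
(binding pockets are sequence-local), targeting a 2.7 % interacting
fraction at study scale (120 chains of 200–450 residues). Biases are
multiplicative sampling weights, so enrichment strength and letter sets
are fully configurable.

What it does **not** emulate: three-dimensional geometry, surface
exposure, evolutionary covariance between positions, or realistic PSSMs
(`make_matched_pssms` produces smoothed one-hot stand-ins, labelled as
such, solely to exercise the PSSM code path offline). Passing tests on
synthetic data therefore demonstrate correctness of the pipeline and the
qualitative behaviour of the encodings under a known signal — not
real-data accuracy, which depends on downloading structures and running
PSI-BLAST upstream.

### End-to-end fixtures

`make_end_to_end_fixture` produces disjoint train/held-out chain sets at
three difficulties (96 + 24 chains of 120–260 residues; seconds to
cross-validate on one CPU):

* **easy** — the nine contact-preferred letters up-weighted ×5 uniformly
  across the whole ±8 neighbourhood of each contact. The signal is
  deliberately *compositional*: the total count of preferred letters
  separates the classes while no single window position is individually
  diagnostic, which is the regime where the order-invariant CPP encoding
  has the advantage over one-hot BPP.
* **hard** — the generator's default modest biases.
* **null** — no bias at all; cross-validated MCC must sit at chance.

Two fixture-design choices deserve emphasis. First, fixture contacts are
isolated single residues separated by at least one full window. With
clustered contacts, overlapping positive windows land in different CV
folds and an RBF SVM can reach MCC ≈ 0.65 on *bias-free* data purely by
near-duplicate memorization — a leakage artifact of pattern-level
cross-validation on overlapping windows that would make any "no signal ⇒
no performance" control meaningless (and that practitioners should keep
in mind when reading pattern-level CV results generally). Second, the
fixture size (≈500 patterns per class) keeps the sampling noise of the
null control (sd ≈ 0.04 in MCC) small relative to its acceptance band.

## Numerical and degenerate-input choices

* Alphabet order is frozen and part of the on-disk model contract.
* Nonstandard residue codes (B, Z, U, O, J) map to X with a warning, in
  sequences and structures alike.
* Negative sampling is uniform without replacement; when the pool is
  smaller than requested, all negatives are kept with a warning.
* Dataset ordering is positives (chain order) then sampled negatives
  (pool order); shuffling happens only inside the seeded CV split.
* `StratifiedKFold(shuffle=True, random_state=seed)` drives fold
  assignment; the SVM itself is deterministic given data and config.
* Ties in ROC scores are handled by collapsing to distinct cutoffs before
  the trapezoid, which is what makes the U-statistic identity exact under
  ties.
* Model files are versioned joblib containers storing config, encoding,
  window and dimension; loading validates the version and prediction
  validates the input dimension.

## Known limitations

* Real-data performance claims are out of reach without the original
  structures and PSI-BLAST profiles; the package validates machinery and
  qualitative behaviour, not headline accuracies.
* Pattern-level CV shares chains between folds; chain-level (grouped)
  splitting would be stricter and is not implemented.
* PPP requires externally generated PSSM files (`<chain_id>.pssm`,
  PSI-BLAST ASCII dialect); the package never runs PSI-BLAST.
* mmCIF structures are not parsed; PDB format only.
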