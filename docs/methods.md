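# Methods

This note documents the models and procedures implemented in `kinsig`, the
parameter choices that matter, what the synthetic data generator does and
does not emulate, and the numerical conventions adopted where the design was
genuinely open.

## Molecular model and signatures

Molecules are parsed from SMILES with RDKit and canonicalised; hydrogens are
implicit throughout. Salts and mixtures are reduced to the largest covalent
fragment (ties: heavy-atom count, then molecular weight, then
lexicographically smallest canonical SMILES) because the signature requires a
connected graph. Duplicate canonical SMILES with conflicting labels keep the
first occurrence with a warning — deterministic and auditable; duplicates
with identical labels are retained to preserve row order and file
round-trips.

The heavy-atom graph is undirected and unweighted: distance means
shortest-path bond count, never geometric distance. Pharmacophore labels are
assigned from `src/kinsig/data/pharmacophores.smarts`, a versioned,
human-editable file of single-atom SMARTS with recursive environments; an
atom may carry several labels (a hydroxyl oxygen is both donor and
acceptor), and the test suite pins the labels on reference molecules so
definition edits are deliberate. The `Aromatic` class is plain RDKit
aromaticity. Hydrophobes are aliphatic carbons not bonded to heteroatoms,
carbon-bound halogens, and thioethers; aromatic carbons are labelled
`Aromatic` only.

The signature counts, for each of the 21 unordered class pairs and each
cutoff in the grid, the unordered atom pairs supporting that class pair
within the cutoff. Conventions: a pair {u, v} contributes once per supported
class pair however many label combinations produce it; same-class pairs are
counted once per atom pair; a single multi-labelled atom cannot pair with
itself. The vector is cumulative in the cutoff by construction and invariant
to atom reindexing (both properties are tested, and the whole computation is
checked against a brute-force pair-enumeration oracle on small molecules).

**Cutoff grid.** Graph distances 1..10 in steps of 1. Drug-like molecules
rarely exceed a topological diameter of ~15 bonds, and cumulative counts at
10 already saturate most fixtures; the grid is configurable and recorded
(with the descriptor registry version and the definitions checksum) in a
registry checksum that models refuse to cross.

**Descriptor registry** (fixed order, version 1): MolLogP, TPSA, HBD, HBA,
rotatable bonds, ring count, PEOE_VSA12, fluorine count, hydrophobe count
(from the definitions file), and the functional-group counters
fr_sulfonamide, fr_urea, fr_pyrrole, fr_Ar_N. Counters use RDKit's
implementations (`fr_sulfonamd`, `fr_urea`, `fr_Nhpyrrole`, `fr_Ar_N`);
note `fr_Ar_N` follows RDKit's definition (aromatic nitrogen count).
Descriptors are always computed, never cached from external sources.

Drug-likeness flags follow the enumerated thresholds: HBA ≤ 10, HBD < 5
(strict), log *p* < 5 (strict), rotatable bonds ≤ 10, TPSA < 140 Å²
(strict). Distribution comparisons between labelled groups use the
two-sample Kolmogorov–Smirnov test (asymptotic p) or Welch's t
(Welch–Satterthwaite degrees of freedom); Welch is refused for two
zero-variance samples.

## Low-redundancy splitting

Morgan fingerprints (radius 2, 2048 bits — the community default for
Tanimoto clustering) feed a leader-style Butina clustering: molecules are
processed in descending neighbour count (similarity ≥ threshold; ties by
lower index), each unassigned molecule claiming its unassigned neighbours.
Thresholds are interpreted as *similarity ≥ t* (recorded in the split
summary, since "75%/55%" could also be read as a distance cut) and default
to 0.75 for the inhibitor and pK_i tasks and 0.55 for the binding-mode task;
`tune_threshold` scans a grid for the threshold whose singleton fraction is
closest to one half.

Whole clusters are assigned to train/test by a seeded randomised greedy
fill (largest first, side chosen with probability proportional to remaining
capacity), retried up to 100 times until the train fraction is within ±5
points of 70% and per-class label proportions on the two sides differ by at
most 10 points (both configurable). Infeasible inputs — e.g. one cluster
holding most of the data — raise an explicit error naming the cluster.

Leader clustering alone does not guarantee that members of *different*
clusters are dissimilar. Because the package promises a leakage bound,
`make_split` by default merges clusters linked by any cross-pair at or above
the threshold (single-linkage closure) before side assignment, making "no
train/test pair with similarity ≥ threshold" hold by construction; the
authoritative check remains a full pairwise scan, exposed as
`max_cross_side_similarity` and reported in the split summary. At tight
thresholds on very homogeneous libraries the merge can create large
assignment groups and an infeasible split — that is reported, not hidden.

A note on granularity: at very small n the ≤10-point balance invariant can
be unsatisfiable (with 10 molecules and a 7/3 split of 5/5 labels the best
achievable gap is ~24 points); the tolerance is a parameter for exactly this
reason.

## Models and evaluation

Four families with fixed hyperparameters: random forest and extra trees with
300 estimators; MLP with one hidden layer of 100 units, relu, adam, max 500
iterations (sizes unstated upstream; these are the common defaults and are
recorded in reports); SVM with RBF kernel, C = 1, gamma = "scale". Any
override is explicit and echoed in the evaluation report.

Cross-validation is stratified 10-fold for classification, plain 10-fold for
regression, deterministic under the seed. Aggregate metrics are computed on
pooled out-of-fold predictions (the convention is written into the report);
the per-fold mean is reported alongside because the two can differ
noticeably for ROC summaries. Metrics: MCC (zero-denominator convention:
MCC = 0, logged, so degenerate folds never crash), F1, balanced accuracy,
rank-formulation AUC with ties at one half; Pearson, Spearman, tie-adjusted
Kendall tau-b, MSE and RMSE (= sqrt(MSE) by construction). Correlations on
constant vectors raise, with MSE/RMSE attached to the error.

Greedy forward selection starts from the empty set, adds the feature
maximising the cross-validated metric (MCC or Pearson *r*), breaks ties by
column order, and stops after `patience = 3` rounds without improvement,
returning the best-scoring prefix. The stopping rule is a package choice:
only final selected-feature counts, not the rule, are stated upstream.

The pK_i task additionally exposes: `remove_outliers` (drop the
⌊fraction·n⌋ largest absolute residuals, ties by index, recompute
correlations — a diagnostic, never silent preprocessing) and
`classify_by_regression` (potent iff predicted pK_i ≥ 6, boundary
inclusive).

Binding modes use four binary models — I vs II, I vs I1/2, I1/2 vs II
(trained on the two classes involved), allosteric-vs-rest (trained on all) —
tree-based by default except I1/2 vs II, where the MLP is the stated best
family. The vote: an allosteric flag wins outright; otherwise the class with
most pairwise wins; a cyclic three-way tie falls back to Type I (the
majority class) with a tie flag. Tiny classes raise a named error rather
than silently fitting.

## Fragment mining

The miner is a bounded exhaustive grow-and-prune search, not a heuristic
re-implementation of a dedicated subgraph mining engine: fragments start as
single atoms and extend by one bond inside focus molecules; canonical
fragment SMILES deduplicate equivalent subgraphs; fragments below the focus
support threshold are never extended. Support is molecule-level
(present/absent) and matching interprets the canonical fragment SMILES as a
SMARTS query (subgraph monomorphism), so the pattern universe is the induced
connected subgraphs of the focus set and counting is standard substructure
matching — the combination under which support is anti-monotone and pruning
is lossless (verified against a subset-enumeration oracle). `max_atoms`
defaults to 10 with a hard bound of 12.

Odds ratios follow the 2×2 convention above; a zero b or c cell is flagged
infinite, a = c = 0 is undefined, and the Haldane–Anscombe +0.5 correction
is available behind a flag. Ranking is by odds ratio then focus support;
among *infinite* odds ratios, hits are ordered by lower complement support
then higher focus support, since a fragment present in every molecule of
both sets (b = 0) is mathematically infinite but scientifically
uninteresting. Pairwise group enrichment skips groups under 5 molecules with
a warning.

## Screening rule

`screen_compounds` requires the conjunction: classifier says inhibitor AND
predicted pK_i ≥ 5.5 (inclusive). The rule is monotone in the cutoff by
construction. Binding-mode votes are reported for all molecules including
screen-outs. Models refuse feature matrices whose registry checksum differs
from the one they were trained under.

## Synthetic data

The generator emulates the *structure* of curated CDK2 bioactivity data, not
its chemistry: molecules are a ring scaffold (benzene, pyridine, furan,
cyclohexane, piperidine) with up to two substituents from a small vocabulary
deliberately free of sulfur, nitriles, ureas and CF3 — so the planted marker
groups (a primary aromatic sulfonamide for the binary/continuous tasks; a
nitrile, methylsulfonyl, urea or trifluoromethyl per binding-mode class) are
fully controllable and detectable. Prevalences and class proportions are hit
exactly up to rounding, not just in expectation.

Default label conditions mirror the curated datasets: 63.6% positives for
the binary task; pK_i centred near 5 with an optional left-censored floor at
5.1 (the censored values stored at the bound with a mask — qualified
measurements are used as-is in training rather than modelled); binding modes
at the 1425/394/190/47 imbalance. The binary model also supports a logistic
odds parameterisation (fragment presence multiplies baseline odds by a
prescribed odds ratio), which is the sampling model under which the miner's
odds ratio is a consistent estimator of the planted value.

What passing tests on these fixtures shows: the pipeline recovers planted
signal at the stated noise levels, the splitter's guarantees hold, and every
combinatorial primitive agrees with brute force. What it does not show:
performance on real medicinal chemistry — the grammar has a few thousand
distinct molecules, far less scaffold diversity than a screening library,
duplicate molecules are common, and descriptors span a much narrower range.
Published-scale performance claims require the real datasets.

### Fixture sizes used by the automated checks

Chosen for single-CPU runtimes: odds-ratio recovery at n = 2000 over 20
seeds (the [10, 26] acceptance interval is ~3 standard errors around the
planted OR of 16); classifier recovery at n = 600 with 2% label flips — the
flip rate sits in the generator's "≤ 5%" noise regime and is set by
arithmetic, since MCC measured against labels with flip rate f is capped
near 1 − 2f even for a perfect model, so 2% (ceiling 0.96) lets the ≥ 0.9
bound measure signal recovery rather than the noise floor; regression
recovery at n = 400 with pK_i linear in three signature features (signal sd
1.2, noise sd 0.4, Pearson ceiling ~0.95 — a single binary fragment effect
of 1.5 caps Pearson at ~0.88 and cannot support a 0.9 bound); split
guarantees at n = 500; miner-vs-oracle equivalence on 8 molecules of ≤ 8
heavy atoms at five support levels.

## Known limitations

- 2D only: no conformers, protonation states, stereochemistry-aware
  pharmacophores or geometric distances.
- The signature's dimensionality depends on the shipped definitions and
  grid; no claim of column-level compatibility with other featurisers.
- The exhaustive miner is for desk-scale fragment analysis; it will not
  scale to large fragment sizes or very large libraries.
- The pairwise binding-mode design inherits the continuum problem: I1/2
  sits between I and II and remains the hardest contrast; the vote's tie
  fallback to Type I encodes the class prior, not chemistry.
- Censored pK_i values are used at their bound during training; no
  censoring-aware likelihood is implemented.
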