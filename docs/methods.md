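# Methods

## Descriptor encoding

Each of the 20 standard amino acids carries a short numeric property
vector per descriptor set. The package ships 13 registered sets totalling
75 components. Two carry published values transcribed into TSV fixtures:

- **Z3** — the 3-component z-scales of Hellberg et al. (z1 ≈
  lipophilicity, z2 ≈ steric bulk, z3 ≈ electronic properties), used for
  all domain-wise encodings;
- **Z5** — the extended 5-component z-scales of Sandberg et al.

**ZBinned** is a package-derived coarse variant of Z3 (each component
tercile-binned to −1/0/1). The remaining ten sets (ProtFP-PCA3/5/8,
ProtFP-Feature, T-scales, ST-scales, VHSE, MS-WHIM, FASGAI, BLOSUM
indices) occupy their conventional dimensions (3, 5, 8, 8, 5, 8, 8, 3, 6,
10) but are **deterministic synthetic stand-ins** — centred random values
generated once and versioned — labelled `_synthetic` in their filenames
and carrying no physicochemical meaning. They exist so that the
full-sequence encoding exposes the canonical 75-column contract; no
result reported by the tests or the acceptance script depends on their
numeric content, and replacing any stand-in with transcribed published
values requires only editing the fixture file. Ambiguity codes (X, B, Z,
U, J, O, gaps) are never imputed; they raise with the offending residue
and position.

A sequence's feature vector is the arithmetic mean of the per-residue
vectors — over the full sequence (`<set>.<component>` columns) or within
each domain of a partition (`d<k>.<component>` columns; domains
ascending, components in table order — this order is canonical and
asserted in tests). Two identities follow and are tested: the
full-sequence encoding is the length-weighted mean of the per-domain
encodings, and a point substitution wt→alt at a position in domain *k*
of length *Lₖ* changes exactly that domain's features, by
`(z(alt) − z(wt))/Lₖ` (mutation locality).

## Domain partitions and coordinate transfer

A partition stores the 1-based first residues of domains 2..N (cuts lie
between residues, so a 12-domain partition has 11 boundaries). Reference
cut points are configuration — they originate from structure inspection,
which is not a reproducible computation — and are read from a small YAML
file. Transfer to family members walks the alignment: each reference
boundary residue's column is located, and each member's boundary is the
ungapped position of its residue in that column. When the member has a
gap there, the boundary moves to the member's next aligned residue to the
right ("start of domain" semantics); this preserves contiguity and full
coverage. A transfer that would create an empty domain raises unless
explicitly allowed. Transfer is invariant to all-gap columns.

## Label harmonization

Database exports pass an ordered cascade: (1) rows without label text are
dropped; (2) literature-mined rows need an occurrence count strictly
greater than 15 (a literal "greater than" reading — 16 or more survives);
(3) case-insensitive substring classification, where text containing
"pathogenic" but not "benign" is pathogenic, the converse benign, and
text with both or neither (e.g. "uncertain significance",
"conflicting: benign/pathogenic", "risk factor") is dropped; (4) grouping
by (sequence, variant), where any cross-source label conflict deletes the
whole group, and agreeing duplicates merge keeping the lexicographically
first source string and the maximum count (a content-neutral choice).
Every exclusion is counted per rule; input rows = output records + logged
drops, and the cascade is idempotent.

## Matrix assembly

One row per wild-type sequence plus one per mutant. Wild-type rows are
labeled benign: with 259 mutants (113 pathogenic) and 23 wild types this
yields the 40/60 pathogenic/benign balance the modeling protocol assumes,
which is the reason for the choice. Records whose annotated wild-type
residue disagrees with the sequence are dropped and counted, never
silently fixed; duplicates are deduplicated with a log entry. Mutants
inherit their wild type's partition (point substitutions do not move
boundaries).

## Modeling protocol

Four architectures: SVM (RBF/polynomial kernels), logistic regression,
random forest, XGBoost, each wrapped in a scikit-learn estimator whose
pipeline standardizes features **inside the training fold only**
(leakage-safe default). Standardization uses the population (divide-by-n)
standard deviation; zero-variance columns keep scale 1 and become
all-zero with a warning. A `paper_mode` switch standardizes once on the
whole matrix before splitting instead, reproducing the common
fit-once-on-everything protocol; both are exposed, the leakage-safe one
is the default, and the divergence is deliberate.

Performance estimation is repeated stratified k-fold CV, default 10 folds
× 10 repeats, reported as mean ± sample sd over folds for accuracy, F1,
precision, sensitivity and ROC AUC with pathogenic as the positive class.
ROC AUC is computed within each fold from held-out probabilities and
averaged over folds. Undefined ratios (no positive calls / no positive
truths in a fold) become NaN with a warning and are excluded from
aggregation. Grid search is exhaustive over shipped default grids (SVM:
kernel × C × gamma; LR: C; RF: trees × depth; XGBoost: trees × depth ×
learning rate — package defaults spanning the usual operating ranges, as
the search protocol rather than specific candidate values is the fixed
part of the method); the selection criterion is mean CV accuracy, ties
broken by mean ROC AUC then first-in-grid order. All stochastic
components derive from a single run seed; the CLI derives per-stage seeds
by a fixed hash so a manifest fully determines a run.

## Feature importance

Built-in importance is Gini impurity decrease for the tree ensembles
(sums to 1) and absolute coefficient magnitude for logistic regression;
non-linear SVM kernels have no per-feature attribute and raise — for the
SVM, only permutation importance feeds the consensus, which then equals
its permutation top-k. Permutation importance shuffles each feature
`n_repeats = 10` times and records the mean accuracy drop on the supplied
rows. Domain ranking aggregates a domain's per-feature scores by the
**sum of absolute values** (mean and max are available; the choice is a
package decision since three z-components must be reduced to one domain
score), descending, ties broken by ascending domain index. The consensus
domain set of two rankings is the intersection of their top-k (k = 6)
sets, ordered by the first ranking.

## Minority-rule consensus

A variant is consensus-pathogenic iff at least one member model predicts
pathogenic; the consensus score is the maximum member pathogenic
probability. Two consequences are asserted as invariants: consensus
sensitivity ≥ every member's, and consensus precision ≤ every
positive-calling member's. External evaluation removes panel variants
from the training rows first (by `seq_id:variant` row id), then reports
per-model and consensus confusion counts and metrics plus an audit table;
assay phenotypes map to labels as {as WT, slightly reduced} → benign,
{no response, reduced} → pathogenic.

## Synthetic data generator

`generate_family` emulates a paralog family with a shared 12-domain
architecture: a uniformly random ancestor, members by independent
per-site substitution (default divergence 0.1 — the conserved-core end of
a transporter family's identity range, chosen so the family is
recognisably related at the default sequence length), and occasional 1-3
residue insertions only at domain junctions (probability = divergence per
junction), assigned to the end of the preceding domain — so the true
partitions are known and the emitted alignment recovers them exactly by
construction. Default domain lengths (40, 20, 22, 18, 24, 20, 26, 15, 21,
19, 23, 32; 280 residues total) are shorter than real transporter domains
to keep one mutation's effect on a domain mean detectable and the test
suite fast.

`generate_variants` plants the signal in descriptor space — the very
quantity the encoding averages, so recovery is a genuine end-to-end test
of encoding + modeling rather than a leak. Pathogenic variants sample
positions inside the sensitive domains and alternates with probability
∝ exp(effect_size · d/d_max), where d is the z-scale Euclidean
displacement from the wild-type residue; benign variants sample positions
anywhere with weight ∝ exp(−effect_size · d/d_max). `effect_size` is the
inverse temperature of this preference: the default 6 makes pathogenic
substitutions nearly maximal-displacement, and 0 collapses both classes
to the identical null distribution (uniform position anywhere, uniform
alternate — including the position rule, so the null truly carries no
signal). Class balance defaults to 40/60 pathogenic/benign.

What the generator does **not** emulate: phylogenetic correlation between
members (all are independent draws from one ancestor), realistic
full-family divergence (real paralogs can exceed 50% divergence, where
between-member feature variance would swamp single-mutation shifts),
structure-mediated mutation effects, position-dependent mutability, or
label noise. Passing the recovery tests therefore demonstrates that the
pipeline detects a descriptor-displacement signal localized in a domain
under favorable, known conditions — not that real clinical labels are
predictable at the same accuracy.

## Problem sizes and tolerances

The recovery study uses a 12-member family with 150 benign + 100
pathogenic variants, a random forest of 200 trees, and 5×5 repeated
stratified CV; importance recovery uses 10 independently seeded
replicates with 10 permutation repeats. These sizes were chosen so the
whole suite runs in a couple of minutes on one CPU while keeping the
fold-level dispersion small. Under the null (effect 0) the labeled matrix
is 62% benign, so a noise-fit classifier drifts toward the majority rate
≈ 0.6 rather than 0.5; the chance check is therefore phrased as "within
3 fold-sd of 0.5", which the fold dispersion at these sizes
accommodates, though marginally — at some seeds the gap sits near the
3-sd boundary. Floating-point assertions use 1e-9…1e-12 tolerances where
identities are exact and Monte-Carlo tolerances where they are not.

## Known limitations

- Ten of the thirteen descriptor sets are synthetic placeholders (above);
  full-sequence encodings are structurally complete but only the z-scale
  content is physicochemically meaningful.
- Only single-residue missense substitutions are supported; indels,
  stops and nucleotide-level notation are rejected at parse time.
- Three-letter residue codes and HGVS notation must be converted
  upstream.
- Reference domain boundaries are user configuration; the package
  transfers but never derives them.
- The minority rule maximizes sensitivity by construction and will
  inherit any member's false positives; it is the right ensemble only
  when false negatives are costlier than false positives.
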