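# Methods

## Molecular graphs and stereo perception

Structures enter as SMILES, one record per glycoconjugate including the
spacer/linker and the immobilization carboxylic acid; the library never
appends linker chemistry itself. Parsing (RDKit) produces a heavy-atom
graph whose nodes carry element, a hybridization class (sp/sp2/sp3/other),
the attached-hydrogen count, and a tetrahedral CIP descriptor (R/S, or
"none" for atoms without defined configuration). Stereo is perceived once
at parse time. Multi-fragment inputs are rejected: a glycoconjugate record
is a single molecule.

## Atom q-grams (AQG)

`enumerate_aqg` counts all connected **induced** subgraphs of the
heavy-atom graph with 1..q atoms. Induced subgraphs (rather than edge
subsets) match graphlet/q-gram conventions and keep the census finite and
interpretable. Enumeration is ESU-style: every connected vertex subset is
generated exactly once from its minimum vertex via exclusive-neighbor
extension. Each subgraph is keyed by a canonical code obtained by
exhaustive minimal-form search: among all vertex orderings consistent with
the sorted node-label sequence, the lexicographically smallest
upper-triangle adjacency bitstring is taken. Exhaustive canonicalization
is provably canonical and independently testable (the suite checks it
against brute-force subset enumeration with VF2 isomorphism grouping);
its factorial worst case is acceptable for q ≤ 4–5 and feasible up to the
supported q ≤ 8, but it is the reason the default experiments use q = 4.

Bond orders are not encoded; node hybridization serves as their proxy.
Node labels are assembled from four switchable features (element,
hybridization, H-count, chirality); with all four off the census counts
pure shapes, which is the ablation baseline. Chirality labels inside a
subgraph are the parent molecule's CIP descriptors — they are not
re-perceived on the fragment, since the fragment is a probe of the parent's
configuration, not a standalone molecule.

## Circular fingerprints

`circular_fingerprint` wraps RDKit's Morgan generator with *unfolded*
identifiers: the full 32-bit environment ids are kept as dictionary keys
rather than folded into a fixed width, so dimensionality is exactly the
number of distinct environments in the input set and collisions cannot
silently merge features. Chirality enters through the standard
`includeChirality` atom invariants. Standard connectivity invariants
(element, degree, H count, charge, ring membership) are used; the radius
bound r ≤ 6 is a sanity limit, with r = 3 the conventional default.

One caveat found during development: inverting chiral tags on a molecule
in place leaves the generator's stereo perception stale. All stereoisomer
generation therefore round-trips variants through canonical SMILES before
any fingerprinting.

## Vocabularies and vectors

A vocabulary is the lexicographically sorted union of codes over a
training set — deterministic regardless of input order. Vectorization
aligns a count map to the vocabulary; codes unseen at vocabulary time are
dropped (with a logged count), which is the cold-start behaviour every
fixed-dimension encoder shares: a new molecule can only be described in
terms of substructures the training set exhibited.

## RFU calibration

Per array, net spot signal is foreground − background averaged over the
(nominally six) replicate spots; negative means are kept at this stage.
The non-/weak-binder peak is found by Gaussian KDE with bandwidth 0.2 and
the maximum of the density below 4000 RFU taken as the background peak.
Two choices the bandwidth and cutoff do not themselves fix:

* the KDE is computed on **log10(RFU)** — a 0.2 bandwidth is only
  physically meaningful on the log axis, where array signal spans three
  decades; non-positive net values carry no information about the
  background mode and are excluded from the density (they are still
  rescaled afterwards);
* the density is evaluated on a uniform 512-point log10 grid spanning the
  data, the maximum is restricted to grid points below the cutoff, and
  ties break toward the lower RFU.

Fractions bound are then the linear rescale f = (RFU − peak)/(65,536 −
peak) clamped to [0, 1]; the global maximum 65,536 is a configurable
constant (16-bit scanner saturation). Arrays are grouped by exact match of
(cbpID, sample description, investigator); groups with fewer than three
distinct concentrations are dropped, since fewer points cannot constrain a
concentration dependence.

Resampling onto a grid interpolates f linearly in log10(C) and holds the
nearest endpoint constant outside the measured range. Constant
end-extrapolation deliberately avoids inventing sigmoid parameters the
data do not determine; it also gives the natural expansion of
single-concentration measurements into constant profiles. Concentration
units (μg/ml for arrays, μM for affinity data) are carried explicitly and
never interconverted — molar masses are not known for all lectin
preparations — so a lectin group lives in one unit throughout.

Affinity constants convert by single-site occupancy f = C/(C + Kd), with
Kd = 1/Ka; f(Kd) = 0.5 exactly and f → 0 at vanishing concentration. The
dense grid is {1, 1.5, 2, 3, 4, 5, 7} × 10^(−5..1) plus 100 μM — 50
points; the coarse grid is 0.1/1/10/100.

## The regressor

A fully connected network with tanh hidden layers (default 2 × 100,
within the 2–3 layers × 50–100 units family) and linear outputs maps
[M / s, (log10 C − μ)/σ] to one f per lectin; s is the maximum absolute
count over the training matrix, μ and σ standardize log10 concentration
over the training rows. Outputs are clamped to [0, 1] only at reporting
time — raw outputs may leave the interval, and thresholding predictions at
f > 0 relies on that. Monotonicity in C is not enforced. Prediction at
C = 0 is an error (log transform), not a silent zero.

Training is Adam (lr 0.001, weight decay 0.0001 coupled into the
gradient, the convention of the common Adam implementations), 200 epochs
of shuffled minibatches of 64, all seeded. The loss is MSE over observed
targets only: unobserved (molecule, concentration, lectin) triples
contribute exactly zero gradient, so records observed on three outputs
train identically to a three-output model, and appending fully unobserved
records is a no-op (both properties are asserted in the suite). The
optimizer, forward and backward passes are written directly on numpy
arrays; at these widths a deep-learning framework adds no speed.

Folds are assigned to structure groups (canonical SMILES of the full
record by default, or a caller-supplied key), shuffled by a seeded RNG and
dealt round-robin, so folds are balanced within one group and molecules
sharing a structure — and all concentrations of a molecule — stay
together. Dataset-subset experiments (array-only, affinity-only, merged,
output-restricted) are pure dataset filters over the same architecture.

## Stereoisomer generation

Enantiomers invert every defined tetrahedral parity; epimers invert
exactly one, in atom-index order. Only tetrahedral centers are handled —
axial/planar chirality does not occur in these datasets — and atoms with
undefined configuration stay undefined in every variant. Double-bond
geometry is untouched (reflection preserves cis/trans). Variants
round-trip through canonical SMILES, so enantiomer∘enantiomer is the
identity on canonical forms, |epimers| equals the stereocenter count, and
constitution (formula, heavy-atom graph) is preserved; CIP letters at
*other* centers may relabel after a single inversion in rare relational
cases, which is why variants are compared as whole molecules rather than
letter-by-letter.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not glycan biochemistry in full:

* **Structures** come from a grammar of pyranose-like six-rings: five
  ring stereocenters with random @/@@ tags, three decoration sites drawn
  from hydroxyl (p = 0.6), acetamido (0.25) or deoxy (0.15), and one of
  four alkyl/glycolyl linkers ending in the immobilization carboxylic
  acid. Every emitted SMILES is valid, connected, and stereocenter-rich;
  duplicates are rejected. Optionally 30% of the molecules form exact
  enantiomer pairs (generated through the stereo module), sharing a
  `base_id` so grouped CV can hold a pair out together.
* **Binding truth** is motif-based: each synthetic lectin matches a
  substructure query — mostly chirality-sensitive single- or two-center
  ring configurations (the single-center case mirrors how real lectins
  separate epimeric sugars such as Gal/Glc), plus one achiral
  acetamido-recognizing control — and assigns Kd,hit of 0.2–0.5 μM to
  carriers, Kd,miss = 1 M to everything else. Hit affinities are strong
  enough that the weakest default dose (0.1 μM) produces signal well
  above the background-peak search window, and misses are true
  non-binders at every dose; both properties are required for the
  calibration loop to be well-posed, and hit rates (~20–50%) leave
  binders and non-binders in every fold.
* **Arrays**: per (lectin, concentration), each molecule's net RFU is a
  log-normal background draw (mode 150 RFU, spread 0.2 decades) plus
  f · (65,536 − 150), with six replicates carrying 10% multiplicative
  noise, clipped at the scanner maximum, over a 4-point μM grid.

Not modelled: multivalency/avidity, spot-printing artefacts, saturation
nonlinearity below the hard clip, inter-array batch effects, or sequencing
readouts. Passing the closed-loop tests therefore shows the pipeline's
statistical machinery is correct under its own assumptions, not that real
arrays are this well behaved.

## The recovery experiment and its scoring

The end-to-end experiment uses 200 molecules (30% enantiomer pairs), 5
lectins, the 4-point grid, 10-fold grouped CV, AQG q = 4 features, and
the default training budget — sizes chosen so the full loop runs in tens
of seconds on one CPU. Enantiomer pairs are grouped into the same fold,
so a pair is always predicted by a model that saw neither member:
chirality knowledge must come from diastereomers in the training folds.

Recovery is scored as the Spearman correlation between true and held-out
predicted f over all triples, after values below 0.05 — the pipeline's
stated calibration accuracy — are reported as zero on both sides. The
floor is an identifiability requirement, not a convenience: non-binder
true fractions (10⁻⁷..10⁻⁴ across the dose range) are strictly ordered
mathematically but lie two orders of magnitude below the calibration
noise, so without the floor even a perfect predictor of the calibrated
targets scores only ρ ≈ 0.5 and the statistic measures the truth
surface's sub-noise microstructure rather than model quality (with the
floor, that same perfect predictor scores ρ ≈ 0.99).

The chirality ablation re-runs the identical experiment with chirality
dropped from the node labels. Mirror-image pairs then featurize
identically, so within any one model their predictions are *exactly*
equal — the ablated enantiomer gap is zero by construction, while the
chirality-aware model separates discordant pairs by a large margin. This
pairing (able vs structurally blind) is the package's central scientific
property.

## Known limitations

* Cold start: molecules contributing only unseen substructure codes
  vectorize toward zero and predict like the training-set background.
* Exhaustive AQG canonicalization is factorial in q-gram size; q ≥ 5 on
  large sets calls for a refinement-based canonizer.
* The regressor does not enforce monotonicity of f in C, and clamping can
  hide systematic negative drift in raw outputs.
* μg/ml and μM data streams can be merged into one model only through an
  external grouping of lectins; the package will not convert units.
* The 11 comparison metrics return NaN (with a warning) on zero
  denominators; downstream aggregation must handle NaN explicitly.
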