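# Methods

## The model

`pharmgnn` predicts molecular properties with a message-passing neural
network that pools atoms hierarchically through a *pharmacophore reduced
graph* (RG).  A molecule is a heavy-atom graph `G = (V, E)`; the RG
`RG = (V', E')` collapses atom groups into typed pharmacophore nodes while
preserving topology.  The forward pass has four phases:

1. **Atom-level message passing** (K rounds).  Atom states start as a linear
   map of the atom feature vector.  Each round, every atom gathers messages
   from its bonded neighbours with single-head attention: the compatibility
   score is a learned linear form of the center and neighbour states (plus a
   bond-feature term), passed through a leaky rectifier (slope 0.2) and
   softmax-normalized over the neighbour set.  Bond features enter the
   neighbour's score and value terms rather than the message function
   itself, so the first round effectively sees a linear map of concatenated
   neighbour-atom and bond features.  The update producing state `h^j` adds
   the message to `j − 1` skip-connection residuals — learned linear maps of
   the earlier states `h^1 … h^{j−1}` — before a rectifier and dropout.  The
   residuals keep gradients alive across rounds.
2. **Graph reducing.**  Per pharmacophore node, the *initial state* `S_rg`
   is the sum of its member atoms' final hidden states; an attention gather
   over those members yields a message; a gated recurrent unit (GRU) blends
   the two, with `S_rg` as the carried state and the message as the input
   (the orientation is configurable).
3. **RG-level message passing** (T rounds) over the reduced graph, same
   attention + GRU pattern.  The integer RG edge weight is clipped at a
   configurable maximum, embedded as a learned vector, and injected into
   score and value terms exactly like a bond feature — symmetry between the
   two levels.  A molecule whose RG has a single node skips this phase
   entirely (its state passes through unchanged and the output is flagged);
   a strict mode rejects such molecules instead.
4. **Molecule readout** — graph reducing's special case where every node
   belongs to one group.  `S_mol` is the sum of node states; the attention
   weights over nodes are exposed as the *per-pharmacophore importances*;
   the GRU output `h_mol` is the molecule embedding and doubles as the
   task-learned fingerprint.

A two-layer rectified MLP maps `h_mol` to the output: one value per task for
regression, a two-score column pair per task for classification (paired with
a cross-entropy loss; missing labels are masked).

The network, its gradients and the Adam optimizer are implemented on a small
reverse-mode automatic-differentiation core over NumPy float64 arrays
(`pharmgnn.autodiff`), with graph batches expressed as disjoint unions and
all gather/softmax/pool steps as segment operations.  Float64 arithmetic
makes runs bit-reproducible under a fixed seed and keeps finite-difference
gradient checks tight (~1e-6).

## The reduction scheme

Eighteen node types: the product of three ring categories — aromatic ring >
aliphatic ring > acyclic — and six feature categories — positively
ionizable > negatively ionizable > joint donor/acceptor > donor > acceptor >
no feature — each list in priority order.  Types carry two-letter
element-symbol aliases; five are fixed by the naming scheme this package
follows (Y, Co, Ti, Ni, Sc) and the remaining thirteen are package-assigned.

Feature evidence comes from a SMARTS table
(`pharmgnn/data/pharmacophore_smarts.tsv`) covering ionizable groups at
physiological pH (amines, amidines/guanidines, imidazole; carboxylic/
sulfonic/phosphonic acids, tetrazole, acidic imide N–H, bare ions), N–H/O–H/
S–H donors and N/O lone-pair acceptors.  The table is a plain-text file and
deliberately editable: rows can be replaced wholesale to swap in another
perception scheme.  Priority resolution happens at the group level on the
union of member-atom evidence; *joint donor/acceptor* fires when donor and
acceptor evidence are both present (whether on one atom, e.g. hydroxyl, or
different atoms of one group, e.g. pyrazole).

Grouping rules (frozen, with the genuinely open choices resolved as
follows):

* **One node per SSSR ring.**  Fused systems become one node per smallest
  ring rather than one node per ring system; the fusion is expressed by the
  edge-weight rule below.  Atoms on a fusion bond belong to both ring nodes
  — the only case of multiple membership.
* **Edge weight = 1 + number of bonds shared by both nodes.**  A bond is
  shared only when both endpoints belong to both nodes (a ring-fusion
  bond).  Naphthalene's two rings therefore connect with weight 2 while
  biphenyl's connecting bond gives weight 1 — the weight distinguishes
  fusion from linkage.
* **Acyclic runs.**  Contiguous acyclic atoms with the same per-atom
  resolved feature category merge into one node; featureless linkers form
  their own no-feature nodes.
* **Exocyclic substituent atoms** (phenol O, aniline N…) form their own
  acyclic nodes rather than joining the ring node.

## Molecule handling

Parsing, SMARTS matching, scaffolds and drawing all go through RDKit.
Molecules are re-parsed from their canonical SMILES so atom order is
canonical and featurization is spelling-invariant.  Standardization keeps
the largest fragment by heavy-atom count (ties by molecular weight),
neutralizes charges where a neutral form exists, and rejects results with no
carbon.  Atom features: element one-hot (B/C/N/O/F/Si/P/S/Cl/Br/I + other),
formal charge, degree and H-count one-hots, hybridization, aromaticity,
chirality — 37 dimensions.  Bond features: type, conjugation, ring
membership, stereo — 11 dimensions.  The encoding is frozen under
`FEATURE_VERSION`.  Activity labeling uses a 1000 nM potency threshold with
the boundary convention *active iff potency < 1000 nM*.

## Training protocol

Splits are 8:1:1, random or Bemis–Murcko scaffold-grouped (whole scaffold
groups assigned greedily in seed-shuffled order; a scaffold never spans two
partitions; acyclic molecules share the empty-scaffold group).  Experiments
repeat five times; reports carry mean ± standard error with SE defined as
the across-run standard deviation (ddof = 1) divided by √5.  Metrics: RMSE
for regression; mean per-task ROC-AUC and Matthews correlation for
classification, missing labels masked, with AUC reported as missing (with a
warning) for single-class partitions.

Training is mini-batch Adam (learning rate 1e-3 by default) with L2 weight
decay on weight matrices and regression labels standardized with
training-set statistics.  Early stopping and checkpoint selection follow a
*monitored* quantity that keeps improving as the model organizes: RMSE for
regression and validation cross-entropy for classification (defaults: 300
epochs, patience 30).  ROC-AUC is reported alongside but deliberately not
monitored — on an easily separable task AUC saturates within a few epochs,
and selecting checkpoints by it would freeze the network before the readout
attention has specialized, hollowing out the interpretability the
architecture exists for.  The hyperparameter search draws uniformly from
the fixed space — weight decay {1e-3, 1e-4}, K {2..5}, T {1..3}, batch
{16, 32}, hidden/fingerprint dimension {64, 128, 256, 512}, dropout
{0 .. 0.5} — and each trial runs a short schedule (20 epochs, patience 5,
enough for attention allocation to stabilize on the synthetic tasks);
trials are compared by the monitored validation quantity and the best
trial's already-trained model is returned and reused across repeats rather
than re-searched.  One reading note on the searched space: the source
protocol labels the first parameter "base_lr (base L2 weight decay)",
conflating two names; this package reads it as weight decay and exposes the
learning rate separately.

## Synthetic data

The fixture generator assembles molecules from hand-curated pools: twelve
single-ring scaffolds covering all twelve ring-bearing types (benzene,
pyridine, pyrrole, pyrazole, imidazole, tetrazole, cyclohexane,
tetrahydropyran, piperidine, 2-pyrrolidinone, morpholin-3-one, succinimide)
and ten substituents covering the six acyclic types (methyl, ethyl,
hydroxyl, methoxy, nitrile, carboxyl, aminoethyl, acetamido, aromatic-only
amino, fluoro).  Substituents attach only to ring carbons bearing hydrogen
and never to each other, so each fragment's node-type contribution is
context-free (the one context-sensitive fragment, the amino substituent, is
restricted to aromatic rings) and the molecule's ground-truth type multiset
is the sum of its fragments' tags — recorded at generation time,
independent of the reduction code, which is what makes the library an
oracle for it.  A second ring system is attached with probability 0.35 and
1–3 substituents per molecule; 200 molecules guarantee full 18-type
coverage via stratified cycling.  Labels are linear in ground-truth type
counts plus Gaussian noise (regression) or the indicator of a target type
(classification).

What the generator does *not* emulate: realistic drug-likeness, tautomerism,
stereochemistry-dependent activity, activity cliffs, label noise structure,
or assay artifacts.  Passing tests therefore demonstrate that the machinery
is correct and that RG-determined signals are recoverable — not that the
model reaches any particular accuracy on real assay data.

## The self-organizing map

Fingerprints project onto a rectangular lattice (default 10×10, 200 epochs)
by batch SOM: each epoch assigns every molecule to its best-matching unit by
Euclidean distance and replaces each codebook vector by the Gaussian-
neighborhood-weighted mean of the assigned points, the radius decaying
exponentially (1.5 → 0.2 by default).  The codebook initializes on the plane
of the first two principal components, so the lattice is topographically
ordered from the start; combined with a backtracking safeguard (an update
that would raise the quantization error is halved toward the previous
codebook), the per-epoch quantization error is non-increasing by
construction.  Random data-row initialization and a wider radius remain
available (`init="sample"`), trading early error increases for training-time
self-organization.  Neurons holding both actives and inactives are flagged
as conflict neurons.

## Numerical and degenerate-input choices

* Attention over an empty gather set (an isolated atom, a node with no RG
  neighbours) returns a zero message; segment softmax shifts by the segment
  maximum for overflow safety with exact gradients.
* Single-pharmacophore molecules are accepted and flagged by default
  (strict mode rejects them).  Because the first atom update has no
  residual terms, a molecule with no bonds at all (methane) carries no
  atom-feature signal into its embedding; such molecules are out of the
  method's intended domain.
* RG edge weights clip at 4 for the learned embedding; weights above that
  are chemically rare (≥4 shared fusion bonds).
* One integer seed drives weight initialization, batch shuffling, dropout
  masks and search sampling; fixed seeds reproduce runs bit-for-bit.
* Early stopping restores the best-validation checkpoint; a non-finite loss
  aborts with a diagnostic rather than continuing.

## Known limitations

* The attention functional form at the atom level is a reconstruction of
  the cited graph-attention construction (single head, concatenation score);
  multi-head variants are out of scope.
* The reduction's fused-ring granularity and exocyclic-substituent
  assignment are documented interpretations; alternatives (whole ring
  systems as one node) would change node counts on fused scaffolds.
* The SMARTS table is a curated reconstruction of standard pharmacophore
  perception rules, not a transcription of any specific published table;
  it is shipped as data so users can substitute their own.
* Problem sizes in the tests and the acceptance script (200-molecule
  oracle library, 50-molecule capacity check, 1000-molecule learnability
  task with a budget-5 search) are the package's chosen study conditions
  for desk-scale verification; external benchmark corpora are supported via
  the CSV reader but not bundled.
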