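# Methods

## Model

The predictor scores a drug–protein pair through three encoder branches
and an interaction transformer.

**Protein branch.**  Residues are graph nodes.  Edges come from three
deterministic rules: peptide bonds between chain neighbours; backbone
hydrogen bonds wherever an N(i)–O(j) distance falls below 3.5 Å with
sequence separation |i−j| ≥ 3 (a standard geometric criterion that needs
no hydrogen placement); and each residue's k = 5 nearest Cα neighbours,
ties broken toward the lower residue index, symmetrised.  The GCN treats
the union of the three edge sets as one adjacency; the types are carried
as attributes for typed variants.  Node features concatenate a 1280-d
per-residue embedding from a pluggable language-model provider with three
residue properties: formal charge at pH 7, isoelectric point, and
Kyte–Doolittle hydropathy.  "X" residues receive the column-wise mean row.

**Drug branch.**  Heavy atoms are nodes; edges are the bonds parsed from
the SMILES.  Hydrogens are implicit and carried as a per-atom count.
384-d per-token embeddings are reduced to one row per atom by a
grammar-walk alignment: tokens are matched left-to-right, atom-bearing
tokens (element symbols, aromatic symbols, bracket atoms) pair with RDKit
atom order, and the pairing is validated by an exact count check.  Atom
properties (element one-hot, degree, formal charge, aromaticity, implicit
hydrogens) complete the node features.

**Feature balancing.**  A handful of property columns sits next to more
than a thousand embedding dimensions; concatenated naively, the first GCN
layer is initialised essentially blind to the properties.  Property blocks
are therefore standardised with fixed constants (the 20-residue table's
statistics for proteins; nominal count/flag scales for drugs) and rescaled
so both blocks carry comparable total energy.  This is a representation
choice, not a data change: it applies identically to every entity.

**Subpocket branch.**  Pockets are ranked by their ligandability score
(stable sort, descending; rank 1 is best).  Subpockets are pooled in
pocket-rank order — within a pocket, in assignment-file order — until the
cap M = 30; a pocket that cannot be decomposed contributes itself as a
single subpocket.  Covalently connected fragments (proxy: inter-atomic
distance ≤ 2.0 Å) with fewer than five atoms are discarded; a subpocket
with no surviving fragment is dropped before padding.  Remaining slots are
filled with placeholder graphs of one zero-feature node.  Subpocket atom
graphs carry covalent edges (≤ 2.0 Å) and typed contact edges (≤ 4.5 Å);
contact edges keep message passing informative across the disconnected
fragments of a cavity lining.  Atom features are element one-hots, a
backbone flag, and the parent residue's charge, hydropathy and
aromatic-ring flag.  One shared-weight GCN encodes all M graphs, so
identical graphs give identical rows of the M × d output.

**Encoders.**  Graph convolution uses the symmetric-normalised adjacency
with self-loops, three layers of width d = 128, ReLU, dropout 0.1.
Pooling concatenates the element-wise max over nodes with an
attention-gated weighted sum (softmax over a learned per-node scalar) and
projects linearly to d.  Protein, drug and subpocket encoders have
distinct parameters; only the subpocket encoder is shared across the set.

**Interaction transformer.**  The (M+2) × d token matrix is ordered
[drug, protein, s_1 … s_M].  Positions are 0 for the two global rows and
for placeholders, and the parent pocket's rank k_i for real subpockets;
they index a zero-initialised learned embedding table, so the encoding
starts as the identity and training decides its geometry.  One post-norm
encoder layer (4 heads, feed-forward 512, dropout 0.1) updates the tokens;
placeholder tokens are not masked (an optional mask exists, off by
default).  The head concatenates the updated drug and protein rows into a
2d vector, passes it through a ReLU MLP (2d → d → d/2) and a final linear
unit, and applies a sigmoid.  Binary cross-entropy is clipped at
ε = 1e-7 to avoid log 0 without measurable bias.

**Query/key initialisation.**  At d = 128 a Glorot-width query/key
product collapses the softmax to near-uniform attention, and with the
shallow training budget the attention maps can stay flat even when the
classifier is accurate, which makes them useless for interpretation.  The
query and key weights are therefore initialised 5× wider
(`qk_init_gain`), which keeps early attention non-degenerate so that
useful patterns can be retained by training.  Predictive accuracy is
insensitive to this choice; interpretability is not.

**Training.**  Adam, learning rate 1e-4, batch size 32, up to 30 epochs.
After each epoch the model is scored on the validation fold; the returned
checkpoint is the one with the best validation ROC-AUC.  Early stopping
(patience 6 non-improving epochs, configurable) shortens runs that have
converged — in practice convergence arrives between epochs 10 and 25.
Arrays are float32; all randomness (shuffling, dropout, initialisation)
is driven by explicit seeded generators, so a fixed seed reproduces a run
bit-for-bit on one CPU.

## Evaluation protocols

Random split: seeded pair-level shuffle, 7:2:1.  Unseen-entity split: 20%
of drugs (or proteins) are sampled and *all* their pairs become the test
fold; the rest splits 7:2 into train/valid.  Cross-domain split: drugs are
clustered by single linkage on Jaccard distances of 1024-bit radius-2
circular fingerprints (cut at 0.6), proteins on cosine distances of
amino-acid + dipeptide composition vectors (420-d, cut at 0.12 — chosen so
realistic fixture sets form multiple clusters per side; both exposed as
parameters); 60% of the clusters on each side define the source domain,
pairs with both entities in source clusters train (with 1/8 carved out
for validation, mirroring the 7:1 train:valid mass of the random split),
and 20% of the remaining target-domain pairs are the test fold.  Metrics:
ROC-AUC, PR-AUC, and sensitivity/specificity at the best-F1 threshold
scanned on validation scores only.

## Embedding providers

The architecture depends only on the widths (1280 per residue, 384 per
token).  Any object with `dim` and `embed_tokens(tokens)` is a provider.
The bundled stub provider returns unit-variance pseudo-random rows keyed
by a hash of (seed, token, position) — deterministic across platforms,
with no pretrained content.  Sequences beyond a provider's context window
are embedded in overlapping windows (overlap 64) and stitched from window
centres.  Embeddings can be cached on disk keyed by content hash.

## Geometric fallback pocket detector

When no assignment file is supplied, pockets come from a grid-and-ray
scan: grid points (default spacing 1.0 Å) at least a probe radius
(1.4 Å, the water convention) from every atom are kept if at least 9 of
14 scan rays (6 axial + 8 diagonal) hit protein within 8 Å.  Buried
points are clustered by grid adjacency; clusters smaller than 5 points or
without any point ≥ 2.5 Å from every atom are surface grooves and are
discarded; each pocket is split into subpockets by eroding the point
cloud at narrow apertures and re-growing around the cores.  The score is
the buried-point count normalised to the largest pocket; lining atoms are
those within 4.5 Å of a pocket point.  This is deliberately simple
plumbing — a real cavity-detection export should be preferred when
available.

## Synthetic benchmark

The generator emulates the statistical structure the model assumes:
binding decided at the subpocket level.  Structures are geometric toys,
not physical proteins — a Cα trace wound as a spherical spiral shell
around each cavity (so cavities are genuine enclosed voids with lining
atoms) and continued as a clash-free random walk, relaxed so consecutive
Cα distances stay within 3.8 ± 0.2 Å, with backbone N/C/O and Cβ atoms
placed from the local chain frame.  Each protein has 2 pockets of 2–3
overlapping spherical lobes (the ground-truth subpockets).  Every lobe
carries a *signature* class — basic (K/R), aromatic (F/W) or polar (N/Q)
— and its lining residues are drawn from that class with probability
0.85; filler residues avoid all signature alphabets.  Ligands (8–25 heavy
atoms) are carbon/heteroatom chains with motif branches — carboxylate
C(=O)O, benzene ring, amide C(=O)N — inserted at random positions; motif
presence is exact by construction and verified by substructure match.

A pair is positive iff the ligand carries a motif whose signature class
lines one of the protein's subpockets; the best-scored matching subpocket
is recorded as the causal site.  Labels are then flipped at the noise
rate.  Defaults: 200 proteins × 50 drugs subsampled to 2000 pairs, 52–64
residues per protein, 2 signatures per protein, motif probability 0.293
(which balances the classes near 50%), label noise 0.05, everything a
pure function of the seed.  Pocket scores are lining-atom counts on a
fixed scale plus mild noise, keeping them strongly rank-correlated with
ground-truth bindability.

What passing on this benchmark does and does not show: it demonstrates
that the architecture can learn a subpocket-level matching rule from
graph and property features, that the split protocols and metrics behave
as specified, and that attention over subpocket tokens recovers planted
binding sites.  It does not demonstrate chemical realism — the stub
embeddings carry no evolutionary or chemical prior, toy structures have
no side-chain packing, and real binding is not a boolean motif match — so
benchmark numbers say nothing about accuracy on experimental DTI data.

## Problem sizes and numerical choices

The shipped study runs 2000 pairs for up to 30 epochs on one CPU in a few
minutes (float32, ragged graph batches packed into block-diagonal sparse
adjacencies, repeated entities encoded once per batch).  Degenerate
inputs are defined: an empty pocket list yields M placeholders; a
single-node graph reduces the GCN to its layer stack and both poolings to
the node itself; ties in pocket scores keep input order; ties in
attention ranking resolve to the lower slot.  Attention-row
normalisation is asserted to 1e-5, permutation invariances to 1e-5, and
ROC-AUC against a concordance oracle to 1e-10 in the test suite.

## Known limitations

No mmCIF input, single chain per PDB, no insertion codes.  The H-bond
rule uses backbone geometry only.  The geometric detector is a fallback,
not a CAVIAR replacement.  Real language-model adapters are out of the
box only as the provider contract; plugging in ESM-2/ChemBERTa requires
their own packages.  Training is single-threaded CPU; the engine supports
exactly the operations this model needs.
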