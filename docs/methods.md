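# Methods

## Molecular graphs and features

Molecules enter as SMILES and are parsed with RDKit into heavy-atom graphs;
hydrogens appear only as an attached-H-count feature. Atom features
(23 dims): element one-hot over {C, N, O, S, F, Cl, Br, I, P, other},
heavy-atom degree one-hot 0–5, formal charge clipped to [−2, +2],
aromaticity bit, attached-H count one-hot 0–4. Bond features (6 dims):
order one-hot {single, double, triple, aromatic}, conjugation bit, ring
bit. This is the standard neural-fingerprint feature set; the choice is an
assumption of this package, not something the learning problem dictates.
Degrees above 5 are rejected at parse time because the convolution weights
are indexed by degree.

## Fingerprint construction

With L convolution layers (supported 1–4, default 3) and fingerprint
length F (default 32), atom states start as the raw atom features. Layer
l update for atom a of degree d:

    total_a = [state_a ⊕ 0_bond] + Σ_{b∈N(a)} [state_b ⊕ bondfeat_ab]
    state'_a = tanh(total_a · W_{l,d} + c_l)

Degree-0 (isolated) atoms use the d = 0 matrix with no pooled term. At
every step s = 0..L each atom writes softmax(state · O_s + o_s) into the
fingerprint, so Σ_i f_i = N_atoms (L + 1) exactly and each entry is
non-negative. Writing at step 0 as well as after each layer is a design
choice: it preserves atom-level information and yields the testable sum
invariant. tanh (rather than ReLU, which is used in the prediction head)
keeps the fingerprint smooth in the parameters.

Every write is retained as an `ActivationTrace`. The single-molecule
fingerprint is accumulated from the trace in a fixed order so that
`trace.total()` equals the fingerprint bit-exactly; the batched path may
differ from it by last-bit rounding (≤ 1e-15 relative), which the batch
tests tolerate at 1e-12.

## Prediction head and training

The fingerprint feeds `ann_layers` (2–4) hidden ReLU layers of width 64
(an architectural constant outside the tuning grid, as is the GCN hidden
width of 32) and a linear scalar output. Targets are standardized to zero
mean/unit variance on the training split and predictions un-standardized
to eV; with a constant target the standard deviation is forced to 1 so
training degenerates gracefully to fitting the constant.

Loss is MSE in standardized units plus L2 on weight matrices (biases
excluded). The optimizer is Adam with the grid learning rates; the
gradients through softmax writes, tanh convolutions and the ReLU head are
hand-derived and validated two ways: per-coordinate central differences
(step 1e-4, worst relative error ~1e-6, asserted < 1e-4) and a
full-gradient directional derivative (agreement ~1e-10). Training aborts
on a non-finite loss rather than continuing silently.

Early stopping fires when the last 20 validation losses span at most 0.01
(in standardized loss units — the natural units of the monitored
quantity). The comparison is inclusive and applied with a 1e-12 absolute
guard so that a span that is exactly the band in decimal (e.g. 0.51 −
0.50) is not rejected by float representation. Default epoch cap is 200.

## Ensembling

Members are trained independently from hyperparameters sampled without
replacement from the enumerated grid (216 combinations: 2 × 3 × 2 × 3 ×
2 × 3). The combiner is a linear layer over member outputs with identity
activation, initialized at uniform averaging (1/K, bias 0) and fitted on
the validation set with members frozen. Because the combiner is linear in
its parameters, each of its 3–5 training epochs applies one exact
Gauss–Newton step — the first epoch already solves the normal equations
and the rest are fixed points. This keeps the combiner "minimally
trained" while guaranteeing it is never worse than the best single member
on the validation set (the least-squares optimum dominates every
single-member selection).

## Substructure attribution

For each fingerprint index the maximal activation is the largest
*per-write softmax contribution* observed across molecules, atoms and
steps — not the post-aggregation fingerprint entry, which would conflate
many atoms' writes. The attributed substructure is the k-hop neighborhood
of the writing atom at the step k where the write occurred, with radii
reported in 1..4. Step-0 writes describe a lone atom before any pooling;
they are excluded from the default report and, when explicitly requested,
appear at radius 0 flagged `atom_only`. Ties break to the first
occurrence in (molecule, atom, step) order; with real-valued softmaxes
exact ties essentially never occur. Adding molecules can only raise each
index's maximum, which the tests check as a monotonicity property.

## Synthetic data

The generator assembles molecules atom by atom with explicit valence
bookkeeping: 4–30 heavy atoms drawn from C (66%), N (10%), O (12%),
S (4%), F/Cl (4% each, terminal only); random attachment builds a tree,
up to two ring closures join spare-valence atoms at distance 2–6, and
single bonds upgrade to double with probability 0.25 where both ends have
spare valence. RDKit sanitization is the final arbiter; the rare failure
redraws the molecule. Every emitted SMILES therefore parses back through
the package's own parser.

Two target modes:

* **surrogate** — target = −5.0 − 0.12·#C + 0.35·#N + 0.25·#O +
  0.5·#rings − 0.3·#double + N(0, 0.05²). The coefficients are fixed and
  documented so parameter recovery is testable: the features are exactly
  readable off the graph, so a correctly wired model should approach the
  noise floor. The benchmark (2,000 molecules, 70-15-15 split, the
  smallest grid model, ≤ 100 epochs) reaches held-out R² ≈ 0.97.
* **energy-like** — pseudo-HOMO and pseudo-LUMO correlated with the
  surrogate score, clipped to [−9.57, −2.60] eV and [−4.35, 2.81] eV
  respectively, emulating the span of B3LYP frontier-orbital energies in
  public small-molecule corpora.

Either mode can inject `n_extreme` quaternary-ammonium molecules
(`C[N+](C)(C)C` and homologues) with targets near −12 eV (HOMO) / −4 eV
(LUMO) — far outside the generated range, mimicking charged chemotypes
absent from training chemical space. After training on regular molecules
only, these injections produce the large residuals that the outlier
flagging (|standardized residual| > 3, zero-variance guard) must recover
exactly.

What the generator does *not* emulate: real electronic structure (targets
are composition surrogates, so tests show correct mechanics, not chemical
accuracy), stereochemistry, tautomers, charged species outside the
injected ammonium set, and molecules beyond 30 heavy atoms. Passing the
recovery tests demonstrates that the architecture, gradients and pipeline
are correct — not that the model matches DFT on real data, which requires
the external 111,725-molecule corpus and long training.

## Evaluation conventions

SMAPE uses denominator (|y| + |x|) with factor 100, bounding it at 100%;
a (0, 0) pair contributes 0 by the perfect-prediction limit, with a
strict mode that raises instead. R² is 1 − SS_res/SS_tot with the
convention R² = 1 for a perfect fit to constant data and 0 otherwise.
Residual outliers default to 3 standard deviations; note that with n
points the largest attainable standardized residual is √(n−1), so very
small sets need a lower threshold (the unit tests use 1.5 for an n = 4
hand example).

## Problem sizes

Default test and reproduction runs use 2,000-molecule surrogate
benchmarks, 1,200-molecule energy-like runs, 240-molecule ensemble
members and 20-molecule attribution sets — sizes chosen so the full suite
and the reproduction script each complete in about half a minute on one
CPU while leaving every claimed invariant exercised at realistic molecule
complexity.

## Checkpoints

Models and ensembles serialize to versioned JSON
(`molorb-checkpoint`, version 1); floats round-trip bit-exactly through
`repr`-faithful JSON, which the tests assert array-equal.
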