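# Methods

This note documents the models implemented in `aabp_allostery`, the
parameters that matter, the synthetic data the package generates in place
of crystal structures and molecular-dynamics trajectories, and the
numerical choices made where the design was genuinely open.

## Scientific setting

Periplasmic amino-acid-binding proteins (AABPs) such as the *E. coli*
glutamine- (GlnBP), histidine- (HisJ) and lysine/arginine/ornithine-binding
(LAOBP) proteins consist of two globular lobes — conventionally the
"Thumb" (large lobe) and "Index Finger" (small lobe) — joined by two short
hinge linkers. Substrate binding drives a closure of the two lobes around
the ligand, like a hand grasping a ball. The package provides the
coarse-grained toolchain used to dissect that closure: elastic-network
fluctuation analysis, trajectory statistics, learned residue-interaction
graphs, shortest-path signaling analysis and per-residue binding-energy
filtering. Cross-protein residue statements use a consensus numbering
(1–238) defined by the three-way sequence alignment; the consensus frame is
partitioned into eight segments (T-α 1–17, T-αβα 18–60, IT1 61–91, I-β
92–97, I-Loop 98–112, I-βα 113–156, I-2βα 157–185, IT2 186–238) and three
coarse regions (Thumb 1–85 ∪ 197–238, Linker 86–90 ∪ 193–196, Index Finger
91–192). The one-residue tension between IT1 ending at 91 and the Index
Finger starting at 91 is resolved in favour of the eight-segment table
(IT1 ends at 91, I-β starts at 92).

## Sequence alignment

Global affine-gap alignment (Needleman–Wunsch/Gotoh) with BLOSUM62,
gap open 11 and gap extend 1 — the classic protein-BLAST parameterization —
implemented through Biopython's `PairwiseAligner` (a gap of length L costs
`open + L·extend`). Percent identity is reported over the *trimmed*
alignment core: columns inside the first and last position where both rows
carry residues; internal gap columns count as mismatches. Coverage is the
fraction of the query spanned by that core. The three-way alignment is
progressive: the closest pair (highest pairwise identity, ties by input
order) is aligned first, then the third sequence is aligned to the pair's
column profile with the same gap scheme, scoring a residue against a column
by the mean BLOSUM62 score over the column's non-gap members. Tie-breaks in
the profile DP prefer substitution over a gap in the new sequence over a
gap column. No iterative refinement is performed; the MSA columns define
the consensus numbering.

## Gaussian network model (GNM)

Residues are nodes; pairs with Cα–Cα distance ≤ 7.3 Å (0.73 nm) are joined
by identical springs of stiffness γ. The Kirchhoff matrix Γ has −1 for
contacts and the contact count on the diagonal. With k_BT/γ = 1 (profiles
are in relative units), mean-square fluctuations and cross-correlations
come from the mode-restricted pseudoinverse,
`<ΔR_i·ΔR_j> = 3 (k_BT/γ) Σ_k v_ki v_kj / λ_k`. "Slow" defaults to the 2
lowest non-zero modes (two-lobe geometry: one hinge bend plus one twist)
and "fast" to the 10 highest, both configurable — the counts are a
convention of standard GNM practice. Hot spots are local minima of the
fast-mode profile below a quantile (default 0.25); hinges are local minima
of the slow-mode profile. Zero modes are detected at |λ| < 1e−8·λ_max
(double-precision eigensolver noise); their count equals the number of
connected components, and disconnected networks are analysed with a
warning.

## Anisotropic network model (ANM)

Pairs within 15 Å (the community-standard Cα ANM cutoff; the isotropic
model's 7.3 Å is too sparse for a stable 3N Hessian) contribute the 3×3
super-element `h_ij = −(γ/R_ij²) d_ij d_ijᵀ` of the Hessian, the exact
second derivative of the harmonic pair potential at the reference geometry
(validated against finite differences in the tests). The six rigid-body
zero modes are excluded from all derived quantities. Mode displacement
fields give per-residue motion directions and amplitudes. The open→closed
overlap is `|v_k·Δr|/(|v_k||Δr|)` computed *after* Kabsch superposition of
the closed onto the open structure on shared residues, which removes
rigid-body contamination from Δr; over a complete internal basis the
squared overlaps sum to at most 1.

## Trajectory statistics

Kabsch superposition uses the standard SVD solution with the determinant
sign correction. RMSF is computed after superposing all frames onto the
mean structure and re-iterating the mean once (the reference choice is a
documented convention, not physics). Relational-inference node features
are 6-dimensional — position and velocity in x, y, z — with velocities
taken from the integrator when available and from central finite
differences of the (strided) positions otherwise; each dimension is
standardized to zero mean and unit variance with the transform recorded,
which makes the learning insensitive to units.

## Relational inference (NRI)

A variational autoencoder over discrete edge types learns an interaction
graph from node feature trajectories. The encoder embeds each node's
windowed trajectory (window default 20 steps), passes messages once over
the fully connected pair graph (node→edge, edge→node, node→edge with a
skip connection from the first edge embedding), and emits K logits per
ordered pair (K default 4, with type 0 fixed as "no edge"; K = 2 is used
for binary recovery benchmarks). Edge samples are Gumbel-softmax relaxed.
The decoder sends per-edge-type MLP messages gated by z and predicts the
next step through a skip connection; during training the ground truth is
re-fed only every 10 steps and the decoder otherwise rolls out its own
predictions, so reconstruction error compounds unless the inferred graph
is right. The ELBO uses a fixed-unit-variance Gaussian likelihood on the
standardized features and a uniform categorical prior.

Two annealing schedules stabilize the notoriously collapse-prone joint
optimum on single systems: the Gumbel temperature anneals linearly from
2.0 to 0.5, and the KL weight from 4.0 to 1.0 over the first half of
training. Without them the posterior saturates into an all-edge state
whose logits no longer pass gradients. Everything — MLPs, Adam,
backpropagation through the rollout and the Gumbel reparameterization —
is implemented directly in NumPy with hand-derived gradients (checked
against central finite differences to ~1e−6 relative error), sized for a
few dozen nodes on one CPU. Training is exactly reproducible given the
config seed.

Edge-recovery benchmarks follow the field's standard protocol: spring
networks of 5 unit-mass particles (zero-rest-length springs, edge
probability 0.5, velocity-Verlet, dt 0.05) observed for 3 independent
rollouts of 4000 steps each, features strided by 4 so one model step spans
appreciable dynamics. Residue trajectories are coarse-grained by averaging
blocks of 10 consecutive residues (238 residues → 24 blocks) before
training; block-level edge probabilities are aggregated into
domain-interaction matrices by averaging the non-no-edge probability over
ordered block pairs.

## Signaling pathways

Residues in spatial contact are joined by edges weighted
`w = −log(max(c, ε))`, where c is the coupling — |GNM cross-correlation|
or the learned edge probability — clipped to [0, 1−1e−9] and floored at
ε = 1e−4. The monotone log map turns path weight minimization into
coupling-product maximization while keeping all weights positive. One
minimum-weight path per (source, sink) pair is computed with Dijkstra
distance maps from both endpoints; ties on weight are broken by fewer
hops, then by the lexicographically smallest node sequence, making results
order-independent. Default sources are consensus residues 11 and 117 (the
substrate-recognition positions) and default sinks the I-Loop
(consensus 98–112). Residue occurrence frequency across the path set ranks
mediating residues; the "top pathway" maximizes mean member frequency
(ties: smaller weight, then lexicographic).

## Binding energetics

Per-residue MM-GBSA decompositions are consumed as five-column tables
(E_VDW, E_ELE, E_GB, E_GBSUR, E_TOT in kJ/mol, "value ± sd" cells,
Unicode minus accepted); the energy computation itself is upstream and out
of scope. E_TOT is recomputed as the component sum rounded to 2 decimals.
Key residues are those with E_TOT strictly below −1.00 kJ/mol, sorted most
favorable first. In the packaged reference table the recomputed sums match
the printed totals to ±0.03 kJ/mol for 16 of 17 rows; one LAOBP row
deviates by 0.05 (the printed components and total are mutually
inconsistent beyond rounding), which the tests report rather than mask.

## Synthetic data

The generator produces every input the pipeline needs:

- **Two-domain structures.** Each lobe is a self-avoiding chain of beads at
  3.8 Å spacing laid on a jittered spherical spiral (winding gap ~4.4 Å),
  sized so ~110 residues make a lobe of ~12 Å radius. The lobes face each
  other across a 6 Å surface gap — so the binding-cleft interface is
  spring-connected, as in a real protein; without that contact the
  anisotropic network has floppy zero-energy mechanisms — and are joined by
  a folded zig-zag linker (collinear linkers likewise create spurious zero
  modes). The hinge angle (lobe-centroid angle at the linker midpoint;
  default open 150°, closed 110°) is set exactly by rigid rotation of one
  lobe about the hinge, which preserves lobe-internal geometry to machine
  precision.
- **ENM-sampled trajectories.** Frames are the mean structure plus
  Gaussian mode amplitudes with variance `amplitude/λ_k` over the softest
  internal ANM modes (default 30), optionally AR(1)-correlated in time
  (coefficient 0.9) so finite-difference velocities carry signal. This
  reproduces the network's equilibrium fluctuation statistics but has no
  inertial dynamics, no anharmonicity and no solvent friction — passing
  tests show the analysis chain recovers what the network model puts in,
  not that real MD would behave identically.
- **Spring benchmarks.** Erdős–Rényi connectivity over ≤20 particles,
  velocity-Verlet integration (energy drift <1% over default runs),
  optional observation noise, exact adjacency returned for scoring.
- **Energy tables.** Component draws adjusted so exactly `n_key` rows fall
  below −1.00 kJ/mol with a ≥0.18 kJ/mol margin, so rounding can never
  flip the filter.

All generators are pure functions of (spec, seed).

## Problem sizes

Test and acceptance runs use deliberately desk-scale sizes: 86-residue
hinge pairs for elastic-network properties (230 residues for the pipeline
default), 3000–5000-frame trajectories for sampling-statistics checks, and
three 5-particle spring systems × three rollouts × 4000 steps for edge
recovery. These sizes were chosen so the full suite completes on a single
CPU while every statistical assertion retains a comfortable margin.

## Known limitations

- The reference six-structure analyses (sequence identities, GNM profile
  correlations across the real open/closed triads) require the RCSB
  entries 1GGG/1WDN, 2M8C/1HPB, 2LAO/1LST; the loader takes a local
  directory or downloads them when a network is present.
- The NRI implementation is a deliberately small variant: single
  message-passing round, MLP encoder/decoder, no attention, no GPU.
- Pathway edge weighting (−log coupling restricted to contacts) is one
  defensible operationalization; current-flow and betweenness variants are
  out of scope.
- The MM-GBSA energies themselves, explicit-solvent MD and all-atom normal
  modes are out of scope throughout.
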