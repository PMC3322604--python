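# Methods

## The model and its assumptions

`ncsx` treats a partial protein model as a set of chain fragments —
maximal runs of residues with consecutive author numbering and bonded
Cα–Cα geometry (≤ 4.5 Å, covering cis and trans peptides with margin; a
numbering gap or a longer jump starts a new fragment). All analysis is
Cα-based; further atoms ride along rigidly. The central assumption is the
usual one for NCS: copies of the molecule in the asymmetric unit share a
fold, so fragments from different copies superpose well over genuine
common stretches, and the rotations of those superpositions concentrate
around the true operators while chance matches scatter. Crystallographic
symmetry is not expanded — the method operates on the asymmetric-unit
model in one Cartesian frame — and electron density is never consulted.

## Detection

Every fixed-length window (stride 1) of every eligible fragment is
superposed onto every window of every other fragment. Superposition uses
the quaternion eigenvalue (Kearsley) formulation: the optimal proper
rotation is the eigenvector of a 4×4 matrix for its smallest eigenvalue.
It cannot return a reflection, and the minimum r.m.s.d. is evaluated from
the residuals directly, which is better conditioned than the eigenvalue
when the optimum is near zero. A batched variant computes the whole
window-pair r.m.s.d. grid at once for pre-screening; full transforms are
derived only for accepted pairs.

Matches are kept when their r.m.s.d. falls below 0.4 Å (resolution better
than 2.8 Å) or 0.5 Å (otherwise); the boundary is resolved to the looser
value at exactly 2.8 Å. Each unordered window pair yields two directed
matches carrying mutually inverse operators, so an N-fold assembly
produces clusters in inverse pairs (a 180° operator is its own inverse
and forms a single cluster).

Rotation clustering is greedy leader clustering on matches sorted by
ascending r.m.s.d. (most reliable first): a match joins the first cluster
whose founding rotation is within 5° — angles measured as
θ = 2 arccos |q₁·q₂|, which absorbs the q ≡ −q ambiguity — else it founds
a new cluster. The stored representative is the medoid (member minimising
its maximal angle to all members). Greedy assignment depends on order in
principle; for well-separated NCS rotations (tested: intra-cluster < 2°,
inter-cluster > 10°) the partition is shuffle-invariant. Near-identity
clusters (rotation < 5°) are retained but flagged as translational, since
common structural motifs also produce them.

Fragments shorter than 5 residues are carried but excluded from matching
— short fragments contribute noise to the operator census, not signal.
The default stretch length is the floor of the current average fragment
length (minimum 5), the adaptive choice appropriate inside a model-
building loop where small windows on noisy fragments breed false
operators. An optional filter removes short matches whose two stretches
are both entirely α-helical under a pure Cα fingerprint (d(i,i+3) ∈
[4.5, 5.6] Å and d(i,i+4) ∈ [5.7, 6.7] Å for all applicable i): helices
match each other regardless of NCS, and within one ideal helix even
register-shifted windows superpose, so helix-only evidence is weak.

## Extension and tail transfer

An accepted match grows symmetrically, alternating one residue per side
per step and skipping exhausted sides; after each step the r.m.s.d. is
recomputed over the full overlap of length L_ext and must stay within
0.2·L_ext Å, else that side closes. A match violating the threshold at
its initial length is dropped. The literal 0.2·L_ext rule is permissive —
4 Å at L_ext = 20 — so growth can run a few residues past a genuine
divergence point; a configurable absolute cap (`extension_rmsd_cap`,
default none) is provided for stricter use. Windows lying inside an
already-grown overlap at the same register are not re-grown (growth is
monotone, they reach the same maximum); they are counted as contributing
matches, which is what the N_matches weight term measures.

The tail-transfer transform is re-derived from the full extended overlap,
not the initial window — better conditioned, and the mapping happens only
after extension completes. Tails are transferred only for ends where one
fragment continues past the overlap and the other stops; when both
continue, the copies genuinely diverge there and a transferred tail would
collide with the target's own residues. All atoms of a tail residue are
transformed (side-chain atoms are needed for side-chain restraints), but
only Cα geometry is ever scored. Proposed atoms closer than 0.7 Å
(strict) to any existing atom — including previously accepted
higher-ranked candidates — are deleted; a residue losing its Cα is
dropped whole. Near-coincident candidates (Cα centroids within 1.0 Å),
which arise for NCS orders > 2 when the same span is reachable from
several copies, are reduced to the highest-weight one.

## Weighting

    W = C · (S_cluster + S_NCS) · N_matches / max(r.m.s.d._ext, 0.01 Å)

S_cluster scores the candidate's rotation cluster against the mean
cluster size (0 below the mean, 1 at/above, 2 at/above twice, 3 at/above
three times; equality resolves upward — the verbal rule leaves equality
unassigned, and resolving upward keeps "equal to the mean" from scoring
like "smaller"). S_NCS scores the cluster against the expected extent of
one NCS-related part: 3 at/above the full expected size, 2 at/above half,
1 at/above a quarter, else 0. The expected size comes from the stated
assembly composition when available (total residues / NCS order), else
from the built residue count divided by a census of the detected
non-identity rotation-angle groups plus one. The 0.01 Å denominator floor
keeps exact (noise-free) overlaps from producing infinite weights. C
(default 1) rescales all weights equally and never affects ranking. The
additive combination of the two S terms is one plausible reading of the
published description of the ingredients; it reproduces every stated
property (range ≈ 0–100 on realistic inputs, monotonicity in each term,
zero when cluster support is absent) and is isolated in a single function
should a different combination be preferred. Weights are an ordinal
ranking device, not calibrated probabilities. By default only the top
three candidates are merged back; the exclusion-test harness instead
merges every non-clashing candidate, since it measures maximal retrieval
rather than safe feedback into chain tracing.

## Restraints

Extended overlaps strictly longer than 15 residues between fragments
docked into the sequence become restraint groups: main-chain atoms
restrained at class `medium`, side-chain atoms at `loose`, numeric sigmas
left to the refinement program. The keyword writer is table-driven (one
`ncsr span …` line per group, sorted, bit-stable) with a JSON sidecar;
the spelling is pinned by a golden-file test and trivially retargetable
to another dialect. Restraints are regenerated per invocation, not
accumulated.

## Synthetic data

The generator builds an N-subunit assembly from one subunit trace:
`mixed_coil` (default), a self-avoiding Cα walk with 3.8 Å steps, pseudo
bond angles in [85°, 145°] and a 3.6 Å exclusion radius; or
`helix_bundle`, three ideal antiparallel helices (2.3 Å radius, 1.5 Å
rise, 100°/residue) joined by short turns. The default is the coil: an
ideal helix is degenerate for Cα matching (register-shifted windows
superpose at ~0 r.m.s.d.), which is precisely the pathology the
helix-only filter addresses, and the idealised retrieval benchmark should
not depend on it. Each residue carries its Cα plus a dummy Cβ placed
1.53 Å along the local bisector. Proper cyclic assemblies put copy k at
k·360/N° about a common axis, with the ring radius grown until adjacent
copies are > 4.5 Å apart everywhere; improper assemblies apply a random
rotation (30–150°) and a separating translation. Defaults — 5 subunits of
69 residues — mirror the pentameric test structure used to validate the
original procedure (345 residues total).

`noise_sigma` is the r.m.s. radial displacement per atom (isotropic
Gaussian, per-component σ/√3). Under this convention two noisy copies
differ by ≈ σ√2 r.m.s.d., which is the quantity the match threshold sees:
σ = 0.3 Å gives copy-to-copy stretch r.m.s.d. ≈ 0.42 Å, inside the 0.5 Å
acceptance band, matching the intended regime where detection still works
at realistic coordinate error. (Under a per-component reading the same σ
would push copies past the threshold entirely.)

What the generator does not emulate: phase-dependent coordinate error
(noise here is i.i.d. isotropic, real building errors are correlated
along the chain), tracing mistakes such as shortcuts and spurious loops,
genuine conformational differences between copies, sequence-docking
errors, and density support. Passing the idealised retrieval tests
therefore demonstrates the correctness of the operator algebra, the
bookkeeping and the thresholds — not performance on real maps, where
accuracy is bounded by the true inter-copy differences.

## The exclusion test

Blocks of 15–30 residues are deleted round-robin across subunits at
uniformly random positions until the requested fraction (±2%, whole
blocks; the final block is trimmed when the target requires it) is
removed. Up to 35% excluded, placement is rejection-resampled so that no
subunit-local span is deleted from every copy at once — retrieval then
remains information-theoretically possible — while above 35% no such
protection applies and completeness may drop, reproducing the regime
where the method recovers most but not all of the structure. Deleting so
much that a subunit vanishes raises an error.

Retrieval runs the full pipeline with a fixed 10-residue stretch, merges
every accepted candidate (restricted to positions that exist in the
reference numbering), re-segments — fragments flanking a filled gap fuse
— and repeats until a cycle adds nothing (at most 8 cycles). The fixed
stretch is deliberate: the adaptive average-length default can exceed the
longest span two fragments still share after block deletion, leaving true
relations undetectable, whereas 10-residue coil windows below 0.4 Å are
essentially never spurious. Completeness is the percentage of excluded
residues present in the final model; the r.m.s.d. against the reference
is computed over retrieved Cα under the identity mapping — both models
share one frame, so no re-superposition is allowed (it would hide
operator error).

## Numerical choices and degenerate inputs

- Quaternions are canonicalised to non-negative scalar part; cluster
  bookkeeping is thereby deterministic.
- Superposition requires ≥ 3 points and rejects collinear or coincident
  sets (second singular value < 1e-8) rather than returning an arbitrary
  rotation.
- All tie-breaks are explicit: match ordering by (r.m.s.d., fragment ids,
  offsets); candidate ranking by (weight desc, L_ext desc, target
  fragment, side); restraint groups sorted by chain/residue ranges.
  Identical inputs and seeds give byte-identical outputs.
- Exact-NCS inputs give r.m.s.d. 0 everywhere; the weight denominator
  floor (0.01 Å) and the strict clash inequality keep that case finite
  and stable.

## Problem sizes

The shipped validation uses the 5 × 69-residue pentamer (the composition
of the original test structure), exclusion levels of 5–50%, 100 random
point sets for the superposition oracle, and 20 seeds for the noisy
weight-accuracy study; the full suite and the acceptance script each run
in about a minute on one CPU.

## Known limitations

- The weight formula's algebraic combination of S terms is a
  reconstruction from its described ingredients (see above); absolute
  weight values should not be compared across implementations, only the
  ranking.
- The literal 0.2·L_ext extension tolerance loosens linearly with length;
  at long overlaps it accepts real divergence (mitigated by the optional
  cap and by the weight denominator).
- Greedy leader clustering can split a true operator's matches into two
  adjacent clusters when rotational spread approaches the 5° tolerance;
  this costs weight resolution, not correctness.
- Sequence docking is taken as given (a per-fragment flag); no docking is
  performed.
- Only altloc 'A' is read; alternate conformations are not modelled.
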