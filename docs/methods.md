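# Methods

This note documents the models, numerical choices and limitations behind
trisym.  Everything stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## Problem setting

Single-pass receptors of the TNF-receptor family assemble as homotrimers.
No single experiment captures the whole architecture: crystal structures
resolve the extracellular region (with flexible spans missing), NMR
ensembles capture the transmembrane helix bundle, and ligand-bound
geometries are known only for homologous receptors.  trisym provides the
geometric operations needed to combine such fragments into a coherent
trimeric model and to test that model's internal consistency: can the
unresolved juxtamembrane linker physically connect the extracellular and
transmembrane parts, and what happens to that connection when the
extracellular region adopts the splayed, ligand-bound arrangement?

## Residue numbering

Three schemes coexist: *file* (author numbering of a deposited entry),
*precursor* (full translated sequence) and *mature* (signal peptide
removed; 16 residues for CD95, the package default).  Conversions run
through `NumberingMap` (`mature = precursor − signal_peptide_length`, valid
only past the signal peptide; `precursor = file + offset`).  Because
literature positions switch schemes freely, every residue reference in
configurations and on the CLI must carry an explicit scheme tag
(`171:precursor`); bare integers are rejected rather than guessed.

Residue identity is keyed on author numbering.  Alternate locations keep
the highest-occupancy atom (ties: first listed).  Residues without a Cα are
dropped with a warning, since no geometric operation here can use them.

## Superposition and core alignment

`kabsch` solves the orthogonal Procrustes problem by SVD with a
determinant guard against reflections; near-collinear inputs trigger a
conditioning warning.  The test suite checks it against an independent
closed-form quaternion (Horn) implementation on 1000 random point sets
(agreement < 1e−6 Å).

`core_align` finds the rigid core shared by two homologous chains:
an initial residue correspondence (global sequence alignment with BLOSUM62
and affine gaps −11/−1, or positional pairing for conformers of one chain)
is refined by alternating superposition with simultaneous removal of all
pairs deviating more than `trim_cutoff` (default 3.5 Å, ≤ 10 iterations).
The per-iteration RMSD is non-increasing by construction and is asserted in
tests.  Homologous receptor ectodomains share fold much more faithfully
than sequence, which is why a rough sequence seed plus structural trimming
suffices.

## Gap completion

For each gap, the template is superposed locally onto the `anchor_k`
(default 4) observed flank residues on each side, and the template residues
between the flank counterparts are copied and renumbered consecutively.
Flank counterparts come from the core alignment; where trimming removed a
flank pair, the structurally nearest template residue (≤ 4 Å after
superposition) is used instead.  A local flank fit, rather than the global
superposition, minimizes junction strain when target and template diverge
away from the gap.  Junction Cα–Cα distances outside the peptide-compatible
window [2.9, 4.7] Å are flagged, not repaired — no loop modeling or energy
minimization is attempted.  Residues outside gaps are bit-identical to the
input; self-template reconstruction recovers deleted coordinates to
< 1e−2 Å.

## Symmetric assembly

A C3 trimer is generated from one protomer by a pose (intrinsic z-y-z Euler
angles about the protomer centroid, then translation to radius ρ along x
and offset ζ along z) plus exact 120° rotations.  Scoring is Cα-only:
contacts are unordered inter-protomer residue pairs within 8 Å, clashes
within 4 Å, total = contacts − 10·clashes (boundaries inclusive).  The
4 Å clash cutoff acts as a Cα hard-sphere diameter: with a smaller cutoff,
interpenetrating poses slip between discrete Cα positions nearly unpunished
and pure burial dominates the ranking, which destroys pose recovery.  The
enumerator counts pairs (0,1) and (0,2) only and rescales by n/2 using the
congruence of chain pairs under cyclic symmetry; tests assert exact
agreement with the direct three-pair count and with an O(n²) brute-force
oracle.

Enumeration is exhaustive over a deterministic grid (defaults 15° angular,
2 Å radial/axial), sorted by score, ties broken by fewer clashes then
lexicographic pose — reproducible bit-for-bit.  This is a transparent
stand-in for shape-complementarity docking: what downstream selection needs
is a ranked set of symmetric candidates, not a particular energy model.

**Pose recovery.**  A featureless cylindrical helix has no recoverable spin
angle, and a loosely packed planted pose is never the optimum of a burial
score.  The recovery fixture therefore uses a *ridged* helix (one knobby
face, like a ridge of large side chains) and plants the bundle at its
*packing pose* — the clash-free, maximally contacting arrangement found by
an independent brute-force search inside the generator.  The enumeration
module must then find that pose from scratch; the acceptance run requires
rank-1 recovery within one grid step on ≥ 95 % of 20 seeded fixtures.

## Ring distances and ensemble statistics

The ring distance of residue *i* in a trimer is the mean of the three
pairwise inter-protomer Cα distances.  Across an ensemble, the SD is taken
over per-conformer ring means with the n−1 denominator; pooling all pairs
of all conformers was rejected because it conflates within-conformer
asymmetry with conformational spread.  Termini are labeled `close` when
their ring is ≤ 30 Å (configurable; the default separates the ~10–21 Å
rings of compact arrangements from the ≥ 39 Å rings of splayed ones, with
the boundary counted as close).

## Linker feasibility and membrane geometry

`n` missing residues between two anchored ones contribute `n + 1` virtual
Cα–Cα bonds; maximal reach uses 3.8 Å per bond (fully extended trans
chain), with a "realistic" 3.0 Å mode offered because fully extended
linkers are rare.  Ring compatibility compares two stacked ring widths
within a tolerance (default 5 Å).  The membrane is two parallel planes
30 Å apart — a hypothesis, not a measurement — and tilt is the angle
between a protomer's dominant principal axis and the membrane normal,
folded into [0°, 90°]; near-isotropic shapes are rejected with a pointer to
the termini-vector fallback.

## Holo placement and hinge search

`place_on_template` superposes one copy of the completed protomer onto each
receptor chain of a ligand-bound homolog trimer via `core_align`; ligand
chains ride along unmodified and per-copy RMSDs are reported.
`hinge_rotate` then rigidly rotates a declared membrane-proximal domain
about an axis through the hinge residue's Cα, scanning 162 icosahedrally
distributed axis directions × 2° angle steps over ±90° and minimizing the
distance from an anchor residue to a target point.  The identity move seeds
the search (achieved ≤ initial always); ties prefer the smaller |angle|.
Domain-internal distances are preserved exactly and junction continuity at
the hinge is reported, not enforced.  The target point is a required input:
which transmembrane anchor a given receptor's hinge should reach is a
modeling decision, not a package default.

## Synthetic fixtures and the pipeline's default conditions

Generators are pure functions of parameters and seed: ideal and ridged
helices, C3 bundles with recorded poses, noisy ensembles (15 conformers by
default, matching typical NMR depositions) whose per-atom Gaussian σ ramps
from a rigid core to floppy termini, gapped target/template pairs sharing
one synthetic fold (random coil, or a straight superhelical rod emulating a
stacked-domain ectodomain), and two-domain chains with a recorded hinge
move whose axis is drawn from the icosahedral set so that the exact inverse
lies in the search space.

The default pipeline run emulates the full study: a 60-residue rod with
residues 28–39 deleted and a homolog template; a TM-like bundle (24
residues, ring radius 6 Å, thin 1 Å helices so that ring values are sharp)
with a 15-conformer ensemble; a Holo template built by splaying the same
fold (35° tilt at 16 Å radius).  Before docking, the protomer is rotated so
its principal axis lies along z (the membrane frame a receptor protomer
actually occupies), and the tilt angle β is scanned over 0–180° so both
vertical orientations appear among candidates.  The bridge stage then
*selects* among the ranked candidates the model whose membrane-proximal
ring best matches the TM ring — the geometric selection rule that singles
out the membrane-compatible arrangement.  Under these defaults the Apo
verdict is "compatible and bridgeable" and the Holo verdict is "splayed and
unbridgeable", robustly across seeds.

What the fixtures do **not** emulate: side-chain packing, disulfide
topology of cysteine-rich domains, sequence-dependent loop geometry,
anisotropic NMR uncertainty, and real docking energetics.  Passing fixture
tests therefore demonstrates the correctness of the geometry, search and
bookkeeping — not that the contact score would select the biologically
correct trimer for a real receptor; on real data that selection is
corroborated by the ring-compatibility and interface evidence, as in the
pipeline's selection rule.

## Determinism and problem sizes

There is no unseeded randomness anywhere: fixture generators take explicit
seeds, searches are exhaustive over fixed grids, and ties break
deterministically, so `run_pipeline` reproduces its JSON summary
byte-for-byte.  Default problem sizes (60-residue protomers, 24-residue
bundles, 15–50-conformer ensembles, ~1300-pose dock grids, 20 recovery
fixtures) were chosen so the whole suite and the acceptance script each
complete in seconds on one CPU while keeping every statistical check
well-resolved.

## Known limitations

* Cα-only throughout; grafted side chains are copied but labeled
  low-confidence and never used geometrically.
* The contact score is not an energy; ranked candidates require downstream
  geometric selection.
* General Cn symmetry is parameterized but only n = 3 is exercised.
* No molecular dynamics, normal-mode analysis, or flexible refinement —
  the hinge search is a rigid, single-domain motion.
* Reproduction of published ring statistics and core alignments needs the
  deposited entries locally (`data/accessions/`); the package never
  downloads them unless explicitly asked (`--fetch`).
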