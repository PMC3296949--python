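# Methods

## Model

`spinlabel` models the MTSSL (R1) side chain as a rigid-geometry kinematic
chain: fixed bond lengths and angles, five free torsions χ1–χ5
(χ1 = N–CA–CB–SG, χ2 = CA–CB–SG–SD, χ3 = CB–SG–SD–CE, χ4 = SG–SD–CE–C3,
χ5 = SD–CE–C3–C4, with C3 the ring-attachment carbon). The
tetramethyl-pyrroline-N-oxyl ring is one rigid unit — no out-of-plane ring
flexibility. The spin center used for all distances is the nitroxide
nitrogen N1; the O1 oxygen is carried along for visualization.

The conformer search is rejection sampling: each trial draws the five χ
values independently and uniformly on [0°, 360°) and keeps the conformer iff

1. no two label atoms more than 3 bonds apart come closer than the internal
   clash cutoff (default 2.0 Å), and
2. at most `allowed_clashes` protein atoms lie strictly closer than the vdW
   cutoff to any label side-chain atom.

No rotamer library, no energy function, no temperature model. This is a
deliberate stance, not a simplification to be fixed later: protein
environments are observed to stabilize χ combinations that are unfavorable
for the free label, so pruning by clash geometry alone keeps every
physically realizable conformer on the table. The cost is that every
accepted conformer weighs equally in the predicted distribution even if
some are thermodynamically rare.

### Template geometry

The label template is generated at import time from ideal internal
coordinates (standard bond lengths and angles, natural-extension-reference-
frame construction), not copied from any crystal structure, so the geometry
is reproducible and dependency-free. The five-membered ring closes to
1.494 Å on its C2–C3 bond (target 1.50 Å); all bond lengths lie in the
chemically plausible 1.2–2.1 Å band enforced by the test suite. The ideal
Cβ construction uses the L-amino-acid branch of the tetrahedral geometry
(improper N–C–CA–CB ≈ +123°), validated against an rdkit-embedded
L-cysteine during development. Attachment superposes the template's
N/CA/CB anchors onto the residue's by least squares (Kabsch); glycine gets
an ideal Cβ constructed from its backbone.

Alternative labels can be defined via the text serialization in
`template_to_text`/`template_from_text` (atom table, bond list, torsion
quadruples, role assignments).

## Parameters

| parameter | default | range | meaning |
|---|---|---|---|
| thoroughness | normal | quick/normal/thorough/painstaking | 10/90/300/1500 trials per search |
| vdw_cutoff | 3.4 Å | 2.6–3.4 | contact distance below which a label/protein pair is a clash; 3.4 ≈ C–C packing distance, 2.6 ≈ heavy-atom H-bond length |
| allowed_clashes | 0 | 0–5 | sub-cutoff contacts a conformer may keep; >0 tolerates conformational uncertainty at the site (flexible surface residues, NMR models) |
| internal_clash_cutoff | 2.0 Å | >0 | self-overlap threshold for label atoms >3 bonds apart; 2.0 forbids genuine overlap while allowing tight 1–4-like proximity in gauche states |
| shell_radius | 4.5 Å | > vdw_cutoff | outer edge of the snuggly-fit contact shell |
| flag_fraction | 0.75 | (0,1] | fraction of the maximum contact count needed for the snuggly flag |
| seed | 0 | — | one seeded generator per search; every trial consumes exactly 5 draws |

The cutoff is uniform over element pairs; per-element vdW radii differ by
~0.3 Å but that is far below the method's intrinsic prediction error.
Values outside the supported ranges require an explicit `force` flag and
are answered with a logged caution, never silently.

### Boundary conventions

One convention pair, tested explicitly: spatial-index radius queries are
closed balls (d ≤ r); clash tests are strict (d < cutoff is a clash, d =
cutoff is not). An environment atom at exactly the vdW cutoff therefore
counts as a snuggly-fit contact, and the contact shell is inclusive on both
edges. Histogram bins are half-open [lo, hi), a value on an edge goes to
the upper bin, and the modal distance is the center of the most populated
bin with ties broken toward the shorter distance. Each environment atom
counts at most once per conformer however many label atoms it approaches.

### Determinism and monotonicity

A search with a given seed reproduces bit-identical ensembles, and because
each trial consumes exactly five RNG draws regardless of acceptance, the
trial sequence is identical across parameter changes. That makes two
subset relations exact (and testable) rather than statistical: tightening
the cutoff from 2.6 to 3.4 Å can only remove accepted trials, and raising
`allowed_clashes` can only add them.

## Structure handling

PDB parsing is delegated to gemmi; coordinate fields are pre-validated so a
malformed number is reported with its line number. Alternate locations
resolve to the highest-occupancy copy (ties prefer altloc A); the first
MODEL of multi-model entries is used unless another is requested.
Clash/contact environments contain all heavy atoms except the labeled
residue itself; hydrogens are always excluded (the cutoff semantics are
heavy-atom distances), waters and hetero records (ligands, ions) are
excluded by default and opt-in. Radius queries run on a uniform hash grid
whose results are verified against brute force in the tests.

Ensembles are written as multi-MODEL PDB files (residue name R1A) with one
header REMARK per model recording the snuggly flag, and can be re-read into
ensembles (χ re-measured from coordinates; search parameters are not
recoverable from the file).

## Synthetic structures and what they do not show

The fixtures module generates the study conditions: an extended Gly-Ala-Gly
tripeptide (exposed site), a cone-shaped cavity with parametric aperture, a
1.5 Å-spaced atom wall and closed cage (impervious at every legal cutoff),
and an exactly symmetric dimer. Barrier pseudo-atoms are carbon records so
the uniform-cutoff semantics apply unchanged.

Two fixture-design notes. A mathematical cone with walls running through
the apex is uninhabitable at any aperture once the cutoff is applied to the
tether atoms, so the cone wall is offset radially by a clearance (default
6 Å) and the aperture alone controls occlusion. And because the cavity is
rotationally symmetric about the CA–CB axis — which is χ1's own rotation
axis — aperture cannot constrain χ1; the confinement observable is the
angular spread of spin-center directions about the cone axis (mean polar
angle ~15° at 40° aperture vs ~29° at 160° in the shipped configuration).

On the exposed tripeptide at default parameters the acceptance fraction is
about 0.22 (10-seed pilot range 0.14–0.29): roughly 35% of uniform
five-torsion space self-clashes and another ~40% folds back over the
peptide's own backbone within the 3.4 Å cutoff. Real surface sites on
folded proteins sit in the same regime or below.

These fixtures exercise the geometry and bookkeeping of the method, not its
biology: pseudo-atom walls have no element diversity, no side-chain
flexibility at the interface, and no solvent. Passing tests on them shows
the sampling, clash logic, scoring and transfer arithmetic are correct;
agreement with experimental PELDOR distributions must come from the
benchmark on real structures (`spinlabel benchmark`, user-fetched PDB
files), which compares ensemble-mean predictions and the Cβ–Cβ + 6.5 Å
baseline against 52 published distances.

## Design choices on open ground

* "within a 4.5 Å sphere around the label conformation" is implemented as
  the union of per-atom spheres (min distance over label side-chain atoms),
  not a sphere around the label centroid — a centroid sphere of that radius
  would not reach the protein surface at all.
* Clash-tested atoms are the label's side chain only; the backbone anchor
  atoms coincide with the labeled residue and are exempt. Residues adjacent
  in sequence get no special treatment.
* Multiple sub-cutoff environment atoms near one label atom count as
  multiple clashes (distinct environment atoms), not one.
* Accepted conformers are not deduplicated or clustered; reported counts
  are raw.
* A search that finds nothing reports an advisory (raise cutoff /
  allowed clashes / thoroughness) but never auto-relaxes parameters.
* Copy-and-move anchors on the single source/target residue's N, CA, C, O,
  CB frame; `revalidate` re-runs the clash test at the target and defaults
  to off, matching the transfer-without-resampling semantics. Both
  behaviors are available because pseudo-symmetric assemblies genuinely
  need the check.
* The ⟨Δr⟩ benchmark residual is defined as prediction − experiment.

## Problem sizes

The test suite and acceptance script run painstaking-depth searches (1500
trials) on fixtures of 100–600 atoms; a full search takes well under a
second there, and the whole suite a few seconds. On real structures the
cost is dominated by environment size; the spatial grid keeps per-trial
clash tests local, and a painstaking search on a ~25 kDa protein runs in
seconds.

## Known limitations

* Uniform sampling with equal weights can only bound, not predict,
  populations when the label is genuinely immobilized; the snuggly-fit flag
  is a pointer for inspection, not a score, and is expected to be more
  reliable for hydrophobic pockets than for polar crevices (contact counts
  add up regardless of whether the underlying interaction is attractive).
* The uniform cutoff ignores element-specific vdW radii and all
  electrostatics.
* No symmetry expansion from crystallographic records: copy-and-move needs
  the target chain present in the coordinate file.
* The label's own hydrogens are implicit; all distances are heavy-atom.
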