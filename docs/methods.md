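# Methods

## Reference numbering

All anchors are expressed in the residue numbering of the PKACα catalytic
subunit (PDB entry 1ATP), the field's de-facto common frame for kinase
catalytic domains. The packaged reference asset
(`data/pkaca_1atp_catalytic.fasta`, IDs 40–300) was reconstructed from the
canonical PKACα numbering landmarks — the glycine-rich loop
G50-T-G52-S-F54-G55, the β3 lysine K72, the αC glutamate E91, the
catalytic-loop Y164-R165-D166 (PKACα carries Tyr where most kinases carry
His, so the motif pattern is [HY]-R-D), D166-L-K-P-E170-N, the
D184-F185-G186 DFG motif and the A206-P207-E208 APE motif — and every
anchor ID is re-verified against the asset at load time.

A target chain is numbered by global pairwise alignment of its extracted
sequence against this reference (biopython `PairwiseAligner`, BLOSUM62,
gap open 10 / extend 0.5, free end gaps). The alignment score floor
(default 120) separates genuine kinase domains from noise: shuffled 120-mer
decoys score ≤ ~55 against the reference while true kinase domains score in
the hundreds; the floor is re-derived empirically in the test suite.
Residues the alignment leaves unmatched (insertions) carry no reference ID
and are invisible to the classifiers but retained in structures and
alignments. Noncanonical anchor residues (e.g. a DFG→NFG mutant) produce
warnings and a `noncanonical` flag, never an error; a chain missing an
anchor entirely (e.g. an unresolved activation loop covering 184–186)
cannot be numbered and is rejected with the list of unresolved anchors.

## Classifiers

Four elements are classified independently; feature unavailability
(missing atoms) makes the affected element `unassigned` with a
machine-readable reason, never an exception.

* **αC-helix** — minimal Lys72(NZ)–Glu91(OE1/OE2) distance *d*:
  *d* ≤ 4.0 Å → in; *d* ≥ 8.5 Å → out; otherwise the Glu side-chain
  dihedral χ decides (|χ| ≤ 100° → inter, else in). The three thresholds
  are the published salt-bridge criteria; both distance thresholds are
  inclusive. The χ rule compares the dihedral's magnitude — a signed
  reading would call χ = −120° "inter", which contradicts the rule's
  intent of detecting a rotated-but-unbroken glutamate. Which χ index is
  used (default χ1) is configuration.
* **P-loop** — four features (ψ at IDs 49 and 56, ξ over Cα 55–58, Cα
  distance 54↔170) checked against per-class intervals; a class is
  assigned iff at least `min_conditions` (default 3) of its four conditions
  hold *and* it strictly beats the other class's count; equal qualifying
  counts are ambiguous → unassigned. More than one unavailable feature →
  unassigned.
* **A-loop** — each class is a conjunction of two angular intervals
  (ξ_DFG{−1,D}, ξ_DFG{F,G}) and one distance interval (Cα 160↔189).
  Config validation rejects class boxes that overlap, which guarantees at
  most one class can match.
* **DFG** — a pseudodihedral over a configurable atom quadruple around the
  DFG aspartate; the default is Cα(183), Cα(184), Cγ(184) and the centroid
  of the carboxylate oxygens OD1/OD2. This quadruple is an interpretation
  (the underlying cross-product construction is not uniquely determined by
  its verbal description) and is therefore fully configurable, including
  the in/out angular intervals. When the carboxylate oxygens are absent
  the feature is unavailable rather than silently degenerate.

### Threshold provenance

The αC thresholds (4.0 Å / 8.5 Å / 100°), the 3-of-4 P-loop rule, and the
identity of every feature are published criteria. The *numeric intervals*
for the A-loop and P-loop classes are not publicly printed; they ship as a
versioned YAML config (`data/default_classifier.yaml`), with defaults
chosen from kinase-domain structural conventions: angular class boxes of
±[30°, 150°], collapsed/closed distance intervals of [6, 16] / [5, 17] Å
and stretched/open intervals of [18, 30] / [19, 30] Å, separated by
explicit unassigned gaps. Users with access to curated labelled structures
can refit them with `scripts/calibrate_classifier.py` (network required);
the classifier *structure* — which features, which rule — is fixed, only
the interval values are configuration. Consequently, classifications of
real PDB structures with the shipped defaults should be treated as
uncalibrated for A-loop/P-loop until refitting; the αC and DFG elements do
not share this caveat to the same degree.

## Chimeric template construction

The acceptor's C-lobe core (reference IDs 121–182 and 209–300 under the
default boundaries) is treated as the rigid, conformation-invariant frame.
Each donor is superposed onto the acceptor by a least-squares Kabsch fit
(proper rotation enforced via the SVD determinant correction) over the
common C-lobe-core backbone atoms (N, CA, C, O; ≥ 20 common residues
required). The template takes residues ≤ 120 from the N-lobe donor,
183–208 from the A-loop donor and the rest from the acceptor; insertions
follow their preceding numbered residue. Splice-seam C–N distances are
checked against a 2.5 Å covalent-plausibility bound and flagged, never
enforced — downstream modelling engines rebuild seams anyway.

Steric clashes across graft segments (heavy-atom pairs < 2.5 Å, excluding
residues within two sequence positions of each other, whose 1-2/1-3
contacts are covalent) are detected deterministically. The
`truncate_sidechain` relief policy prunes the clashing donor-side residue's
side chain beyond Cβ and re-checks; backbone–backbone clashes cannot be
relieved and mark the template `fatal` (it is still emitted, with the
warning recorded). No energy minimisation is performed anywhere: clash
handling deliberately preserves backbone geometry, which is what both the
classifiers and modelling engines consume.

Segment boundaries (N-lobe ≤ 120, A-loop 183–208) follow conventional
kinase-domain anatomy and live in `SegmentBoundaries`, not in code.

## Ensemble generation

`build_ensemble` validates the donor library (each of the 6 N-lobe and 3
A-loop entries must classify to its library slot — a mislabelled donor is a
load-time error), warns if the acceptor is not DFG-in, superposes each
donor once, and then builds the 18 = 2 × 3 × 3 combinations in the
conventional HM order (P-loop slowest, then αC, then A-loop; HM 12 =
closed A-under-P / stretched / αC-in). Every template failure is recorded
in the JSON manifest and skipped; a single bad combination never aborts a
run. The manifest carries the config hash, tool version and per-template
clash/junction/edit diagnostics, and two runs with identical inputs are
byte-identical modulo the timestamp.

`match_experimental` compares candidate and reference structure sets
all-vs-all by backbone RMSD over their common reference IDs after
superposition; a pair is *similar* iff RMSD < 0.7 Å (the conventional
threshold, configurable) and a *classification match* additionally
requires identical assigned A-loop/P-loop/αC labels.

## Synthetic scaffolds

The fixtures module fabricates kinase-like domains with exactly
controllable classifier observables, so every pipeline stage is testable
without downloads.

**Construction.** A scaffold is a full-backbone chain (N, CA, C, O, CB;
Gly without CB) carrying the packaged reference sequence, built
sequentially in torsion space (NeRF) over ideal bonded geometry. The base
conformation is an α-helical meander with four-residue turns roughly every
20 residues; the turn torsions were fixed once by a randomised search over
turn conformers that maximises the spatial separation between the three
graft segments across all class poses, and are constants of the module.

**Posing.** ψ(49)/ψ(56) are direct torsion assignments. Each Cα
pseudotorsion is driven to its target by a bracketed 1-D root search on
one in-window torsion. The long-range distance 54↔170 is solved on a
hinge torsion inside the N-lobe, which swings the whole C-lobe rigidly;
the 160↔189 distance is solved on short levers at residues 187/188 with a
ψ(182) pre-hinge fallback that rotates the entire loop. When a solver has
several roots it keeps the one with the best self-avoidance score, and
when no single torsion suffices it parks the closest-reaching torsion and
recurses on the rest. The DFG-Asp side chain is posed through χ1 (the
carboxylate-oxygen centroid lies on the Cβ→Cγ cone axis, so the
pseudodihedral is a function of χ1 alone); the Glu side chain is posed
analytically through its χ angles; and the Lys NZ is placed analytically
at exactly the requested minimal distance from the nearer carboxylate
oxygen (axis-aligned displacement, so threshold poses such as 4.0 or
8.5 Å are realised bit-exactly).

**Rigid-core discipline.** The C-lobe-core torsions are identical in every
scaffold — no jitter, no pose dependence — because the core is the common
frame donors are superposed on during grafting. After the A-loop is
reposed, a cyclic-coordinate-descent loop closure over residues 189–208
returns the post-loop anchor (207–208) to the common frame (≤ 1 Å
residual), and the post-loop core is then snapped back exactly; the small
resulting stretch of the 208–209 peptide link stays well inside the 2.5 Å
plausibility bound. Seeded jitter (±2° by default) applies only to N-lobe
and A-loop torsions, making coordinates distinct across seeds while labels
and the core frame are preserved. Construction retries with escalating
jitter (up to ±10°) until donor/acceptor scaffolds reach ≥ 2.7 Å
cross-segment clearance, so spliced synthetic templates are clash-free.

**Fidelity contract.** Measured features equal posed values to well within
10⁻⁶ (degrees/Å); the labelled grid covers all 18 class combinations plus
threshold-boundary and unassigned-band cases, and its generating labels are
recovered by the classifiers with 100% agreement by construction.

**What the scaffolds are not.** They are geometric stand-ins, not physical
proteins: no side chains beyond what the features need, no rotamer
realism, no packing. Passing tests demonstrate that the classifiers read
the defined observables correctly, that grafting preserves segment
geometry and provenance, and that the combinatorics and thresholds behave
as specified — they do not demonstrate classification accuracy on real,
noisy crystal structures, which depends on the interval calibration
discussed above.

## Numerical choices

* Angles cross every interface in degrees, range (−180°, 180°]; distances
  in Å; residue numbering 1-based author IDs plus integer reference IDs.
* Dihedral degeneracy (collinear atoms) raises an explicit error at an
  axis-norm tolerance of 1e-10; superposition requires ≥ 3 non-collinear
  atom pairs (rank check at 1e-8).
* Altloc collapse keeps the highest-occupancy conformer; ties break
  alphabetically (blank first) for reproducibility.
* Root searches use brentq at xtol 1e-13 after a 90-point bracket scan;
  angular objectives are bracketed on wrapped differences with a 180° jump
  guard.
* PDB coordinates round-trip at the format's 3-decimal precision; the
  write→read contract is ≤ 1e-3 Å.

## Known limitations

* A-loop/P-loop interval defaults are uncalibrated against experimental
  structures (no redistributable labelled set); see Threshold provenance.
* The DFG pseudodihedral quadruple is an interpretation, exposed as
  configuration.
* Scaffolds prioritise observable control over physical realism; loop
  closure permits a slightly stretched 208–209 link.
* mmCIF is read-only; written structures are single-chain PDB.
* No nucleic acids, no symmetry/assembly handling, no kinome-scale
  sequence database; users supply target sequences and acceptor
  structures.
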