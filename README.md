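# kinoforge

Geometric classification of kinase catalytic-domain conformations and
combinatorial construction of chimeric **DFG-out** template structures for
homology modelling.

## The problem

Protein kinases in the inactive DFG-out state are prime targets for type II
inhibitors, but DFG-out structures are badly under-represented in the PDB:
for most kinases no experimental DFG-out structure exists at all, and the
DFG-out state is itself an ensemble — the activation loop (A-loop), the
glycine-rich P-loop and the αC-helix each adopt several discrete
conformations that reshape the binding site. `kinoforge` addresses this for
structure-based drug-design groups in two steps:

1. **Classify** any kinase catalytic-domain structure by the geometry of its
   binding-site-forming elements, in a common reference numbering (PKACα,
   PDB entry 1ATP):
   - **DFG** {in, out} — a pseudodihedral over four atoms around the DFG
     aspartate;
   - **A-loop** {closed type 2, open DFG-out, closed A-under-P} — the Cα
     pseudotorsions ξ_DFG{−1,D} and ξ_DFG{F,G} plus the Cα distance
     HRD−4 (ID 160) ↔ DFG+3 (ID 189);
   - **P-loop** {collapsed, stretched} — ψ(49), ψ(56), ξ over Cα 55–58 and
     the Cα distance Φ(54) ↔ HRD+4 (170); a class needs ≥ 3 of its 4
     conditions;
   - **αC-helix** {in, inter, out} — the minimal Lys72(NZ)–Glu91(OE1/OE2)
     salt-bridge distance *d*: *d* ≤ 4 Å → in, *d* ≥ 8.5 Å → out, and in
     between the Glu side-chain dihedral decides (≤ 100° → inter).

2. **Build**, per target kinase, an ensemble of **18 chimeric templates**:
   the rigid C-lobe of a DFG-in acceptor structure of that kinase is fused
   with each of six N-lobe donors (2 P-loop × 3 αC classes) and three
   A-loop donors (2 × 3 × 3 = 18), after Kabsch superposition of each donor
   onto the acceptor over the shared C-lobe-core backbone. Each template is
   emitted as a PDB file with per-residue provenance records plus a
   target-to-template alignment in PIR and aligned-FASTA, directly
   consumable by comparative-modelling engines.

A synthetic-fixtures module generates kinase-like scaffolds whose classifier
observables can be posed to exact values, so the full pipeline is testable
without any PDB download.

## Worked example

Build the 18-template ensemble for a synthetic kinase and inspect it:

```bash
kinoforge make-fixtures --seed 4 --out fixtures/
cd fixtures
python -c "from kinoforge.reference_numbering import load_reference_profile as p; \
print('>target'); print(p().sequence)" > target.fasta
kinoforge build-ensemble --target-fasta target.fasta \
    --acceptor acceptor.pdb:A --library library.yaml \
    --out ensemble/ --kinase demo
```

which prints

```
18/18 templates written to ensemble/
```

`ensemble/manifest.json` then holds one record per template in the
conventional HM ordering (HM 1 = closed type 2 / collapsed / αC-in …
HM 18 = closed A-under-P / stretched / αC-out), and classifying a template
returns exactly the donor classes it was spliced from:

```bash
kinoforge classify ensemble/HM12.pdb --fmt json
```

```
label_dfg: "out", label_aloop: "closed_a_under_p",
label_ploop: "stretched", label_alphac: "in"
```

i.e. HM 12 is the closed A-under-P / stretched / αC-in combination, with the
full feature vector (pseudotorsions in degrees, distances in Å) alongside.

Classify experimental structures the same way (`kinoforge classify
structure.pdb --chain A`); acceptor and donor structures for real runs are
supplied by the user — the acceptor should be a high-resolution, complete
DFG-in structure of the target kinase, ideally ATP- or analogue-bound.

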