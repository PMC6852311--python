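"""Assemble chimeric homology-modelling templates.

A template for one DFG-out conformation is spliced from three structures in
a common reference numbering: the rigid C-lobe core of a DFG-in *acceptor*
(the kinase being modelled), the N-lobe of a donor representing one
P-loop × αC-helix combination, and the activation loop of a donor
representing one A-loop class.  Both donors are first superposed onto the
acceptor by a Kabsch fit over the shared C-lobe-core backbone — the C-lobe
(excluding the A-loop) is the conformation-invariant frame — after which
the desired segments are excised and joined.  Steric clashes across the
graft seams are detected deterministically and optionally relieved by
pruning donor side chains; backbone geometry is never altered.

The target-to-template alignment is emitted alongside each template as a
global pairwise alignment of the target sequence against the concatenated
template sequence, serialisable to PIR and aligned-FASTA for comparative-
modelling engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import geometry
from .errors import (AlignmentFloorError, InsufficientOverlapError,
                     KinoforgeError)
from .reference_numbering import (AlignmentMap, NumberedDomain, ScoringParams,
                                  global_alignment)

__all__ = [
    "SegmentBoundaries",
    "SegmentPartition",
    "TemplateSpec",
    "ChimericTemplate",
    "ClashPair",
    "ClashReport",
    "TemplateAlignment",
    "partition_domain",
    "superpose_donor",
    "splice",
    "detect_clashes",
    "relieve_clashes",
    "build_template_alignment",
    "ACCEPTOR_CLOBE",
    "NLOBE_DONOR",
    "ALOOP_DONOR",
]

ACCEPTOR_CLOBE = "acceptor_clobe"
NLOBE_DONOR = "nlobe_donor"
ALOOP_DONOR = "aloop_donor"

_BACKBONE_NAMES = frozenset(("N", "CA", "C", "O"))
_JUNCTION_BOND_MAX = 2.5  # Å, covalent plausibility of a spliced N–C seam


@dataclass(frozen=True)
class SegmentBoundaries:
    """Reference-ID ranges of the three graft segments.

    The N-lobe runs through the hinge end (β-sheet, P-loop, αC-helix); the
    A-loop spans DFG−1 through the APE motif; the C-lobe core is everything
    else.  The defaults follow conventional kinase-domain anatomy and are
    configuration, not anatomy carved in stone.
    """

    nlobe_start: int = 40
    hinge_end: int = 120
    aloop_start: int = 183
    aloop_end: int = 208

    def __post_init__(self) -> None:
        if not self.nlobe_start <= self.hinge_end < self.aloop_start <= self.aloop_end:
            raise KinoforgeError("segment boundaries out of order")
        if not (self.aloop_start <= 184 and self.aloop_end >= 186):
            raise KinoforgeError("A-loop range must contain the DFG motif (184-186)")

    def segment_of(self, ref_id: int) -> str:
        if ref_id <= self.hinge_end:
            return NLOBE_DONOR
        if self.aloop_start <= ref_id <= self.aloop_end:
            return ALOOP_DONOR
        return ACCEPTOR_CLOBE


@dataclass
class SegmentPartition:
    """Disjoint cover of a domain's residues by graft segment (indices into
    the chain's residue list; insertions follow their preceding numbered
    residue)."""

    n_lobe: list
    c_lobe_core: list
    a_loop: list

    def segments(self) -> dict:
        return {NLOBE_DONOR: self.n_lobe, ACCEPTOR_CLOBE: self.c_lobe_core,
                ALOOP_DONOR: self.a_loop}


def partition_domain(domain: NumberedDomain,
                     bounds: SegmentBoundaries | None = None) -> SegmentPartition:
    bounds = bounds or SegmentBoundaries()
    required = (bounds.hinge_end, bounds.aloop_start, bounds.aloop_end)
    missing = [r for r in required if not domain.has_ref(r)]
    if missing:
        raise KinoforgeError(
            f"boundary residues missing from domain: {missing}")
    out = SegmentPartition([], [], [])
    current = NLOBE_DONOR
    for i, ref_id in enumerate(domain.ref_ids):
        if ref_id is not None:
            current = bounds.segment_of(ref_id)
        # insertions (ref_id None) inherit the running segment
        out.segments()[current].append(i)
    return out


def superpose_donor(donor: NumberedDomain, acceptor: NumberedDomain,
                    bounds: SegmentBoundaries | None = None,
                    min_common: int = 20):
    """Rigidly fit a donor onto the acceptor over the common C-lobe-core
    backbone (N, CA, C, O) and return the moved donor plus diagnostics."""
    bounds = bounds or SegmentBoundaries()
    common = []
    for rid in sorted(set(donor.reference_ids()) & set(acceptor.reference_ids())):
        if bounds.segment_of(rid) != ACCEPTOR_CLOBE:
            continue
        rd = donor.residue_by_ref(rid)
        ra = acceptor.residue_by_ref(rid)
        if all(rd.coord(n) is not None for n in _BACKBONE_NAMES) and \
                all(ra.coord(n) is not None for n in _BACKBONE_NAMES):
            common.append(rid)
    if len(common) < min_common:
        raise InsufficientOverlapError(
            f"only {len(common)} common C-lobe-core residues with complete "
            f"backbone (need >= {min_common})")
    mobile = np.array([donor.residue_by_ref(r).coord(n)
                       for r in common for n in ("N", "CA", "C", "O")])
    reference = np.array([acceptor.residue_by_ref(r).coord(n)
                          for r in common for n in ("N", "CA", "C", "O")])
    result = geometry.superpose(mobile, reference,
                                selection=f"c_lobe_core backbone ({len(common)} residues)")
    moved = donor.transformed(result.transform.rotation, result.transform.translation)
    return moved, result


@dataclass
class TemplateSpec:
    """Which donor classes a template represents, plus its HM index (1–18)."""

    ploop_class: str
    alphac_class: str
    aloop_class: str
    nlobe_donor: str = ""
    aloop_donor: str = ""
    acceptor: str = ""
    model_type_index: int = 0

    def tag(self) -> str:
        return f"HM{self.model_type_index:02d}"

    def as_dict(self) -> dict:
        return {"model_type_index": self.model_type_index,
                "ploop_class": self.ploop_class,
                "alphac_class": self.alphac_class,
                "aloop_class": self.aloop_class,
                "nlobe_donor": self.nlobe_donor,
                "aloop_donor": self.aloop_donor,
                "acceptor": self.acceptor}


@dataclass
class ClashPair:
    ref_id_a: int
    atom_a: str
    segment_a: str
    ref_id_b: int
    atom_b: str
    segment_b: str
    distance: float

    @property
    def backbone_backbone(self) -> bool:
        return self.atom_a in _BACKBONE_NAMES and self.atom_b in _BACKBONE_NAMES


@dataclass
class ClashReport:
    cutoff: float
    pairs: list

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ChimericTemplate:
    """Spliced structure with per-residue provenance and diagnostics."""

    residues: list            # Residue objects, ordered by reference id
    ref_ids: list             # parallel reference ids (None for insertions)
    provenance: list          # parallel segment tags
    spec: TemplateSpec
    bounds: SegmentBoundaries
    nlobe_fit: geometry.SuperpositionResult | None = None
    aloop_fit: geometry.SuperpositionResult | None = None
    junction_flags: list = field(default_factory=list)
    clash_report: ClashReport | None = None
    edits: list = field(default_factory=list)      # side-chain prunes
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        present = [r for r in self.ref_ids if r is not None]
        if len(set(present)) != len(present):
            raise KinoforgeError("chimeric template: duplicated reference ids")

    def to_domain(self, anchors=None, name: str = "") -> NumberedDomain:
        from .reference_numbering import AnchorSet
        from .structure_model import ChainStructure
        chain = ChainStructure("A", 0, [r.copy() for r in self.residues],
                               source=(name or self.spec.tag(), "chimera"))
        return NumberedDomain(chain, self.ref_ids, anchors or AnchorSet(),
                              name=name or self.spec.tag())

    def provenance_runs(self) -> list:
        """Contiguous runs of one provenance tag, for REMARK emission."""
        runs = []
        for res, tag in zip(self.residues, self.provenance):
            if runs and runs[-1][0] == tag:
                runs[-1][3] = res.key
            else:
                runs.append([tag, tag, res.key, res.key])
        return [(seg, seg, first, last) for seg, _s, first, last in runs]


def splice(acceptor: NumberedDomain, nlobe_donor_t: NumberedDomain,
           aloop_donor_t: NumberedDomain, bounds: SegmentBoundaries | None = None,
           spec: TemplateSpec | None = None) -> ChimericTemplate:
    """Join the three superposed structures into one chimeric template.

    Residues are drawn by the provenance rule (N-lobe from the N-lobe
    donor, C-lobe core from the acceptor, A-loop from the A-loop donor),
    ordered by reference ID.  Junction seams are checked for covalent
    plausibility (C–N ≤ 2.5 Å) and flagged, never enforced.
    """
    bounds = bounds or SegmentBoundaries()
    spec = spec or TemplateSpec("", "", "")
    sources = {NLOBE_DONOR: nlobe_donor_t, ACCEPTOR_CLOBE: acceptor,
               ALOOP_DONOR: aloop_donor_t}
    residues, ref_ids, provenance = [], [], []
    warnings = []
    for segment, domain in sources.items():
        part = partition_domain(domain, bounds)
        for i in part.segments()[segment]:
            residues.append(domain.chain.residues[i].copy())
            ref_ids.append(domain.ref_ids[i])
            provenance.append(segment)
    order = sorted(range(len(residues)),
                   key=lambda k: (ref_ids[k] if ref_ids[k] is not None
                                  else _preceding_ref(ref_ids, k),
                                  residues[k].key))
    residues = [residues[k] for k in order]
    ref_ids = [ref_ids[k] for k in order]
    provenance = [provenance[k] for k in order]

    # gaps inside segments are tolerated, recorded for the modelling engine
    present = [r for r in ref_ids if r is not None]
    for a, b in zip(present, present[1:]):
        if b > a + 1:
            warnings.append(f"numbering gap {a}..{b}")

    template = ChimericTemplate(residues, ref_ids, provenance, spec, bounds)
    template.warnings = warnings
    # covalent plausibility at provenance seams
    for k in range(len(residues) - 1):
        if provenance[k] == provenance[k + 1]:
            continue
        c = residues[k].coord("C")
        n = residues[k + 1].coord("N")
        if c is None or n is None:
            template.junction_flags.append(
                f"{provenance[k]}|{provenance[k + 1]} at {residues[k].author_id}: "
                "seam atoms missing")
            continue
        d = float(np.linalg.norm(c - n))
        if d > _JUNCTION_BOND_MAX:
            template.junction_flags.append(
                f"{provenance[k]}|{provenance[k + 1]} at {residues[k].author_id}: "
                f"C-N {d:.2f} A")
    return template


def _preceding_ref(ref_ids: list, k: int) -> float:
    for j in range(k - 1, -1, -1):
        if ref_ids[j] is not None:
            return ref_ids[j] + 0.5
    return -1.0


def detect_clashes(template: ChimericTemplate, cutoff: float = 2.5) -> ClashReport:
    """Heavy-atom pairs across different provenance segments closer than the
    cutoff, excluding seam-bonded neighbourhoods (residues within two
    positions of each other, whose 1-2/1-3 contacts are covalent rather
    than steric)."""
    coords, meta = [], []
    for res, rid, seg in zip(template.residues, template.ref_ids,
                             template.provenance):
        for atom in res.atoms.values():
            if atom.element == "H":
                continue
            coords.append(atom.coord)
            meta.append((res, rid, seg, atom.name))
    coords = np.asarray(coords)
    order = {id(res): k for k, res in enumerate(template.residues)}
    pairs = []
    tree = cKDTree(coords)
    for i, j in sorted(tree.query_pairs(cutoff)):
        res_i, rid_i, seg_i, name_i = meta[i]
        res_j, rid_j, seg_j, name_j = meta[j]
        if seg_i == seg_j:
            continue
        if abs(order[id(res_i)] - order[id(res_j)]) <= 2:
            continue  # junction-bonded neighbourhood
        d = float(np.linalg.norm(coords[i] - coords[j]))
        pairs.append(ClashPair(rid_i, name_i, seg_i, rid_j, name_j, seg_j, d))
    pairs.sort(key=lambda p: (p.ref_id_a or -1, p.atom_a, p.ref_id_b or -1, p.atom_b))
    report = ClashReport(cutoff, pairs)
    template.clash_report = report
    return report


def relieve_clashes(template: ChimericTemplate, policy: str = "truncate_sidechain",
                    cutoff: float = 2.5, max_rounds: int = 10) -> ChimericTemplate:
    """Resolve graft-seam clashes without touching backbone geometry.

    ``truncate_sidechain`` prunes the clashing donor-side residue's side
    chain beyond Cβ, re-checks, and records every edit; ``flag_only``
    leaves coordinates untouched.  A backbone–backbone clash cannot be
    relieved and marks the template with a fatal warning (the template is
    still emitted).
    """
    if policy not in ("truncate_sidechain", "flag_only"):
        raise KinoforgeError(f"unknown clash policy {policy!r}")
    report = template.clash_report or detect_clashes(template, cutoff)
    if policy == "flag_only":
        for pair in report.pairs:
            if pair.backbone_backbone:
                _flag_backbone_clash(template, pair)
        return template

    by_ref = {rid: res for res, rid in zip(template.residues, template.ref_ids)
              if rid is not None}
    seg_by_ref = {rid: seg for rid, seg in zip(template.ref_ids, template.provenance)
                  if rid is not None}
    for _round in range(max_rounds):
        report = detect_clashes(template, cutoff)
        actionable = [p for p in report.pairs if not p.backbone_backbone]
        if not actionable:
            break
        pair = actionable[0]
        # prune on the donor side only; prefer the side whose atom is a
        # side-chain atom
        candidates = []
        for rid, name in ((pair.ref_id_a, pair.atom_a), (pair.ref_id_b, pair.atom_b)):
            if rid is None:
                continue
            if seg_by_ref.get(rid) == ACCEPTOR_CLOBE:
                continue
            if name in _BACKBONE_NAMES or name == "CB":
                continue
            candidates.append(rid)
        if not candidates:
            # side-chain atom sits on the acceptor, or only CB involved:
            # treat like an unresolvable contact
            _flag_backbone_clash(template, pair)
            break
        rid = sorted(candidates)[0]
        res = by_ref[rid]
        removed = [key for key in res.atoms
                   if key[0] not in _BACKBONE_NAMES and key[0] != "CB"]
        for key in removed:
            del res.atoms[key]
        template.edits.append(
            f"truncated sidechain of {res.name} {rid} ({seg_by_ref[rid]}) "
            f"beyond CB ({len(removed)} atoms)")
    for pair in detect_clashes(template, cutoff).pairs:
        if pair.backbone_backbone:
            _flag_backbone_clash(template, pair)
    return template


def _flag_backbone_clash(template: ChimericTemplate, pair: ClashPair) -> None:
    msg = (f"fatal-for-template: unresolvable clash "
           f"{pair.segment_a} {pair.ref_id_a}:{pair.atom_a} vs "
           f"{pair.segment_b} {pair.ref_id_b}:{pair.atom_b} at {pair.distance:.2f} A")
    if msg not in template.warnings:
        template.warnings.append(msg)


@dataclass
class TemplateAlignment:
    """Two-row gapped alignment of target vs concatenated template sequence,
    with a per-column segment track for the template row."""

    target_name: str
    template_name: str
    target_row: str
    template_row: str
    segment_track: str        # one char per column: N, C, A, or '-' in gaps
    score: float
    template_first: tuple = (40, "A")   # (author id, chain) of template start
    template_last: tuple = (300, "A")

    def __post_init__(self) -> None:
        if len(self.target_row) != len(self.template_row):
            raise KinoforgeError("alignment rows differ in length")

    def to_pir(self) -> str:
        f_id, f_ch = self.template_first
        l_id, l_ch = self.template_last
        lines = [f">P1;{self.target_name}",
                 f"sequence:{self.target_name}::::::::",
                 _chunk(self.target_row + "*"),
                 f">P1;{self.template_name}",
                 f"structureX:{self.template_name}:{f_id}:{f_ch}:{l_id}:{l_ch}:"
                 "::-1.00:-1.00",
                 _chunk(self.template_row + "*")]
        return "\n".join(lines) + "\n"

    def to_fasta(self) -> str:
        return (f">{self.target_name}\n{_chunk(self.target_row)}\n"
                f">{self.template_name}\n{_chunk(self.template_row)}\n")


def _chunk(text: str, width: int = 60) -> str:
    return "\n".join(text[i:i + width] for i in range(0, len(text), width))


def build_template_alignment(target_seq: str, template: ChimericTemplate,
                             scoring: ScoringParams = ScoringParams(),
                             target_name: str = "target") -> TemplateAlignment:
    """Globally align the target sequence against the template sequence
    (the three segments concatenated in reference order)."""
    if not target_seq:
        raise KinoforgeError("empty target sequence")
    template_seq = "".join(res.one_letter() for res in template.residues)
    aln = global_alignment(target_seq, template_seq, scoring)
    if aln.score < scoring.min_score:
        raise AlignmentFloorError(
            f"target/template too dissimilar: score {aln.score:.1f} "
            f"below floor {scoring.min_score:.1f}")
    target_row, template_row = _gapped_rows(target_seq, template_seq, aln)
    seg_char = {NLOBE_DONOR: "N", ACCEPTOR_CLOBE: "C", ALOOP_DONOR: "A"}
    track = []
    t_pos = 0
    for ch in template_row:
        if ch == "-":
            track.append("-")
        else:
            track.append(seg_char[template.provenance[t_pos]])
            t_pos += 1
    first = template.residues[0]
    last = template.residues[-1]
    return TemplateAlignment(
        target_name=target_name,
        template_name=f"{target_name}_{template.spec.tag()}",
        target_row=target_row,
        template_row=template_row,
        segment_track="".join(track),
        score=float(aln.score),
        template_first=(first.author_id, "A"),
        template_last=(last.author_id, "A"),
    )


def _gapped_rows(seq_a: str, seq_b: str, aln) -> tuple:
    """Reconstruct gapped rows from a biopython alignment's aligned blocks."""
    row_a, row_b = [], []
    pa = pb = 0
    for (a0, a1), (b0, b1) in zip(aln.aligned[0], aln.aligned[1]):
        if a0 > pa:
            row_a.append(seq_a[pa:a0])
            row_b.append("-" * (a0 - pa))
        if b0 > pb:
            row_a.append("-" * (b0 - pb))
            row_b.append(seq_b[pb:b0])
        row_a.append(seq_a[a0:a1])
        row_b.append(seq_b[b0:b1])
        pa, pb = a1, b1
    if pa < len(seq_a):
        row_a.append(seq_a[pa:])
        row_b.append("-" * (len(seq_a) - pa))
    if pb < len(seq_b):
        row_a.append("-" * (len(seq_b) - pb))
        row_b.append(seq_b[pb:])
    return "".join(row_a), "".join(row_b)
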