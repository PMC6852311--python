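"""Chimera assembly: partitioning, donor superposition, splicing,
clash handling and target-to-template alignments."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinoforge.chimera_builder import (ACCEPTOR_CLOBE, ALOOP_DONOR,
                                       NLOBE_DONOR, SegmentBoundaries,
                                       TemplateSpec, build_template_alignment,
                                       detect_clashes, partition_domain,
                                       relieve_clashes, splice,
                                       superpose_donor)
from kinoforge.errors import (AlignmentFloorError, InsufficientOverlapError,
                              KinoforgeError)
from kinoforge.structure_model import Atom


def self_chimera(domain):
    """Chimera from three copies of one structure (identity donors)."""
    spec = TemplateSpec("stretched", "in", "open_dfg_out")
    n_t, _ = superpose_donor(domain, domain)
    a_t, _ = superpose_donor(domain, domain)
    return splice(domain, n_t, a_t, spec=spec)


class TestPartition:
    def test_aloop_contains_dfg(self, default_scaffold):
        part = partition_domain(default_scaffold)
        aloop_ids = {default_scaffold.ref_ids[i] for i in part.a_loop}
        assert {184, 185, 186} <= aloop_ids

    def test_disjoint_cover(self, default_scaffold):
        part = partition_domain(default_scaffold)
        all_indices = sorted(part.n_lobe + part.c_lobe_core + part.a_loop)
        assert all_indices == list(range(len(default_scaffold)))

    def test_missing_hinge_residue_errors(self, default_scaffold):
        from kinoforge.reference_numbering import NumberedDomain
        from kinoforge.structure_model import ChainStructure
        keep = [(r, rid) for r, rid in zip(default_scaffold.chain.residues,
                                           default_scaffold.ref_ids)
                if rid != 120]
        chain = ChainStructure("A", 0, [r.copy() for r, _ in keep])
        domain = NumberedDomain(chain, [rid for _, rid in keep])
        with pytest.raises(KinoforgeError, match="120"):
            partition_domain(domain)

    def test_boundaries_validated(self):
        with pytest.raises(KinoforgeError):
            SegmentBoundaries(aloop_start=190, aloop_end=185)
        with pytest.raises(KinoforgeError, match="DFG"):
            SegmentBoundaries(aloop_start=190, aloop_end=200)


class TestSuperposeDonor:
    def test_identity_donor(self, default_scaffold):
        moved, result = superpose_donor(default_scaffold, default_scaffold)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.n_atoms >= 20 * 4

    def test_known_rigid_motion_inverted(self, default_scaffold):
        rot = Rotation.from_euler("xyz", [15, -30, 45], degrees=True).as_matrix()
        shift = np.array([3.0, -1.0, 2.0])
        displaced = default_scaffold.transformed(rot, shift)
        moved, result = superpose_donor(displaced, default_scaffold)
        assert result.rmsd < 1e-8
        for rid in (130, 200, 250):
            np.testing.assert_allclose(
                moved.residue_by_ref(rid).coord("CA"),
                default_scaffold.residue_by_ref(rid).coord("CA"), atol=1e-8)

    def test_missing_clobe_insufficient_overlap(self, default_scaffold):
        from kinoforge.reference_numbering import NumberedDomain
        from kinoforge.structure_model import ChainStructure
        keep = [(r, rid) for r, rid in zip(default_scaffold.chain.residues,
                                           default_scaffold.ref_ids)
                if rid is not None and rid <= 120]
        chain = ChainStructure("A", 0, [r.copy() for r, _ in keep])
        nlobe_only = NumberedDomain(chain, [rid for _, rid in keep])
        with pytest.raises(InsufficientOverlapError):
            superpose_donor(nlobe_only, default_scaffold)


class TestSplice:
    def test_self_chimera_identity(self, default_scaffold):
        template = self_chimera(default_scaffold)
        assert len(template.residues) == len(default_scaffold)
        for res, rid in zip(template.residues, template.ref_ids):
            orig = default_scaffold.residue_by_ref(rid)
            for key, atom in res.atoms.items():
                np.testing.assert_allclose(atom.coord, orig.atoms[key].coord,
                                           atol=1e-8)
        assert template.junction_flags == []

    def test_provenance_partition(self, default_scaffold):
        template = self_chimera(default_scaffold)
        bounds = SegmentBoundaries()
        for rid, seg in zip(template.ref_ids, template.provenance):
            assert seg == bounds.segment_of(rid)
        runs = template.provenance_runs()
        assert [r[0] for r in runs] == [NLOBE_DONOR, ACCEPTOR_CLOBE,
                                        ALOOP_DONOR, ACCEPTOR_CLOBE]

    def test_aloop_taken_bitwise_from_donor(self, acceptor, donor_library):
        entry = donor_library.aloop["closed_type2"]
        aloop_t, _ = superpose_donor(entry.domain, acceptor)
        nlobe_t, _ = superpose_donor(
            donor_library.nlobe[("stretched", "in")].domain, acceptor)
        template = splice(acceptor, nlobe_t, aloop_t,
                          spec=TemplateSpec("stretched", "in", "closed_type2"))
        for res, rid, seg in zip(template.residues, template.ref_ids,
                                 template.provenance):
            if seg != ALOOP_DONOR:
                continue
            donor_res = aloop_t.residue_by_ref(rid)
            for key, atom in res.atoms.items():
                np.testing.assert_array_equal(atom.coord,
                                              donor_res.atoms[key].coord)

    def test_broken_junction_flagged(self, default_scaffold):
        displaced = default_scaffold.transformed(np.eye(3),
                                                 np.array([80.0, 0.0, 0.0]))
        spec = TemplateSpec("stretched", "in", "open_dfg_out")
        # deliberately skip superposition: the A-loop donor sits 80 Å away
        template = splice(default_scaffold, default_scaffold, displaced,
                          spec=spec)
        assert any("C-N" in flag for flag in template.junction_flags)


class TestClashes:
    def test_self_chimera_clash_free(self, default_scaffold):
        template = self_chimera(default_scaffold)
        assert len(detect_clashes(template)) == 0

    def test_planted_clash_reported_then_relieved(self, default_scaffold):
        template = self_chimera(default_scaffold)
        # plant an N-lobe sidechain atom 1 Å from a C-lobe backbone atom
        target = default_scaffold.residue_by_ref(150).coord("CA")
        offender = next(res for res, seg in zip(template.residues,
                                                template.provenance)
                        if seg == NLOBE_DONOR and res.name != "GLY")
        offender.add_atom(Atom("CG", "C", target + np.array([1.0, 0, 0])))
        report = detect_clashes(template)
        assert len(report) >= 1
        # every reported pair involves the planted atom, and the planted
        # contact itself is among them
        assert all("CG" in (p.atom_a, p.atom_b) for p in report.pairs)
        assert any(150 in (p.ref_id_a, p.ref_id_b) and
                   {p.segment_a, p.segment_b} == {NLOBE_DONOR, ACCEPTOR_CLOBE}
                   for p in report.pairs)
        relieve_clashes(template, policy="truncate_sidechain")
        assert len(detect_clashes(template)) == 0
        assert any("truncated" in e for e in template.edits)

    def test_flag_only_leaves_coordinates(self, default_scaffold):
        template = self_chimera(default_scaffold)
        target = default_scaffold.residue_by_ref(150).coord("CA")
        offender = next(res for res, seg in zip(template.residues,
                                                template.provenance)
                        if seg == NLOBE_DONOR and res.name != "GLY")
        offender.add_atom(Atom("CG", "C", target + np.array([1.0, 0, 0])))
        before = {id(res): {k: a.coord.copy() for k, a in res.atoms.items()}
                  for res in template.residues}
        relieve_clashes(template, policy="flag_only")
        for res in template.residues:
            for key, atom in res.atoms.items():
                np.testing.assert_array_equal(atom.coord, before[id(res)][key])

    def test_backbone_backbone_clash_fatal_flag(self, default_scaffold):
        template = self_chimera(default_scaffold)
        # force two backbone atoms together across segments
        nlobe_res = next(res for res, seg in zip(template.residues,
                                                 template.provenance)
                         if seg == NLOBE_DONOR)
        clobe_res = next(res for res, seg in zip(template.residues,
                                                 template.provenance)
                         if seg == ACCEPTOR_CLOBE)
        nlobe_res.atoms[("N", "")].coord = clobe_res.coord("CA") + 0.5
        relieve_clashes(template, policy="truncate_sidechain")
        assert any(w.startswith("fatal") for w in template.warnings)


class TestTemplateAlignment:
    def test_identical_sequences_gap_free(self, default_scaffold):
        template = self_chimera(default_scaffold)
        target = default_scaffold.sequence()
        alignment = build_template_alignment(target, template)
        assert "-" not in alignment.target_row
        assert "-" not in alignment.template_row
        assert alignment.template_row == target

    def test_target_insertion_opens_template_gap(self, default_scaffold):
        template = self_chimera(default_scaffold)
        seq = default_scaffold.sequence()
        target = seq[:130] + "GS" + seq[130:]
        alignment = build_template_alignment(target, template)
        assert alignment.template_row.count("-") == 2
        assert "-" not in alignment.target_row

    def test_rows_degap_to_inputs(self, default_scaffold):
        template = self_chimera(default_scaffold)
        seq = default_scaffold.sequence()
        target = seq[:100] + seq[103:]  # 3-residue deletion
        alignment = build_template_alignment(target, template)
        assert alignment.target_row.replace("-", "") == target
        assert alignment.template_row.replace("-", "") == seq

    def test_unrelated_sequence_floor_error(self, default_scaffold):
        """Shuffled-composition decoy falls under the empirical score floor."""
        rng = np.random.default_rng(0)
        decoy = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150))
        template = self_chimera(default_scaffold)
        with pytest.raises(AlignmentFloorError):
            build_template_alignment(decoy, template)

    def test_pir_and_fasta_serialisation(self, default_scaffold):
        template = self_chimera(default_scaffold)
        target = default_scaffold.sequence()
        alignment = build_template_alignment(target, template,
                                             target_name="kinase1")
        pir = alignment.to_pir()
        assert pir.startswith(">P1;kinase1\n")
        assert "structureX:" in pir and pir.rstrip().endswith("*")
        fasta = alignment.to_fasta()
        assert fasta.count(">") == 2
        segments = set(alignment.segment_track)
        assert {"N", "C", "A"} <= segments
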