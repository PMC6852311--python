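"""Orchestration: donor libraries, 18-template ensembles, batch
classification and model-vs-experiment matching.

One ensemble-generation run takes a target sequence, a DFG-in acceptor
structure and a donor library holding six N-lobe donors (P-loop ×
αC-helix combinations) and three A-loop donors, and emits one chimeric
template plus target-to-template alignment per combination — 2 × 3 × 3 = 18
templates, indexed 1–18 in the conventional HM order (P-loop slowest, then
αC, then A-loop).  Individual template failures are recorded in the
manifest and never abort the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import geometry
from .chimera_builder import (SegmentBoundaries, TemplateSpec,
                              build_template_alignment, detect_clashes,
                              relieve_clashes, splice, superpose_donor)
from .classifiers import (ALOOP_CLASSES, ALPHAC_CLASSES, PLOOP_CLASSES,
                          ClassifierConfig, classify_structure,
                          compute_features, default_config, FEATURE_NAMES)
from .errors import KinoforgeError
from .reference_numbering import NumberedDomain, ScoringParams, number_chain
from .structure_model import read_structure, select_chain, write_structure

__all__ = [
    "DonorEntry",
    "DonorLibrary",
    "EnsembleManifest",
    "MatchReport",
    "enumerate_specs",
    "build_ensemble",
    "classify_batch",
    "match_experimental",
]

logger = logging.getLogger("kinoforge")


@dataclass
class DonorEntry:
    domain: NumberedDomain
    provenance: str    # e.g. "4QQ5:A" or "synthetic:nlobe_collapsed_in"


@dataclass
class DonorLibrary:
    """Donor structures keyed by their conformational class slots.

    Exactly one N-lobe entry per (P-loop, αC) pair and one A-loop entry per
    A-loop class; every entry's verified classification must match its
    library label, otherwise validation fails at load time.
    """

    nlobe: dict    # (ploop_class, alphac_class) -> DonorEntry
    aloop: dict    # aloop_class -> DonorEntry

    def missing_slots(self) -> list:
        slots = [f"nlobe {p}/{a}" for p in PLOOP_CLASSES for a in ALPHAC_CLASSES
                 if (p, a) not in self.nlobe]
        slots += [f"aloop {a}" for a in ALOOP_CLASSES if a not in self.aloop]
        return slots

    def validate(self, config: ClassifierConfig | None = None) -> None:
        config = config or default_config()
        missing = self.missing_slots()
        if missing:
            raise KinoforgeError("donor library incomplete: " + ", ".join(missing))
        for (ploop, alphac), entry in self.nlobe.items():
            label = classify_structure(entry.domain, config)
            if label.ploop.value != ploop or label.alphac.value != alphac:
                raise KinoforgeError(
                    f"N-lobe donor {entry.provenance} labelled {ploop}/{alphac} "
                    f"but classifies as {label.ploop.value}/{label.alphac.value}")
        for aloop, entry in self.aloop.items():
            label = classify_structure(entry.domain, config)
            if label.aloop.value != aloop:
                raise KinoforgeError(
                    f"A-loop donor {entry.provenance} labelled {aloop} "
                    f"but classifies as {label.aloop.value}")


def enumerate_specs(library: DonorLibrary) -> list:
    """The 18 template specs in HM order (HM 1 = closed type 2 / collapsed /
    αC-in ... HM 18 = closed A-under-P / stretched / αC-out)."""
    missing = library.missing_slots()
    if missing:
        raise KinoforgeError("donor library incomplete: " + ", ".join(missing))
    specs = []
    index = 0
    for ploop in PLOOP_CLASSES:
        for alphac in ALPHAC_CLASSES:
            for aloop in ALOOP_CLASSES:
                index += 1
                specs.append(TemplateSpec(
                    ploop_class=ploop, alphac_class=alphac, aloop_class=aloop,
                    nlobe_donor=library.nlobe[(ploop, alphac)].provenance,
                    aloop_donor=library.aloop[aloop].provenance,
                    model_type_index=index))
    return specs


@dataclass
class TemplateRecord:
    spec: TemplateSpec
    pdb_path: str = ""
    pir_path: str = ""
    fasta_path: str = ""
    clash_count: int = 0
    edits: list = field(default_factory=list)
    junction_flags: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    error: str = ""

    @property
    def fatal(self) -> bool:
        return bool(self.error) or any(w.startswith("fatal") for w in self.warnings)

    def as_dict(self) -> dict:
        d = self.spec.as_dict()
        d.update(pdb=self.pdb_path, pir=self.pir_path, fasta=self.fasta_path,
                 clash_count=self.clash_count, edits=self.edits,
                 junction_flags=self.junction_flags, warnings=self.warnings,
                 error=self.error, fatal=self.fatal)
        return d


@dataclass
class EnsembleManifest:
    kinase: str
    acceptor: str
    records: list
    config_hash: str
    tool_version: str
    timestamp: str

    def as_dict(self) -> dict:
        return {"kinase": self.kinase, "acceptor": self.acceptor,
                "config_hash": self.config_hash, "tool_version": self.tool_version,
                "timestamp": self.timestamp,
                "templates": [r.as_dict() for r in self.records]}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def config_hash(config: ClassifierConfig) -> str:
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_ensemble(target_seq: str, acceptor: NumberedDomain,
                   library: DonorLibrary, out_dir,
                   config: ClassifierConfig | None = None,
                   bounds: SegmentBoundaries | None = None,
                   scoring: ScoringParams = ScoringParams(),
                   kinase: str = "target",
                   clash_policy: str = "truncate_sidechain",
                   validate_library: bool = True) -> EnsembleManifest:
    """Build all 18 chimeric templates plus alignments for one kinase.

    Writes ``<tag>.pdb``, ``<tag>.pir`` and ``<tag>.afa`` per template and a
    JSON manifest; a failed template is recorded and skipped, never fatal
    for the run.
    """
    from . import __version__
    config = config or default_config()
    bounds = bounds or SegmentBoundaries()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if validate_library:
        library.validate(config)
    acceptor_label = classify_structure(acceptor, config)
    if acceptor_label.dfg.value != "in":
        logger.warning("acceptor %s classifies DFG=%s, expected DFG-in",
                       acceptor.name, acceptor_label.dfg.value)
    records = []
    # donors are rigid for the whole run: superpose each once
    fitted = {}
    for key, entry in list(library.nlobe.items()) + list(library.aloop.items()):
        moved, fit = superpose_donor(entry.domain, acceptor, bounds)
        fitted[entry.provenance] = (moved, fit)
    for spec in enumerate_specs(library):
        spec.acceptor = acceptor.name or "acceptor"
        record = TemplateRecord(spec)
        try:
            nlobe_t, nfit = fitted[spec.nlobe_donor]
            aloop_t, afit = fitted[spec.aloop_donor]
            template = splice(acceptor, nlobe_t, aloop_t, bounds, spec)
            template.nlobe_fit, template.aloop_fit = nfit, afit
            detect_clashes(template)
            relieve_clashes(template, policy=clash_policy)
            record.clash_count = len(template.clash_report or [])
            record.edits = list(template.edits)
            record.junction_flags = list(template.junction_flags)
            record.warnings = list(template.warnings)
            tag = spec.tag()
            pdb_path = out_dir / f"{tag}.pdb"
            write_structure(template.residues, pdb_path,
                            provenance=template.provenance_runs())
            alignment = build_template_alignment(target_seq, template, scoring,
                                                 target_name=kinase)
            pir_path = out_dir / f"{tag}.pir"
            fasta_path = out_dir / f"{tag}.afa"
            pir_path.write_text(alignment.to_pir())
            fasta_path.write_text(alignment.to_fasta())
            record.pdb_path = str(pdb_path)
            record.pir_path = str(pir_path)
            record.fasta_path = str(fasta_path)
            logger.info("template %s built (%d clashes, %d edits)",
                        tag, record.clash_count, len(record.edits))
        except KinoforgeError as exc:
            record.error = str(exc)
            logger.error("template %s failed: %s", spec.tag(), exc)
        records.append(record)
    manifest = EnsembleManifest(
        kinase=kinase, acceptor=spec.acceptor, records=records,
        config_hash=config_hash(config), tool_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat())
    manifest.write(out_dir / "manifest.json")
    return manifest


def classify_batch(paths, chains=None, config: ClassifierConfig | None = None,
                   scoring: ScoringParams = ScoringParams()) -> pd.DataFrame:
    """Classify one chain per input file; unreadable or unalignable entries
    become error rows, never exceptions."""
    config = config or default_config()
    rows = []
    chains = chains or {}
    for path in paths:
        path = Path(path)
        chain_id = chains.get(str(path)) or chains.get(path.name)
        row = {"path": str(path), "chain": chain_id or "", "error": ""}
        try:
            structure = read_structure(path)
            cid = chain_id or structure.chain_ids(0)[0]
            row["chain"] = cid
            chain = select_chain(structure, cid, 0)
            domain = number_chain(chain, scoring=scoring, name=path.stem)
            fv = compute_features(domain, config)
            label = classify_structure(domain, config, fv)
            row.update({f"label_{k}": v for k, v in label.as_dict().items()})
            row.update({k: fv.get(k) for k in FEATURE_NAMES})
        except KinoforgeError as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MatchPair:
    candidate: str
    reference: str
    rmsd: float
    n_residues: int
    similar: bool
    classification_match: bool


@dataclass
class MatchReport:
    threshold: float
    pairs: list
    skipped: list            # (candidate, reference, reason)

    def best_partner(self, candidate: str):
        mine = [p for p in self.pairs if p.candidate == candidate]
        return min(mine, key=lambda p: p.rmsd) if mine else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairs])


def match_experimental(candidates: dict, references: dict,
                       threshold: float = 0.7,
                       config: ClassifierConfig | None = None) -> MatchReport:
    """All-vs-all backbone-RMSD comparison of candidate structures (e.g.
    templates or models) against experimental references.

    Pairs are superposed over their common reference IDs; a pair is
    *similar* iff its backbone RMSD is below the threshold (0.7 Å in the
    conventional setting), and a *classification match* additionally
    requires identical assigned A-loop/P-loop/αC classes.  Inputs are
    ``name -> NumberedDomain`` mappings.
    """
    config = config or default_config()
    labels = {}
    for name, domain in {**candidates, **references}.items():
        if name not in labels:
            labels[name] = classify_structure(domain, config)
    pairs, skipped = [], []
    for cname, cdom in candidates.items():
        for rname, rdom in references.items():
            try:
                report = geometry.backbone_rmsd_report(cdom, rdom, fit=True)
            except KinoforgeError as exc:
                skipped.append((cname, rname, str(exc)))
                continue
            pairs.append(MatchPair(
                candidate=cname, reference=rname, rmsd=report.rmsd,
                n_residues=len(report.used_ids),
                similar=report.rmsd < threshold,
                classification_match=labels[cname].matches(labels[rname])))
    return MatchReport(threshold, pairs, skipped)
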