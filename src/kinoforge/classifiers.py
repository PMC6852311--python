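"""Conformational classifiers for kinase catalytic domains.

Four binding-site-forming elements are classified independently:

* **DFG** {in, out} — a pseudodihedral over four atoms around the DFG Asp
  (configurable quadruple; the default uses Cα of DFG−1, Cα and Cγ of the
  Asp, and the carboxylate-oxygen centroid).
* **A-loop** {closed type 2, open DFG-out, closed A-under-P} — the Cα
  pseudotorsions ξ_DFG{−1,D} and ξ_DFG{F,G} plus the Cα distance between
  HRD−4 (ID 160) and DFG+3 (ID 189); each class is a conjunction of two
  angular intervals and one distance interval.
* **P-loop** {collapsed, stretched} — four features (ψ at IDs 49 and 56,
  ξ over Cα 55–58, Cα distance 54–170); a class is assigned when at least
  three of its four conditions hold and it strictly beats the other class.
* **αC-helix** {in, inter, out} — minimal Lys72(NZ)–Glu91(OE1/OE2)
  distance: ≤ 4 Å → in, ≥ 8.5 Å → out; in between, the Glu side-chain
  dihedral decides (≤ 100° → inter, otherwise in).

Feature unavailability (missing atoms) is data, not an error: the affected
element is reported ``unassigned`` with a machine-readable reason.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import geometry
from .errors import ConfigError, MissingAtomError, DegenerateGeometryError

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "Interval",
    "ClassifierConfig",
    "ElementLabel",
    "ConformationLabel",
    "default_config",
    "compute_features",
    "classify_dfg",
    "classify_alphac",
    "classify_ploop",
    "classify_aloop",
    "classify_structure",
    "PLOOP_CLASSES",
    "ALPHAC_CLASSES",
    "ALOOP_CLASSES",
]

PLOOP_CLASSES = ("collapsed", "stretched")
ALPHAC_CLASSES = ("in", "inter", "out")
ALOOP_CLASSES = ("closed_type2", "open_dfg_out", "closed_a_under_p")

FEATURE_NAMES = (
    "xi_dfg_m1_d", "xi_dfg_f_g", "d_hrd_m4_dfg_p3",
    "psi_gmotif_m1", "psi_gmotif_p1", "xi_gmotif_p1_p2", "d_phi_hrd_p4",
    "d_lys_glu", "chi_glu", "dfg_pseudodihedral",
)

_ANGLE_FEATURES = {"xi_dfg_m1_d", "xi_dfg_f_g", "psi_gmotif_m1", "psi_gmotif_p1",
                   "xi_gmotif_p1_p2", "chi_glu", "dfg_pseudodihedral"}


@dataclass
class FeatureVector:
    """All classifier observables for one domain; ``None`` = unavailable,
    with the reason recorded in :attr:`unavailable`."""

    xi_dfg_m1_d: float | None = None
    xi_dfg_f_g: float | None = None
    d_hrd_m4_dfg_p3: float | None = None
    psi_gmotif_m1: float | None = None
    psi_gmotif_p1: float | None = None
    xi_gmotif_p1_p2: float | None = None
    d_phi_hrd_p4: float | None = None
    d_lys_glu: float | None = None
    chi_glu: float | None = None
    dfg_pseudodihedral: float | None = None
    unavailable: dict = field(default_factory=dict)

    def get(self, name: str):
        return getattr(self, name)

    def available(self, name: str) -> bool:
        return getattr(self, name) is not None

    def as_dict(self) -> dict:
        return {n: self.get(n) for n in FEATURE_NAMES}


@dataclass(frozen=True)
class Interval:
    """Closed interval; for angles, ``lo > hi`` wraps through ±180°."""

    lo: float
    hi: float
    angular: bool = False

    def contains(self, x: float) -> bool:
        if x is None:
            return False
        if self.angular:
            x = geometry.wrap_angle(x)
            if self.lo <= self.hi:
                return self.lo <= x <= self.hi
            return x >= self.lo or x <= self.hi
        return self.lo <= x <= self.hi

    def midpoint(self) -> float:
        if self.angular and self.lo > self.hi:
            return geometry.wrap_angle((self.lo + self.hi + 360.0) / 2.0)
        return (self.lo + self.hi) / 2.0

    def overlaps(self, other: "Interval") -> bool:
        if not self.angular:
            return self.lo <= other.hi and other.lo <= self.hi
        probes = [self.lo, self.hi, other.lo, other.hi,
                  self.midpoint(), other.midpoint()]
        return any(self.contains(p) and other.contains(p) for p in probes)


def _interval(pair, angular: bool) -> Interval:
    lo, hi = float(pair[0]), float(pair[1])
    if not angular and lo > hi:
        raise ConfigError(f"malformed distance interval [{lo}, {hi}]")
    return Interval(lo, hi, angular)


@dataclass
class QuadrupleAtom:
    ref_offset: int
    atom: str | None = None
    centroid: tuple | None = None


@dataclass
class ClassifierConfig:
    """Versioned classifier thresholds; see the packaged YAML for defaults."""

    version: int
    dfg_in: Interval
    dfg_out: Interval
    dfg_quadruple: list
    alphac_d_in_max: float
    alphac_d_out_min: float
    alphac_chi_inter_max: float
    glu_chi_index: int
    ploop_min_conditions: int
    ploop_classes: dict      # name -> {feature: Interval}
    aloop_classes: dict      # name -> {feature: Interval}

    def validate(self) -> None:
        if not self.alphac_d_in_max < self.alphac_d_out_min:
            raise ConfigError("alphac: d_in_max must be < d_out_min")
        if not 1 <= self.ploop_min_conditions <= 4:
            raise ConfigError("ploop: min_conditions must be in 1..4")
        if set(self.ploop_classes) != set(PLOOP_CLASSES):
            raise ConfigError(f"ploop classes must be {PLOOP_CLASSES}")
        if set(self.aloop_classes) != set(ALOOP_CLASSES):
            raise ConfigError(f"aloop classes must be {ALOOP_CLASSES}")
        if self.dfg_in.overlaps(self.dfg_out):
            raise ConfigError("dfg: in/out intervals overlap")
        # A-loop class boxes must be pairwise disjoint so at most one matches
        names = list(self.aloop_classes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                box_a = self.aloop_classes[a]
                box_b = self.aloop_classes[b]
                if all(box_a[f].overlaps(box_b[f]) for f in box_a):
                    raise ConfigError(f"aloop: class boxes {a!r} and {b!r} overlap")

    @staticmethod
    def from_dict(doc: dict) -> "ClassifierConfig":
        try:
            dfg = doc["dfg"]
            quad = [QuadrupleAtom(int(q["ref_offset"]), q.get("atom"),
                                  tuple(q["centroid"]) if "centroid" in q else None)
                    for q in dfg["quadruple"]]
            if len(quad) != 4:
                raise ConfigError("dfg quadruple must have 4 entries")
            alphac = doc["alphac"]
            ploop = doc["ploop"]
            aloop = doc["aloop"]
            ploop_classes = {
                name: {
                    "psi_gmotif_m1": _interval(c["psi_gmotif_m1"], True),
                    "psi_gmotif_p1": _interval(c["psi_gmotif_p1"], True),
                    "xi_gmotif_p1_p2": _interval(c["xi_gmotif_p1_p2"], True),
                    "d_phi_hrd_p4": _interval(c["d_phi_hrd_p4"], False),
                } for name, c in ploop["classes"].items()}
            aloop_classes = {
                name: {
                    "xi_dfg_m1_d": _interval(c["xi_dfg_m1_d"], True),
                    "xi_dfg_f_g": _interval(c["xi_dfg_f_g"], True),
                    "d_hrd_m4_dfg_p3": _interval(c["d_hrd_m4_dfg_p3"], False),
                } for name, c in aloop["classes"].items()}
            cfg = ClassifierConfig(
                version=int(doc.get("version", 1)),
                dfg_in=_interval(dfg["in_interval"], True),
                dfg_out=_interval(dfg["out_interval"], True),
                dfg_quadruple=quad,
                alphac_d_in_max=float(alphac["d_in_max"]),
                alphac_d_out_min=float(alphac["d_out_min"]),
                alphac_chi_inter_max=float(alphac["chi_inter_max"]),
                glu_chi_index=int(alphac.get("glu_chi_index", 1)),
                ploop_min_conditions=int(ploop.get("min_conditions", 3)),
                ploop_classes=ploop_classes,
                aloop_classes=aloop_classes,
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise ConfigError(f"malformed classifier config: {exc}") from exc
        cfg.validate()
        return cfg

    @staticmethod
    def from_yaml(path) -> "ClassifierConfig":
        with open(path) as fh:
            return ClassifierConfig.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def pair(iv):
            return [iv.lo, iv.hi]
        return {
            "version": self.version,
            "dfg": {
                "in_interval": pair(self.dfg_in),
                "out_interval": pair(self.dfg_out),
                "quadruple": [
                    {"ref_offset": q.ref_offset,
                     **({"atom": q.atom} if q.atom else {}),
                     **({"centroid": list(q.centroid)} if q.centroid else {})}
                    for q in self.dfg_quadruple],
            },
            "alphac": {"d_in_max": self.alphac_d_in_max,
                       "d_out_min": self.alphac_d_out_min,
                       "chi_inter_max": self.alphac_chi_inter_max,
                       "glu_chi_index": self.glu_chi_index},
            "ploop": {"min_conditions": self.ploop_min_conditions,
                      "classes": {n: {f: pair(iv) for f, iv in c.items()}
                                  for n, c in self.ploop_classes.items()}},
            "aloop": {"classes": {n: {f: pair(iv) for f, iv in c.items()}
                                  for n, c in self.aloop_classes.items()}},
        }


def default_config() -> ClassifierConfig:
    text = importlib.resources.files("kinoforge.data") \
        .joinpath("default_classifier.yaml").read_text()
    return ClassifierConfig.from_dict(yaml.safe_load(text))


def _dfg_pseudodihedral(domain, cfg: ClassifierConfig) -> float:
    asp_id = domain.anchors.dfg_asp_id
    points = []
    for q in cfg.dfg_quadruple:
        res = domain.residue_by_ref(asp_id + q.ref_offset)
        if res is None:
            raise MissingAtomError(f"missing residue at reference {asp_id + q.ref_offset}")
        if q.atom is not None:
            c = res.coord(q.atom)
            if c is None:
                raise MissingAtomError(
                    f"missing {q.atom} at reference {asp_id + q.ref_offset}")
            points.append(c)
        else:
            coords = [res.coord(n) for n in q.centroid]
            coords = [c for c in coords if c is not None]
            if not coords:
                raise MissingAtomError(
                    f"no atom of {list(q.centroid)} at reference {asp_id + q.ref_offset}")
            points.append(np.mean(coords, axis=0))
    return geometry.dihedral(*points)


def compute_features(domain, cfg: ClassifierConfig | None = None) -> FeatureVector:
    """Compute every classifier observable; a pure function of coordinates.

    Missing atoms mark the affected feature unavailable instead of raising.
    """
    cfg = cfg or default_config()
    a = domain.anchors
    fv = FeatureVector()

    def compute(name, fn):
        try:
            setattr(fv, name, float(fn()))
        except (MissingAtomError, DegenerateGeometryError) as exc:
            fv.unavailable[name] = str(exc)

    compute("xi_dfg_m1_d", lambda: geometry.ca_pseudotorsion(domain, a.dfg_asp_id - 2))
    compute("xi_dfg_f_g", lambda: geometry.ca_pseudotorsion(domain, a.dfg_asp_id))
    compute("d_hrd_m4_dfg_p3",
            lambda: geometry.ca_distance(domain, a.hrd_minus4_id, a.dfg_plus3_id))
    compute("psi_gmotif_m1", lambda: geometry.backbone_psi(domain, a.psi_pre_id))
    compute("psi_gmotif_p1", lambda: geometry.backbone_psi(domain, a.psi_post_id))
    compute("xi_gmotif_p1_p2",
            lambda: geometry.ca_pseudotorsion(domain, a.xi_gmotif_start_id))
    compute("d_phi_hrd_p4",
            lambda: geometry.ca_distance(domain, a.gmotif_phi_id, a.hrd_plus4_id))
    compute("d_lys_glu",
            lambda: geometry.min_atom_distance(domain, a.lys_id, ("NZ",),
                                               a.glu_id, ("OE1", "OE2")))

    def chi():
        res = domain.residue_by_ref(a.glu_id)
        if res is None:
            raise MissingAtomError(f"missing residue at reference {a.glu_id}")
        return geometry.sidechain_chi(res, cfg.glu_chi_index)

    compute("chi_glu", chi)
    compute("dfg_pseudodihedral", lambda: _dfg_pseudodihedral(domain, cfg))
    return fv


@dataclass
class ElementLabel:
    value: str                  # class name or "unassigned"
    evidence: dict = field(default_factory=dict)
    reason: str | None = None   # populated when unassigned

    @property
    def assigned(self) -> bool:
        return self.value != "unassigned"


def classify_dfg(fv: FeatureVector, cfg: ClassifierConfig) -> ElementLabel:
    x = fv.dfg_pseudodihedral
    if x is None:
        return ElementLabel("unassigned",
                            reason=fv.unavailable.get("dfg_pseudodihedral",
                                                      "dfg_pseudodihedral unavailable"))
    ev = {"dfg_pseudodihedral": x}
    if cfg.dfg_out.contains(x):
        return ElementLabel("out", ev)
    if cfg.dfg_in.contains(x):
        return ElementLabel("in", ev)
    return ElementLabel("unassigned", ev, reason="pseudodihedral between in/out intervals")


def classify_alphac(fv: FeatureVector, cfg: ClassifierConfig) -> ElementLabel:
    d = fv.d_lys_glu
    if d is None:
        return ElementLabel("unassigned",
                            reason=fv.unavailable.get("d_lys_glu", "d_lys_glu unavailable"))
    ev = {"d_lys_glu": d}
    if d <= cfg.alphac_d_in_max:
        return ElementLabel("in", ev)
    if d >= cfg.alphac_d_out_min:
        return ElementLabel("out", ev)
    chi = fv.chi_glu
    if chi is None:
        return ElementLabel("unassigned", ev,
                            reason="chi needed: d in intermediate band but "
                            + fv.unavailable.get("chi_glu", "chi_glu unavailable"))
    ev["chi_glu"] = chi
    if abs(chi) <= cfg.alphac_chi_inter_max:
        return ElementLabel("inter", ev)
    return ElementLabel("in", ev)


def classify_ploop(fv: FeatureVector, cfg: ClassifierConfig) -> ElementLabel:
    features = ("psi_gmotif_m1", "psi_gmotif_p1", "xi_gmotif_p1_p2", "d_phi_hrd_p4")
    missing = [f for f in features if not fv.available(f)]
    if len(missing) > 1:
        return ElementLabel("unassigned",
                            reason="features unavailable: " + ", ".join(missing))
    counts = {}
    fired = {}
    for name, box in cfg.ploop_classes.items():
        hits = [f for f in features if fv.available(f) and box[f].contains(fv.get(f))]
        counts[name] = len(hits)
        fired[name] = hits
    ev = {f: fv.get(f) for f in features}
    ev["conditions"] = fired
    qualifying = [n for n, c in counts.items() if c >= cfg.ploop_min_conditions]
    if not qualifying:
        return ElementLabel("unassigned", ev, reason="no class reaches min conditions")
    best = max(counts, key=lambda n: counts[n])
    others = [c for n, c in counts.items() if n != best]
    if counts[best] >= cfg.ploop_min_conditions and all(counts[best] > c for c in others):
        return ElementLabel(best, ev)
    return ElementLabel("unassigned", ev, reason="ambiguous: equal qualifying counts")


def classify_aloop(fv: FeatureVector, cfg: ClassifierConfig) -> ElementLabel:
    features = ("xi_dfg_m1_d", "xi_dfg_f_g", "d_hrd_m4_dfg_p3")
    missing = [f for f in features if not fv.available(f)]
    if missing:
        return ElementLabel("unassigned",
                            reason="features unavailable: " + ", ".join(missing))
    ev = {f: fv.get(f) for f in features}
    for name in ALOOP_CLASSES:
        box = cfg.aloop_classes[name]
        if all(box[f].contains(fv.get(f)) for f in features):
            return ElementLabel(name, ev)
    return ElementLabel("unassigned", ev, reason="outside all class boxes")


@dataclass
class ConformationLabel:
    dfg: ElementLabel
    aloop: ElementLabel
    ploop: ElementLabel
    alphac: ElementLabel

    def as_dict(self) -> dict:
        return {"dfg": self.dfg.value, "aloop": self.aloop.value,
                "ploop": self.ploop.value, "alphac": self.alphac.value}

    def matches(self, other: "ConformationLabel") -> bool:
        """Classification match over the three flexible elements (A-loop,
        P-loop, αC), requiring both sides assigned."""
        for el_a, el_b in ((self.aloop, other.aloop), (self.ploop, other.ploop),
                           (self.alphac, other.alphac)):
            if not el_a.assigned or not el_b.assigned or el_a.value != el_b.value:
                return False
        return True


def classify_structure(domain, cfg: ClassifierConfig | None = None,
                       fv: FeatureVector | None = None) -> ConformationLabel:
    """Composite classification; A-loop/P-loop/αC are classified regardless
    of the DFG state, and the DFG label is always reported."""
    cfg = cfg or default_config()
    if fv is None:
        fv = compute_features(domain, cfg)
    return ConformationLabel(
        dfg=classify_dfg(fv, cfg),
        aloop=classify_aloop(fv, cfg),
        ploop=classify_ploop(fv, cfg),
        alphac=classify_alphac(fv, cfg),
    )
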