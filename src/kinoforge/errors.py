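"""Exception hierarchy shared across the package."""


class KinoforgeError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(KinoforgeError):
    """A structure file could not be read under the requested dialect."""


class NoProteinError(KinoforgeError):
    """A parsed file contains no protein chains."""


class ChainLookupError(KinoforgeError, LookupError):
    """Requested chain or model is absent; message lists what is available."""


class MissingAtomError(KinoforgeError):
    """A named atom required by a geometric feature is absent."""


class DegenerateGeometryError(KinoforgeError):
    """Dihedral/superposition input is geometrically degenerate."""


class AlignmentFloorError(KinoforgeError):
    """Pairwise alignment score fell below the configured floor."""


class AnchorUnresolvedError(KinoforgeError):
    """One or more reference anchors could not be mapped onto the chain."""

    def __init__(self, anchor_names):
        self.anchor_names = tuple(anchor_names)
        super().__init__("anchor unresolved: " + ", ".join(self.anchor_names))


class ConfigError(KinoforgeError):
    """Classifier or pipeline configuration failed validation."""


class InsufficientOverlapError(KinoforgeError):
    """Too few common reference positions for a reliable superposition."""


class InfeasiblePoseError(KinoforgeError):
    """Requested synthetic-scaffold feature values cannot be realised."""
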