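"""Exception hierarchy for fvstates."""


class FvStatesError(Exception):
    """Base class for all fvstates errors."""


class StructureError(FvStatesError):
    """Malformed or incomplete input structure (e.g. missing chain H or L)."""


class TopologyError(FvStatesError):
    """Trajectory does not match its topology (atom-count mismatch, ...)."""


class GeometryError(FvStatesError):
    """Degenerate geometry: collinear selections, insufficient core coverage."""


class FeatureError(FvStatesError):
    """Featurization failure: unknown loop, all torsions missing, label mismatch."""


class EstimationError(FvStatesError):
    """Model estimation failure: empty connected set, rank-deficient covariance."""


class InputError(FvStatesError, ValueError):
    """Invalid argument values (non-stochastic matrix, lag >= length, ...)."""


class UnsupportedResidueError(FvStatesError):
    """Residue cannot be analyzed (glycine in sidechain-orientation analysis)."""
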