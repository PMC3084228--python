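"""Exception hierarchy for the off-target screening toolkit."""


class OffpipeError(Exception):
    """Base class for all toolkit errors."""


class PDBParseError(OffpipeError):
    """Malformed fixed-width PDB record; message names the line number."""


class RosterError(OffpipeError):
    """Atom rosters differ across MODELs of a multi-model file."""


class SelectionError(OffpipeError):
    """A selector or window matched nothing (or was ambiguous)."""


class GenerationError(OffpipeError):
    """Synthetic fixture generation failed after bounded retries."""


class DegenerateFitError(OffpipeError):
    """Too few or collinear points for a rigid superposition."""


class SubstitutionTableError(OffpipeError):
    """Residue code missing from the amino-acid substitution table."""


class FitError(OffpipeError):
    """Distribution fit on degenerate input."""


class ScreeningError(OffpipeError):
    """Background generation or screening failure."""


class ComparabilityError(OffpipeError):
    """Two sites do not share a parent structure."""


class ParameterizationError(OffpipeError):
    """Force-field parameters unresolvable for some atom."""


class SchemaError(OffpipeError):
    """Parameter file or edge table violates its documented schema."""


class OptimizationError(OffpipeError):
    """Minimization diverged or started from a non-finite energy."""


class NotMinimizedError(OffpipeError):
    """Normal-mode analysis requested away from a local minimum."""


class NormalizationError(OffpipeError):
    """Constant or undersized background for score normalization."""


class KindError(OffpipeError):
    """Network node used with the wrong kind."""


class PipelineError(OffpipeError):
    """A pipeline stage failed; message names the stage."""
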