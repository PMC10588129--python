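"""Exception hierarchy for deconvbench."""


class DeconvbenchError(Exception):
    """Base class for all deconvbench errors."""


class ConfigurationError(DeconvbenchError):
    """Invalid configuration (bad proportions, non-partition pools, unknown names)."""


class DegenerateCompositionError(DeconvbenchError):
    """A composition collapsed to all-zero mass."""


class MissingCellTypeError(DeconvbenchError):
    """A required cell type is absent from the source data."""


class MalformedTableError(DeconvbenchError):
    """A posterior table row violates the simplex contract."""


class EmptyReferenceError(DeconvbenchError):
    """Subsetting a reference retained zero cells."""


class InfeasibleMinimumError(DeconvbenchError):
    """Downsampling target smaller than the number of cell types."""


class ShapeError(DeconvbenchError):
    """Dimension mismatch between operands."""


class ConvergenceError(DeconvbenchError):
    """Iterative solver exceeded its iteration cap."""


class GeneOverlapError(DeconvbenchError):
    """Too few shared genes between signature and bulk sample."""


class RegistryError(DeconvbenchError):
    """Unknown deconvolution method name."""


class AnnotationError(DeconvbenchError):
    """Cells lacking required annotation labels."""


class AlignmentError(DeconvbenchError):
    """Estimate and truth tables do not align on samples / cell types."""


class CoverageError(DeconvbenchError):
    """A method is present in one evaluation table but not another."""


class FormatError(DeconvbenchError):
    """A file does not conform to the expected on-disk format."""
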