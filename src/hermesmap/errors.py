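"""Exception types shared across the pipeline."""


class HermesmapError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(HermesmapError, ValueError):
    """An argument is outside its documented range."""


class FormatError(HermesmapError, ValueError):
    """An input file violates its format contract."""


class GenerationError(HermesmapError, RuntimeError):
    """Synthetic-data generation cannot satisfy its postconditions."""


class ConsistencyError(HermesmapError, RuntimeError):
    """Internal pipeline state is inconsistent (e.g. an unclassified peptide)."""


class GeometryError(HermesmapError, ValueError):
    """A geometric input is degenerate (e.g. a zero-length polyline)."""
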