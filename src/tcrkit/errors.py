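"""Exception hierarchy.  Every tcrkit error derives from TCRKitError so
batch drivers can catch one type and keep going."""


class TCRKitError(Exception):
    pass


class ParseError(TCRKitError):
    """Structure file could not be parsed."""


class FormatError(TCRKitError):
    """Unknown or unsupported file format."""


class FetchError(TCRKitError):
    """Remote structure retrieval failed."""


class ClassificationError(TCRKitError):
    """Chain could not be classified (e.g. empty sequence)."""


class NumberingError(TCRKitError):
    """IMGT numbering failed (alignment identity below threshold)."""


class AnchorError(TCRKitError):
    """A conserved anchor residue (IMGT 23/104) is missing."""


class GeometryError(TCRKitError):
    """Binding geometry is undefined for this input (e.g. apo TCR)."""


class FrameError(GeometryError):
    """MHC groove frame could not be constructed."""


class ParameterError(TCRKitError):
    """Score parameters are invalid."""


class FitError(TCRKitError):
    """Distribution fitting failed (degenerate data)."""


class ConfigError(TCRKitError):
    """Configuration / parameter file violates the schema."""


class CorrespondenceError(TCRKitError):
    """No atom correspondence could be built between two structures."""


class InterfaceError(TCRKitError):
    """No interface residues at the given cutoff."""


class GraphError(TCRKitError):
    """Residue graph construction failed."""


class DatasetError(TCRKitError):
    """Every input of a dataset build failed."""


class FixtureError(TCRKitError):
    """Toy-complex specification is impossible."""
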