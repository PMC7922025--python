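"""Exception hierarchy."""


class ChlorosimError(Exception):
    """Base class for package errors."""


class XYZFormatError(ChlorosimError, ValueError):
    """Malformed XYZ file; message names the offending line."""


class DegenerateGeometryError(ChlorosimError, ValueError):
    """Geometry does not define the requested quantity (collinear axes,
    coincident atoms, zero-length bonds)."""


class MappingError(ChlorosimError, ValueError):
    """Invalid atom-role index map."""


class CalibrationError(ChlorosimError, ValueError):
    """Spacing calibration target is unattainable in the given bracket."""


class UsageError(ChlorosimError, ValueError):
    """Inconsistent arguments (dimension mismatch, non-chain aggregate...)."""


class NoPeakError(ChlorosimError, ValueError):
    """Spectrum is identically zero; no peak exists."""
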