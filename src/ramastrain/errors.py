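"""Exception hierarchy for ramastrain."""


class RamastrainError(Exception):
    """Base class for all package errors."""


class FormatError(RamastrainError):
    """A file could not be parsed in the requested format."""


class EmptyModelError(RamastrainError):
    """A structure or model contains no atoms."""


class StructureError(RamastrainError):
    """A structural contract is violated (e.g. inconsistent trajectory frames)."""


class SequenceError(RamastrainError, ValueError):
    """An invalid residue letter or sequence was supplied."""


class GeometryError(RamastrainError):
    """Degenerate geometry (collinear points, zero-length bond vectors)."""


class NoTransitionError(RamastrainError):
    """A melting curve shows no detectable conformational transition."""


class FitError(RamastrainError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""


class DegenerateProfileError(RamastrainError):
    """A profile is constant and cannot be standardized."""
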