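"""Exception hierarchy.

All package errors derive from :class:`MitocharError` so callers can catch
one base class; the CLI maps the three subclasses to distinct exit codes.
"""


class MitocharError(Exception):
    """Base class for all mitochar errors."""


class FormatError(MitocharError):
    """Malformed or unsupported input file content."""


class CoordinateError(MitocharError):
    """Feature coordinates inconsistent with the genome."""


class ComputeError(MitocharError):
    """A computation is undefined for the given input (degenerate CDS,
    all-ambiguous sequence, zero comparable codons, ...)."""
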