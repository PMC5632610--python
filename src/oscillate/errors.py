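"""Exception hierarchy.

``InputError`` covers malformed or inconsistent user inputs (bad Newick,
missing table columns, unknown taxa); ``DegenerateDataError`` covers inputs
that are structurally valid but carry no information for the requested
statistic (constant traits, all-tied contrasts, zero variance). The CLI maps
the two classes onto distinct exit codes.
"""


class OscillateError(Exception):
    """Base class for all package errors."""


class InputError(OscillateError, ValueError):
    """Malformed or inconsistent input data."""


class NewickError(InputError):
    """Invalid Newick text or tree violating the rooted-tree invariants."""


class DegenerateDataError(OscillateError, ValueError):
    """Structurally valid data that cannot support the requested statistic."""
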