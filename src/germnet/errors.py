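"""Exception hierarchy.

``InputError`` marks problems a user can fix (malformed files, inconsistent
identifiers, thresholds out of range); everything else is an internal fault.
The CLI maps these onto exit codes 1 and 2 respectively.
"""


class GermnetError(Exception):
    """Base class for all package errors."""


class InputError(GermnetError):
    """User-correctable input or configuration problem."""
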