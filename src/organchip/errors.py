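"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage/argument problems -> 2,
unreadable or malformed inputs -> 3, anything else -> 4.
"""


class OrganChipError(Exception):
    """Base class for all package-specific errors."""


class InputError(OrganChipError):
    """A required input file or path is missing or unreadable."""


class FormatError(OrganChipError):
    """Input exists but its contents violate the expected format."""


class ArgumentError(OrganChipError, ValueError):
    """An argument value violates a documented precondition."""


class CapacityError(OrganChipError):
    """A generator could not satisfy a placement/size constraint."""
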