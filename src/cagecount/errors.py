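"""Exception hierarchy.

All package-specific failures derive from :class:`CageCountError` so callers
can catch one base class; parse/validation errors carry enough context
(file, line, field) to be actionable from a CLI.
"""

from __future__ import annotations


class CageCountError(Exception):
    """Base class for all cagecount errors."""


class StreamParseError(CageCountError):
    """A stream file is syntactically malformed."""

    def __init__(self, path: str, line: int | None, message: str):
        self.path = path
        self.line = line
        where = f"{path}:{line}" if line is not None else path
        super().__init__(f"{where}: {message}")


class ClassMappingError(CageCountError):
    """An unknown class id or label was encountered."""


class StreamValidationError(CageCountError):
    """A stream violates a structural invariant (boxes, ordering, ranges)."""


class ContractError(CageCountError):
    """A function was called outside its documented precondition."""


class DegenerateSpanError(ContractError):
    """Inner span mode with overlapping fences yields an empty interval."""


class ConfigError(CageCountError):
    """A run configuration value is invalid; the message names the field."""
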