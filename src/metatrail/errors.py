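"""Exception hierarchy.

Data problems (bad cell values, missing required fields) are *never* raised:
they are collected as :class:`~metatrail.model.ValidationIssue` records so a
whole batch can be reported at once.  Exceptions are reserved for misuse of
the API, misconfiguration of a study, and authorization failures.
"""


class MetatrailError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetatrailError):
    """Invalid study configuration: duplicate templates/fields, bad dictionary
    wiring, unregistered custom validators, malformed setup rows."""


class AuthorizationError(MetatrailError):
    """Actor lacks the admin flag or the required project role."""


class NotFoundError(MetatrailError):
    """A named project, template, field, sample or dictionary does not exist."""


class UnknownTemplateError(NotFoundError):
    """Event name does not resolve to any configured event template."""


class AnnotationSyntaxError(ConfigurationError):
    """Malformed curly-brace input-type annotation; the message names the
    offending token."""


class FormatError(MetatrailError):
    """Malformed CSV input (bad ``#DataTemplate:`` line, ragged row...);
    the message names the offending line or row."""


class SetupError(ConfigurationError):
    """Raised when a setup CSV contains invalid rows.  Carries the full
    aggregated error report in :attr:`issues`."""

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(f"row {i.row_index}: {i.message}" for i in self.issues)
        super().__init__(f"setup file invalid: {lines}")


class QueryError(MetatrailError):
    """Malformed query tree or a leaf naming an unknown field."""


class UsageError(MetatrailError):
    """API misuse: e.g. parent_value supplied for a parentless dictionary,
    replay over events of mixed entities."""
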