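"""Pluggable ontology-term lookup.

A field definition may carry an ``ontology_class`` identifier.  When the
store is given a provider, validation can restrict such a field to the
class's known terms; without one, the identifier is descriptive metadata
only.  The static provider here is backed by a plain mapping and is the
reference implementation for tests and offline use — a live terminology
service would implement the same two methods.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Optional, Protocol


class OntologyProvider(Protocol):
    def has_class(self, class_id: str) -> bool: ...

    def terms(self, class_id: str) -> list[str]:
        """All term labels of the class, including subclass terms."""
        ...


class StaticOntologyProvider:
    """Mapping-backed provider: ``{class_id: [term, ...]}``."""

    def __init__(self, classes: Mapping[str, Iterable[str]]):
        self._classes = {k: sorted(set(v)) for k, v in classes.items()}

    def has_class(self, class_id: str) -> bool:
        return class_id in self._classes

    def terms(self, class_id: str) -> list[str]:
        return list(self._classes.get(class_id, []))


def term_issue(provider: Optional[OntologyProvider], class_id: Optional[str],
               value: str) -> Optional[str]:
    """Return an error message if ``value`` is not a term of ``class_id``
    under the given provider; None when valid or not checkable."""
    if provider is None or not class_id or value == "":
        return None
    if not provider.has_class(class_id):
        return None
    if value not in provider.terms(class_id):
        return f"{value!r} is not a term of ontology class {class_id!r}"
    return None
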