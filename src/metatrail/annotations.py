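"""The curly-brace input-type annotation grammar.

A field definition may carry one annotation string that constrains the
values the field accepts:

==============================  =============================================
annotation                      meaning
==============================  =============================================
``{radio(A;B;C)}``              value must be exactly one listed option
``{dropdown(A;B;C)}``           same semantics, drop-down presentation
``{multi-dropdown(A;B;C)}``     value is a ``;``-joined subset of the options
``{ReadOnly:NA}``               value is fixed; empty cells fill the default
``{RegEx([ACTG]*)}``            value must match the pattern entirely
``{validate:Class.method}``     a registered custom validator is invoked
``{Dictionary:city,Parent:State}``  value must be in the named controlled
                                list, filtered by the row's parent field
==============================  =============================================

Option lists split on ``;`` preserving order and internal spaces.  An absent
or empty annotation means free-form input (type checking only).
"""
from __future__ import annotations

import re
from typing import Callable, Mapping, Optional, Protocol

from .errors import AnnotationSyntaxError, ConfigurationError
from .model import InputSpec, ValidationIssue

_PAREN_KEYWORDS = {
    "radio": "radio",
    "dropdown": "dropdown",
    "multi-dropdown": "multi_dropdown",
    "regex": "regex",
}
_COLON_KEYWORDS = {
    "readonly": "readonly",
    "validate": "custom_validator",
    "dictionary": "dictionary",
}
_VALIDATOR_KEY_RE = re.compile(r"[A-Za-z_]\w*\.[A-Za-z_]\w*")


def parse_annotation(text: Optional[str]) -> InputSpec:
    """Parse an annotation string into an :class:`InputSpec`.

    Empty or absent text yields the free-form spec.  Raises
    :class:`AnnotationSyntaxError` naming the offending token on unbalanced
    braces, unknown keywords or empty option lists.
    """
    s = (text or "").strip()
    if not s:
        return InputSpec()
    if not s.startswith("{") or not s.endswith("}") or len(s) < 2:
        raise AnnotationSyntaxError(f"unbalanced braces in annotation {s!r}")
    body = s[1:-1]

    m = re.fullmatch(r"([A-Za-z-]+)\((.*)\)", body, flags=re.DOTALL)
    if m:
        keyword, args = m.group(1), m.group(2)
        kind = _PAREN_KEYWORDS.get(keyword.lower())
        if kind is None:
            raise AnnotationSyntaxError(f"unknown annotation keyword {keyword!r}")
        if kind == "regex":
            try:
                re.compile(args)
            except re.error as exc:
                raise AnnotationSyntaxError(
                    f"invalid regular expression {args!r}: {exc}") from exc
            return InputSpec(kind="regex", pattern=args)
        options = args.split(";")
        if options == [""]:
            raise AnnotationSyntaxError(f"empty option list in {keyword!r} annotation")
        if any(o == "" for o in options):
            raise AnnotationSyntaxError(
                f"empty option token in {keyword!r} annotation {args!r}")
        return InputSpec(kind=kind, options=tuple(options))

    m = re.fullmatch(r"([A-Za-z]+):(.*)", body, flags=re.DOTALL)
    if m:
        keyword, rest = m.group(1), m.group(2)
        kind = _COLON_KEYWORDS.get(keyword.lower())
        if kind is None:
            raise AnnotationSyntaxError(f"unknown annotation keyword {keyword!r}")
        if kind == "readonly":
            return InputSpec(kind="readonly", default=rest)
        if kind == "custom_validator":
            if not _VALIDATOR_KEY_RE.fullmatch(rest):
                raise AnnotationSyntaxError(
                    f"custom validator key must be dotted Class.method, got {rest!r}")
            return InputSpec(kind="custom_validator", validator_key=rest)
        # dictionary: "<name>" or "<name>,Parent:<field>"
        name, sep, parent_part = rest.partition(",")
        if not name:
            raise AnnotationSyntaxError("empty dictionary name in annotation")
        parent_field = None
        if sep:
            pm = re.fullmatch(r"[Pp]arent:(.+)", parent_part)
            if not pm:
                raise AnnotationSyntaxError(
                    f"malformed dictionary parent clause {parent_part!r}")
            parent_field = pm.group(1)
        return InputSpec(kind="dictionary", dictionary_name=name,
                         parent_field=parent_field)

    raise AnnotationSyntaxError(f"unrecognized annotation body {body!r}")


def render_annotation(spec: InputSpec) -> str:
    """Canonical serialization; ``parse_annotation(render_annotation(s)) == s``."""
    if spec.kind == "freeform":
        return ""
    if spec.kind == "radio":
        return "{radio(%s)}" % ";".join(spec.options)
    if spec.kind == "dropdown":
        return "{dropdown(%s)}" % ";".join(spec.options)
    if spec.kind == "multi_dropdown":
        return "{multi-dropdown(%s)}" % ";".join(spec.options)
    if spec.kind == "readonly":
        return "{ReadOnly:%s}" % spec.default
    if spec.kind == "regex":
        return "{RegEx(%s)}" % spec.pattern
    if spec.kind == "custom_validator":
        return "{validate:%s}" % spec.validator_key
    if spec.kind == "dictionary":
        if spec.parent_field:
            return "{Dictionary:%s,Parent:%s}" % (spec.dictionary_name, spec.parent_field)
        return "{Dictionary:%s}" % spec.dictionary_name
    raise ValueError(f"cannot render spec of kind {spec.kind!r}")


class StoreContext(Protocol):
    """What annotation evaluation needs from the surrounding store."""

    def dictionary_values(self, name: str, parent_value: Optional[str] = None) -> list[str]: ...

    def get_validator(self, key: str) -> Callable: ...


def validate_against_spec(
    spec: InputSpec,
    raw: str,
    row_context: Mapping[str, str],
    store_context: Optional[StoreContext],
    *,
    row_index: int = 0,
    field: str = "",
) -> tuple[list[ValidationIssue], str]:
    """Evaluate one submitted value against a parsed annotation.

    Returns ``(issues, effective_raw)``; the effective value differs from
    ``raw`` only for read-only fields, where an empty cell is filled with the
    default.  Empty values are accepted by every kind except read-only
    (requiredness is a separate check).  Custom validators are *not* run
    here — they need whole-row context and live in the validation engine.
    """

    def issue(code: str, message: str) -> ValidationIssue:
        return ValidationIssue(row_index=row_index, field=field, code=code,
                               message=message)

    if spec.kind == "readonly":
        if raw == "":
            return [], spec.default
        if raw != spec.default:
            return [issue("readonly_conflict",
                          f"read-only field accepts only {spec.default!r}, "
                          f"got {raw!r}")], raw
        return [], raw

    if raw == "" or spec.kind in ("freeform", "custom_validator"):
        return [], raw

    if spec.kind in ("radio", "dropdown"):
        if raw not in spec.options:
            return [issue("option_violation",
                          f"{raw!r} is not one of the allowed options")], raw
        return [], raw

    if spec.kind == "multi_dropdown":
        bad = [t for t in raw.split(";") if t not in spec.options]
        if bad:
            return [issue("option_violation",
                          f"tokens not in allowed options: {bad!r}")], raw
        return [], raw

    if spec.kind == "regex":
        if re.fullmatch(spec.pattern, raw) is None:
            return [issue("pattern_mismatch",
                          f"{raw!r} does not match pattern {spec.pattern!r}")], raw
        return [], raw

    if spec.kind == "dictionary":
        if store_context is None:
            raise ConfigurationError(
                "dictionary annotation requires a store context")
        parent_value = None
        if spec.parent_field is not None:
            parent_value = row_context.get(spec.parent_field) or None
        allowed = store_context.dictionary_values(spec.dictionary_name,
                                                  parent_value)
        if raw not in allowed:
            scope = (f" under {spec.parent_field}={parent_value!r}"
                     if spec.parent_field else "")
            return [issue("dictionary_violation",
                          f"{raw!r} not in dictionary "
                          f"{spec.dictionary_name!r}{scope}")], raw
        return [], raw

    raise ValueError(f"unhandled spec kind {spec.kind!r}")
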