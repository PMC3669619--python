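"""Minimal JSON-Schema-subset validator for the shipped response schemas.

Covers exactly the keywords the schemas in ``phylotastic/schemas`` use:
``type``, ``properties``, ``required``, ``items``, ``enum``,
``minimum``/``maximum`` and ``additionalProperties`` (boolean form).
"""

from __future__ import annotations

import json
from importlib import resources

__all__ = ["SchemaError", "validate", "load_schema"]

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "null": type(None),
}


class SchemaError(ValueError):
    pass


def load_schema(name: str) -> dict:
    """Load a schema shipped in ``phylotastic/schemas`` by file name."""
    ref = resources.files("phylotastic").joinpath("schemas", name)
    return json.loads(ref.read_text())


def _check_type(instance, expected: str, path: str) -> None:
    if expected == "number":
        ok = isinstance(instance, (int, float)) and not isinstance(instance, bool)
    elif expected == "integer":
        ok = isinstance(instance, int) and not isinstance(instance, bool)
    else:
        ok = isinstance(instance, _TYPES[expected])
    if not ok:
        raise SchemaError(f"{path}: expected {expected}, "
                          f"got {type(instance).__name__}")


def validate(instance, schema: dict, path: str = "$") -> None:
    """Raise :class:`SchemaError` if ``instance`` violates ``schema``."""
    stype = schema.get("type")
    if stype is not None:
        types = stype if isinstance(stype, list) else [stype]
        err = None
        for t in types:
            try:
                _check_type(instance, t, path)
                err = None
                break
            except SchemaError as exc:
                err = exc
        if err is not None:
            raise err
    if "enum" in schema and instance not in schema["enum"]:
        raise SchemaError(f"{path}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise SchemaError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, value in instance.items():
            if key in props:
                validate(value, props[key], f"{path}.{key}")
            elif schema.get("additionalProperties") is False:
                raise SchemaError(f"{path}: unexpected key {key!r}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            validate(item, schema["items"], f"{path}[{i}]")
    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            raise SchemaError(f"{path}: {instance} < minimum {schema['minimum']}")
        if "maximum" in schema and instance > schema["maximum"]:
            raise SchemaError(f"{path}: {instance} > maximum {schema['maximum']}")
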