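"""Load group and synapse definitions from YAML/JSON config.

A group definition is a mapping with keys ``N``, ``model``, and optionally
``threshold``, ``reset``, ``refractory``, ``method`` and ``namespace``.
Namespace values are unit-expression strings (``"20*ms"``), numbers, or
nested ``{value, unit}`` mappings; ``refractory`` is a unit-expression
string.  Example::

    N: 10
    model: |
      dv/dt = (v0 - v)/tau : volt
    threshold: v > -50*mV
    reset: v = -60*mV
    refractory: 5*ms
    namespace:
      tau: 20*ms
      v0: -40*mV
"""

from __future__ import annotations

import json
import pathlib

import yaml

from .groups import NeuronGroup
from .units import parse_unit_expression

__all__ = ["load_group", "group_from_dict"]


def _coerce(value):
    if isinstance(value, str):
        return parse_unit_expression(value)
    if isinstance(value, dict) and "value" in value:
        return value["value"] * parse_unit_expression(value.get("unit", "1"))
    return value


def group_from_dict(spec, extra_namespace=None):
    """Build a NeuronGroup from a decoded config mapping."""
    spec = dict(spec)
    namespace = {k: _coerce(v) for k, v in (spec.get("namespace") or {}).items()}
    namespace.update(extra_namespace or {})
    refractory = spec.get("refractory")
    if isinstance(refractory, str):
        refractory = parse_unit_expression(refractory)
    return NeuronGroup(
        spec["N"], spec["model"],
        threshold=spec.get("threshold"), reset=spec.get("reset"),
        refractory=refractory, method=spec.get("method"),
        namespace=namespace, name=spec.get("name"))


def load_group(path, extra_namespace=None):
    """Read one group definition from a YAML (or JSON) file."""
    text = pathlib.Path(path).read_text()
    spec = json.loads(text) if str(path).endswith(".json") \
        else yaml.safe_load(text)
    return group_from_dict(spec, extra_namespace)
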