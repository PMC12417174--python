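"""JSON round-trip for result/report objects.

Every report dataclass in the package registers itself here so that
``save_report``/``load_report`` can serialize any of them with a type tag,
turning NumPy arrays into lists and back.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Callable, Type

import numpy as np

__all__ = ["register_report", "save_report", "load_report"]

_REGISTRY: dict[str, Type] = {}


def register_report(cls: Type) -> Type:
    """Class decorator: make a dataclass (de)serializable by name."""
    _REGISTRY[cls.__name__] = cls
    return cls


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        name = type(obj).__name__
        payload = {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if name in _REGISTRY:
            return {"__report__": name, "fields": payload}
        return payload
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        if "__report__" in obj:
            cls = _REGISTRY[obj["__report__"]]
            fields = {k: _from_jsonable(v) for k, v in obj["fields"].items()}
            return cls(**fields)
        return {k: _from_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj


def save_report(report: Any, path: str | Path) -> None:
    """Serialize a registered report dataclass to JSON."""
    Path(path).write_text(json.dumps(_to_jsonable(report), indent=2))


def load_report(path: str | Path) -> Any:
    """Reconstruct a report previously written by :func:`save_report`."""
    return _from_jsonable(json.loads(Path(path).read_text()))
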