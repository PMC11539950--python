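"""Result serialization: everything a run produces goes to JSON with a
schema version and a config echo sufficient to replay it."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

SCHEMA_VERSION = 1


def _plain(obj):
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return obj
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_plain(v) for v in obj]
    return str(obj)


def result_to_json(result, config: dict | None = None) -> dict:
    """Dataclass/dict result -> JSON-ready dict (stable key order)."""
    body = _plain(result)
    out = {"schema_version": SCHEMA_VERSION}
    if config is not None:
        out["config"] = _plain(config)
    out["result"] = body
    return out


def write_result(result, path, config: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(result_to_json(result, config), fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
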