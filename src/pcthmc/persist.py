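"""Model persistence: versioned, self-describing JSON model files.

A model file embeds everything needed to reproduce predictions: the class
hierarchy with its vector ordering, the induction parameters (including
the seed), the attribute declarations and the tree(s).  Serialization is
canonical (sorted keys, fixed separators), so identical models produce
byte-identical files.
"""

from __future__ import annotations

import json
import os
import tempfile

from .ensemble import EnsembleModel
from .pct import PCTree

__all__ = ["save_model", "load_model"]


def save_model(model: PCTree | EnsembleModel, path) -> None:
    """Atomically write a model file (never leaves a partial file)."""
    text = model.to_json()
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "wt", encoding="utf-8") as fh:
            fh.write(text)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_model(path) -> PCTree | EnsembleModel:
    with open(path, "rt", encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("format") != "pcthmc-model":
        raise ValueError(f"{path}: not a model file")
    kind = obj.get("kind")
    if kind == "pct":
        return PCTree.from_dict(obj)
    if kind == "ensemble":
        return EnsembleModel.from_dict(obj)
    raise ValueError(f"{path}: unknown model kind {kind!r}")
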