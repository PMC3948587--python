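"""Structured output helpers: JSON records and TSV tables."""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["write_tsv", "equilibrium_to_dict", "dump_json"]


def write_tsv(
    path, header: Sequence[str], rows: Iterable[Sequence], fmt: str = "{:.10g}"
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            cells = []
            for v in row:
                if isinstance(v, str):
                    cells.append(v)
                elif v is None:
                    cells.append("NA")
                else:
                    cells.append(fmt.format(float(v)))
            fh.write("\t".join(cells) + "\n")


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float):
        if math.isnan(v):
            return None
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
    return v


def equilibrium_to_dict(rec) -> dict:
    d = {
        "label": rec.label,
        "coordinates": rec.y.tolist(),
        "admissible": rec.admissible,
        "source": rec.source,
    }
    if rec.stability is not None:
        d["stability"] = {
            "classification": rec.stability.classification,
            "leading_real_part": _jsonable(rec.stability.leading_real_part),
        }
    return d


def dump_json(obj, path) -> None:
    def default(v):
        out = _jsonable(v)
        if out is v and not isinstance(v, (dict, list, str, int, float, bool, type(None))):
            return str(v)
        return out

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
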