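"""Small shared helpers: reporting-grade rounding and hashing."""

from __future__ import annotations

import hashlib
import json
import math
from typing import Any


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Dollar and CO2e figures in reports use commercial rounding, not
    banker's rounding.  A tiny pre-round at 1e-6 guards against binary
    representation error flipping an exact .5 tie.
    """
    x = round(x, 6)
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def sha256_of_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_of_obj(obj: Any) -> str:
    """Stable hash of a JSON-serialisable object (sorted keys)."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()
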