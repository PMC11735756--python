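"""Small shared helpers: deterministic seed fan-out and config hashing."""

from __future__ import annotations

import hashlib
import json
from typing import Any


def child_seed(root_seed: int, *names: Any) -> int:
    """Derive a child seed deterministically from a root seed and a name path.

    Child seeds for different stages/recordings are statistically independent
    (SHA-256 based) and reproducible. The result is always < 2**31 so it can
    seed any RNG backend.
    """
    key = "/".join([str(int(root_seed))] + [str(n) for n in names])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:12]
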