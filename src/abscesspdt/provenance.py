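"""Deterministic provenance helpers: config hashing and per-task seeds."""

from __future__ import annotations

import hashlib
import json

__all__ = ["config_hash", "task_seed"]


def config_hash(obj) -> str:
    """Stable SHA-256 hex digest of a JSON-serializable object.

    Keys are sorted so the hash is invariant under dict key reordering.
    """
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def task_seed(master_seed: int, *key_parts) -> int:
    """Per-task RNG seed derived by stable hashing of (master seed, task key).

    Adding grid cells to a sweep never perturbs the seeds of existing cells.
    Result is a non-negative int below 2^31.
    """
    payload = json.dumps([int(master_seed), *[str(p) for p in key_parts]],
                         separators=(",", ":"))
    digest = hashlib.sha256(payload.encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
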