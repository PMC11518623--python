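"""Deterministic seed derivation.

A single pipeline-level seed deterministically derives per-stage seeds, so
every stage is independently reproducible.  Derivation: SHA-256 over the
root seed and a tuple of string/int tags, truncated to 31 bits (numpy
Generator accepts it, and it stays below 2**31 for portability).
"""
from __future__ import annotations

import hashlib


def derive_seed(root: int, *tags: object) -> int:
    """Derive a child seed from ``root`` and a sequence of hashable tags.

    Stable across processes and platforms (unlike ``hash``).
    """
    h = hashlib.sha256()
    h.update(str(int(root)).encode())
    for t in tags:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
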