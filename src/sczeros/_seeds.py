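"""Deterministic seed derivation for per-condition random streams."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a child seed < 2**31 from a master seed and hashable tokens.

    Stable across processes and Python versions (sha256 of the repr tuple,
    not the builtin ``hash``).
    """
    key = repr((int(master_seed),) + tuple(tokens)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
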