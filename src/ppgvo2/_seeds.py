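"""Seed fan-out: one run seed derives independent per-stage seeds."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, label: str) -> int:
    """Stable sub-seed for a named pipeline stage, below 2**31."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
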