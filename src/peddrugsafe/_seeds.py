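"""Deterministic per-stage seed derivation from a single pipeline seed."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *names) -> int:
    """Stable sub-seed from (seed, names); always < 2**31."""
    tag = ":".join([str(int(seed))] + [str(n) for n in names])
    digest = hashlib.blake2b(tag.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
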