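"""Deterministic seed derivation.

Every stream of randomness in the package (cohort sampling, phantom rendering,
batch shuffling, dropout masks, travel schedules) is seeded through this one
hash so that runs are reproducible across platforms and so that independent
streams (e.g. two centers sharing a master seed) do not collide.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31  # keep derived seeds in the positive int32 range


def derive_seed(*parts: object) -> int:
    """Map an arbitrary tuple of hashable labels to a stable 31-bit seed.

    The labels are rendered with ``str`` and joined with ``"|"`` before being
    fed through SHA-256; the first four bytes of the digest (big endian) are
    reduced modulo 2**31.  The function is pure: the same labels always give
    the same seed, on any platform.
    """
    key = "|".join(str(p) for p in parts).encode("utf-8")
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % _MOD
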