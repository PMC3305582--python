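"""Stable, platform-independent seed derivation.

Every source of randomness in the toolkit is seeded from a single master
seed.  Per-locus / per-stage seeds are derived by hashing the master seed
together with a string label (e.g. a variant id), so that subsetting the
SNP set or rerunning a single stage never changes any other result.
"""

from __future__ import annotations

import hashlib

_MOD = 2**31  # keep derived seeds comfortably below 2**31


def derive_seed(master: int, *labels) -> int:
    """Derive a child seed from ``master`` and any number of string-able labels.

    Uses SHA-256 so the mapping is stable across Python versions and
    platforms (``hash()`` is salted and unsuitable).
    """
    key = ":".join([str(int(master))] + [str(l) for l in labels])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little") % _MOD
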