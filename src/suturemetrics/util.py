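"""Seed bookkeeping: one master seed deterministically labels every stage."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, label: str) -> int:
    """Stable per-stage seed derived from a master seed and a stage label.

    Uses SHA-256 of ``"<master>:<label>"`` truncated to 31 bits, so any
    master seed yields valid seeds for numpy, scikit-learn and xgboost and
    the derivation is identical across platforms and runs.
    """
    digest = hashlib.sha256(f"{int(master)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
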