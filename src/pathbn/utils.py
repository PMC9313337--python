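"""Seed derivation: every random draw flows from one master seed."""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *labels) -> int:
    """Stable child seed (< 2**31) from a master seed and a label path."""
    text = f"{master}|" + "|".join(str(x) for x in labels)
    digest = hashlib.sha256(text.encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)
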