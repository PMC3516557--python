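"""Deterministic derivation of per-stage child seeds from one master seed.

One user-facing seed fans out to independent generator seeds so that any
stage (universe, screen, interactions, gene sets, annotations, null lists)
can be regenerated on its own and still match a full-pipeline run.  The
derivation hashes ``"<seed>|<label>|<label>..."`` with SHA-256 and keeps the
top 31 bits, so child seeds are stable across platforms and Python versions
and always fit a signed 32-bit integer.
"""

import hashlib

__all__ = ["child_seed"]


def child_seed(seed: int, *labels: str) -> int:
    """Derive a reproducible child seed for the stage identified by *labels*."""
    payload = "|".join([str(int(seed)), *labels]).encode("utf-8")
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
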