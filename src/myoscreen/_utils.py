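"""Small shared helpers: error types, seed derivation, file digests."""

from __future__ import annotations

import hashlib
from pathlib import Path


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class MissingDataError(ValueError):
    """An operation met missing values its contract forbids."""


class SchemaError(ValueError):
    """Feature columns do not match the schema a model was trained on."""


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed from a master seed.

    Stable across runs and platforms (sha256 of ``"<seed>:<stage>"``),
    bounded below 2**31 so it is a valid seed everywhere.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
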