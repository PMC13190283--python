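"""Shared fixtures: deterministic seeds derived without Python's salted hash."""

import zlib

import pytest

from g2lhe.synthetic import PRESETS


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from string/int parts (run-stable)."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@pytest.fixture(scope="session")
def preset_names():
    return sorted(PRESETS)
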