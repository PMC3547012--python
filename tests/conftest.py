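from __future__ import annotations

import numpy as np
import pytest

from mtsnip.io import LabelledAlignment, SampleRecord


def make_alignment(
    seqs: dict[str, str],
    species: dict[str, str] | None = None,
    localities: dict[str, str] | None = None,
    coords: dict[str, tuple[float, float]] | None = None,
    reference_id: str | None = None,
) -> LabelledAlignment:
    """Build a LabelledAlignment with minimal metadata for tests."""
    metadata = []
    for sid in seqs:
        lat = lon = None
        if coords and sid in coords:
            lat, lon = coords[sid]
        metadata.append(
            SampleRecord(
                sample_id=sid,
                species=(species or {}).get(sid, "spX"),
                locality_name=(localities or {}).get(sid, ""),
                lat=lat,
                lon=lon,
            )
        )
    return LabelledAlignment(sequences=seqs, metadata=metadata, reference_id=reference_id)


def random_sequences(rng: np.random.Generator, n: int, length: int, alphabet: str = "ACGT-") -> list[str]:
    symbols = np.array(list(alphabet))
    return ["".join(symbols[rng.integers(0, len(symbols), size=length)]) for _ in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
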