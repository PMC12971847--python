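"""Scoring of the two subjective instruments collected after each trial.

SUS (System Usability Scale): ten statements rated 1-5, alternating positive
(odd) and negative (even) wording.  Odd items contribute ``raw - 1``, even
items ``5 - raw``; the sum of the ten adjusted contributions times 2.5 gives
a 0-100 usability score, banded as low (< 50), moderate (50-69), good
(70-89) or excellent (90-100).  Because scores live on a grid of multiples
of 2.5, the band edges are unambiguous.

NASA-TLX: six workload dimensions each rated on a 10-point scale and
categorised per dimension as low (1-3), moderate (4-6) or high (7-10).  No
composite or pairwise-weighted TLX score is computed — the raw-rating,
per-dimension categorisation is the instrument as administered here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InputError

__all__ = [
    "SusResponse",
    "TlxResponse",
    "TLX_DIMENSIONS",
    "score_sus",
    "sus_band",
    "categorize_tlx",
]

TLX_DIMENSIONS = ("mental", "physical", "temporal", "performance", "effort", "frustration")


@dataclass(frozen=True)
class SusResponse:
    """Ten SUS item ratings, item 1 first, each an integer in 1..5."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise InputError(f"SUS requires exactly 10 items, got {len(self.items)}")
        for idx, v in enumerate(self.items, start=1):
            if not (isinstance(v, int) and 1 <= v <= 5):
                raise InputError(f"SUS item {idx} must be an integer in 1..5, got {v!r}")


@dataclass(frozen=True)
class TlxResponse:
    """Six NASA-TLX dimension ratings, each an integer in 1..10."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 6:
            raise InputError(f"NASA-TLX requires exactly 6 items, got {len(self.items)}")
        for dim, v in zip(TLX_DIMENSIONS, self.items):
            if not (isinstance(v, int) and 1 <= v <= 10):
                raise InputError(f"TLX item {dim!r} must be an integer in 1..10, got {v!r}")


def sus_band(score: float) -> str:
    if score < 50:
        return "low"
    if score < 70:
        return "moderate"
    if score < 90:
        return "good"
    return "excellent"


def score_sus(r: SusResponse | Sequence[int]) -> tuple[float, str]:
    """SUS usability score in [0, 100] and its qualitative band."""
    if not isinstance(r, SusResponse):
        r = SusResponse(tuple(r))
    adjusted = sum(
        (v - 1) if idx % 2 == 1 else (5 - v) for idx, v in enumerate(r.items, start=1)
    )
    score = 2.5 * adjusted
    return score, sus_band(score)


def categorize_tlx(r: TlxResponse | Sequence[int]) -> dict[str, str]:
    """Per-dimension workload band: low (1-3), moderate (4-6), high (7-10)."""
    if not isinstance(r, TlxResponse):
        r = TlxResponse(tuple(r))
    out = {}
    for dim, v in zip(TLX_DIMENSIONS, r.items):
        out[dim] = "low" if v <= 3 else ("moderate" if v <= 6 else "high")
    return out
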