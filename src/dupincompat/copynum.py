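"""Read-depth copy-number estimation and carrier calling.

Copy number of a duplicated gene is estimated from the ratio between the
average mapping coverage within the focal region and the genome-wide
average coverage, against a reference carrying a known number of copies of
the family (for a single-copy reference the ratio is the copy number
directly; for a two-copy family measured over the union of both reference
copies, the baseline is 2). Presence of a non-reference copy is called when
the mean depth over its region, on the assembly that carries it, reaches a
threshold (default >= 5x, inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "normalized_coverage",
    "call_presence",
    "estimate_copies",
    "copy_number_table",
]


@dataclass
class CoverageTrack:
    """Per-base depth over one region (BED convention, 0-based half-open)
    plus the genome-wide mean depth used for normalization."""

    chrom: str
    start: int
    end: int
    depths: np.ndarray
    genome_mean_depth: float

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.end - self.start != len(self.depths):
            raise ValueError("depths length must equal region length")
        if len(self.depths) == 0:
            raise ValueError("empty region")
        if np.any(self.depths < 0):
            raise ValueError("negative depth")

    @property
    def mean_depth(self) -> float:
        return float(self.depths.mean())


def normalized_coverage(track: CoverageTrack) -> float:
    """Mean regional depth divided by genome-wide mean depth."""
    if track.genome_mean_depth <= 0:
        raise ValueError("genome-wide mean depth must be positive")
    return track.mean_depth / track.genome_mean_depth


def call_presence(track: CoverageTrack, min_mean_depth: float = 5.0) -> bool:
    """Carrier call: mean depth >= threshold (inclusive)."""
    return track.mean_depth >= min_mean_depth


def estimate_copies(ratio: float, baseline_copies_in_reference: int = 1) -> int:
    """Integer copy number: ratio x baseline, rounded to nearest (ties to
    even)."""
    if baseline_copies_in_reference < 1:
        raise ValueError("baseline must be >= 1")
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    return int(np.rint(ratio * baseline_copies_in_reference))


def copy_number_table(
    tracks: Mapping[str, CoverageTrack],
    baseline_copies_in_reference: int = 1,
    min_mean_depth: float = 5.0,
) -> pd.DataFrame:
    """Per-accession copy-number summary (region, ratio, copies, carrier)."""
    rows = []
    for accession, track in tracks.items():
        ratio = normalized_coverage(track)
        rows.append(
            {
                "accession": accession,
                "region": f"{track.chrom}:{track.start}-{track.end}",
                "ratio": ratio,
                "copies": estimate_copies(ratio, baseline_copies_in_reference),
                "carrier": call_presence(track, min_mean_depth),
            }
        )
    return pd.DataFrame(rows).set_index("accession")
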