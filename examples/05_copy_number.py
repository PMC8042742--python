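"""Estimate gene copy number from coverage ratios and call carriers.

Simulates per-base read depths over a gene region mapped against a
single-copy reference for accessions with 1-3 total family copies, computes
normalized coverage (region mean / genome-wide mean), rounds to integer
copies, and applies the inclusive >= 5x carrier threshold.
"""

import numpy as np

from dupincompat import CoverageTrack, call_presence, estimate_copies, normalized_coverage
from dupincompat.copynum import copy_number_table


def main():
    rng = np.random.default_rng(4)
    depth = 30.0
    tracks = {}
    truth = {}
    for i in range(9):
        copies = 1 + i % 3
        truth[f"acc{i}"] = copies
        tracks[f"acc{i}"] = CoverageTrack(
            "gene_region", 0, 2000,
            rng.poisson(depth * copies, 2000).astype(float), depth,
        )
    table = copy_number_table(tracks, baseline_copies_in_reference=1)
    table["truth"] = [truth[a] for a in table.index]
    print(table.round(3).to_string())

    shallow = CoverageTrack("hpa3_region", 0, 500, np.full(500, 4.9), depth)
    print(
        f"\nnon-reference copy at mean depth 4.9x -> carrier = "
        f"{call_presence(shallow)} (threshold 5.0x, inclusive)"
    )
    print(
        "\nThe ratio column is regional mean depth over genome-wide mean; at\n"
        "30x it recovers the simulated integer copy number essentially always."
    )


if __name__ == "__main__":
    main()
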