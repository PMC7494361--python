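"""Per-base fragment-coverage tracks.

A :class:`CoverageTrack` holds one dense non-negative array per chromosome
(fragment coverage per base, or per fixed bin) plus an optional strand tag.
bedGraph is the canonical text interchange; gaps between records fill with 0.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoverageTrack", "read_bedgraph", "write_bedgraph"]


@dataclass
class CoverageTrack:
    """Dense per-base coverage, one array per chromosome.

    Parameters
    ----------
    data : dict
        Mapping chromosome name -> 1-D float array of coverage per base.
    strand : str
        "+", "-" or "." (unstranded).
    """

    data: dict[str, np.ndarray] = field(default_factory=dict)
    strand: str = "."

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    @property
    def total(self) -> float:
        """Total coverage C: the sum over every base of every chromosome."""
        return float(sum(arr.sum() for arr in self.data.values()))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom])

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Coverage summed over [start, end); out-of-range bases count 0."""
        arr = self.data[chrom]
        lo, hi = max(start, 0), min(end, len(arr))
        if hi <= lo:
            return 0.0
        return float(arr[lo:hi].sum())

    def values_at(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end), 0-filled outside the chromosome."""
        arr = self.data[chrom] if chrom in self.data else np.empty(0)
        out = np.zeros(end - start, dtype=float)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: a * factor for c, a in self.data.items()}, strand=self.strand
        )


def read_bedgraph(path, chrom_lengths: dict[str, int] | None = None,
                  strand: str = ".") -> CoverageTrack:
    """Read a 4-column bedGraph into a dense per-base track.

    Uncovered positions fill with 0.  If ``chrom_lengths`` is omitted the
    length of each chromosome is the largest end coordinate seen.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise ValueError(f"{path}:{i}: negative coverage value {value}")
            if end < start:
                raise ValueError(f"{path}:{i}: end < start")
            records.setdefault(chrom, []).append((start, end, value))
    data = {}
    for chrom, recs in records.items():
        length = (chrom_lengths or {}).get(chrom, max(e for _, e, _ in recs))
        arr = np.zeros(length, dtype=float)
        for start, end, value in recs:
            arr[start:min(end, length)] = value
        data[chrom] = arr
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            data.setdefault(chrom, np.zeros(length, dtype=float))
    return CoverageTrack(data, strand=strand)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write run-length-collapsed bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes:
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            # boundaries of constant runs
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
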