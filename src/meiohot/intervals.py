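"""BED/TSV interval handling. All coordinates 0-based half-open."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["read_intervals", "write_bed", "sort_intervals",
           "overlaps_any", "overlap_lengths"]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def read_intervals(path, fmt: str = "BED") -> pd.DataFrame:
    """Read BED (whitespace, no header) or TSV (header) intervals, sorted.

    Raises ValueError naming the offending line on malformed input.
    """
    if fmt.upper() == "TSV":
        df = pd.read_csv(path, sep="\t")
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"{path}: TSV intervals need a '{col}' column")
    elif fmt.upper() == "BED":
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{i}: expected >=3 BED columns")
                try:
                    row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
                except ValueError as err:
                    raise ValueError(f"{path}:{i}: {err}") from None
                for name, val in zip(_BED_COLS[3:], parts[3:]):
                    row[name] = val
                rows.append(row)
        df = pd.DataFrame(rows, columns=[c for c in _BED_COLS if rows and c in rows[0]])
    else:
        raise ValueError(f"unknown interval format {fmt!r}")
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: interval with end < start")
    return sort_intervals(df)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in _BED_COLS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def _per_chrom(features: pd.DataFrame):
    out = {}
    for chrom, grp in features.groupby("chrom"):
        grp = grp.sort_values("start")
        out[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def overlaps_any(query: pd.DataFrame, features: pd.DataFrame,
                 min_overlap: int = 1) -> np.ndarray:
    """Boolean per query interval: overlaps some feature by >= min_overlap bp."""
    return overlap_lengths(query, features) >= min_overlap


def overlap_lengths(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Maximum single-feature overlap length (bp) for each query interval."""
    idx = _per_chrom(features)
    out = np.zeros(len(query), dtype=int)
    for i, (chrom, qs, qe) in enumerate(
            zip(query["chrom"].to_numpy(), query["start"].to_numpy(),
                query["end"].to_numpy())):
        if chrom not in idx:
            continue
        starts, ends = idx[chrom]
        # features sorted by start; candidates are those starting before qe
        hi = np.searchsorted(starts, qe)
        if hi == 0:
            continue
        ov = np.minimum(ends[:hi], qe) - np.maximum(starts[:hi], qs)
        if len(ov):
            best = ov.max()
            if best > 0:
                out[i] = best
    return out
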