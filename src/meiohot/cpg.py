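"""CpG counting, methylation classification and CpG-dependence curves.

CpG dinucleotides are counted on the forward strand only: "CG" is its own
reverse complement, so each genomic CpG site is counted exactly once.
Methylation classes come from bisulfite read ratios summed over the two
strands of a site; high-copy-number sites are removed before classifying.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import overlap_lengths, overlaps_any

__all__ = [
    "count_cpgs", "filter_alu_like", "classify_methylation",
    "window_features", "overlap_vs_cpg_curve", "peak_cpg_composition",
]


def count_cpgs(sequence: str) -> int:
    """Number of CG dinucleotides (forward strand; N never matches)."""
    return sequence.upper().count("CG")


def count_cpgs_in_intervals(intervals: pd.DataFrame,
                            genome: dict[str, str]) -> np.ndarray:
    """CpG count per interval, from chromosome sequences."""
    return np.array([
        count_cpgs(genome[c][s:e])
        for c, s, e in zip(intervals["chrom"], intervals["start"], intervals["end"])
    ])


def filter_alu_like(repeats: pd.DataFrame, repeat_class: str = "Alu",
                    min_width: int = 250, max_width: int = 350) -> pd.DataFrame:
    """Retain repeats of the target class with width in [250, 350] bp
    (the canonical full-length Alu/B1 size range)."""
    width = repeats["end"] - repeats["start"]
    keep = (width >= min_width) & (width <= max_width)
    if "name" in repeats.columns:
        keep &= repeats["name"].astype(str).str.contains(repeat_class)
    return repeats[keep].reset_index(drop=True)


def classify_methylation(records: pd.DataFrame,
                         meth_threshold: float = 0.75,
                         unmeth_threshold: float = 0.25,
                         copy_number_max: float = 1.5) -> pd.DataFrame:
    """Classify CpG sites from bisulfite counts.

    Expects columns chrom, pos, meth_reads, unmeth_reads and optionally
    strand, copy_number, context.  Processing order: non-CpG-context rows
    are dropped, the two strands of each site are summed, sites with copy
    number > 1.5 are removed, zero-coverage sites are dropped, then the
    methylated/unmethylated ratio thresholds (strict > and <) are applied;
    everything between is ambiguous.
    """
    df = records.copy()
    if "context" in df.columns:
        df = df[df["context"].str.upper() == "CPG"]
    agg = {"meth_reads": "sum", "unmeth_reads": "sum"}
    if "copy_number" in df.columns:
        agg["copy_number"] = "max"
    df = df.groupby(["chrom", "pos"], as_index=False).agg(agg)
    if "copy_number" in df.columns:
        df = df[df["copy_number"] <= copy_number_max]
    total = df["meth_reads"] + df["unmeth_reads"]
    df = df[total > 0].copy()
    df["ratio"] = df["meth_reads"] / (df["meth_reads"] + df["unmeth_reads"])
    df["meth_class"] = np.select(
        [df["ratio"] > meth_threshold, df["ratio"] < unmeth_threshold],
        ["methylated", "unmethylated"], default="ambiguous")
    return df.reset_index(drop=True)


def window_features(chrom_sizes: dict[str, int], genome: dict[str, str],
                    peaks: pd.DataFrame, excluded: pd.DataFrame,
                    methylation: pd.DataFrame | None = None,
                    window: int = 300, stride: int | None = None,
                    min_excl_overlap: int = 10) -> pd.DataFrame:
    """Tile the genome into windows and annotate CpG count, exclusion and
    peak overlap.

    Windows overlapping an excluded annotation (repeats, CpG islands) by
    >= ``min_excl_overlap`` bp are flagged; peak overlap is >= 1 bp.  If a
    methylation table is given, a window's methylation class is that of its
    majority classified CpG (windows without classified CpGs are "none").
    Default tiling is non-overlapping (stride = window).
    """
    stride = stride or window
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size - window + 1, stride):
            rows.append((chrom, start, start + window))
    wins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    wins["cpg_count"] = count_cpgs_in_intervals(wins, genome)
    wins["excluded"] = overlap_lengths(wins, excluded) >= min_excl_overlap if len(excluded) else False
    wins["overlaps_peak"] = overlaps_any(wins, peaks)
    wins["meth_class"] = "none"
    if methylation is not None and len(methylation):
        classified = methylation[methylation["meth_class"] != "ambiguous"]
        for chrom, grp in classified.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            is_meth = (grp["meth_class"] == "methylated").to_numpy()
            sel = wins["chrom"] == chrom
            for i in wins.index[sel]:
                lo, hi = np.searchsorted(pos, [wins.at[i, "start"], wins.at[i, "end"]])
                if hi > lo:
                    wins.at[i, "meth_class"] = (
                        "methylated" if is_meth[lo:hi].mean() > 0.5 else "unmethylated")
    return wins


def overlap_vs_cpg_curve(windows: pd.DataFrame,
                         by_class: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probability that a window overlaps a peak, as a function of its CpG
    count (and methylation class).

    Takes the output of :func:`window_features` with exclusions already
    applied upstream; excluded windows are dropped here as a guard.  Returns
    (curve, fit) where ``curve`` has the per-count overlap fraction and
    ``fit`` the logistic-regression coefficients per class.
    """
    import statsmodels.api as sm

    df = windows[~windows["excluded"]].copy()
    if len(df) == 0:
        raise ValueError("no eligible windows")
    group_cols = ["cpg_count"] + (["meth_class"] if by_class else [])
    curve = (df.groupby(group_cols)
               .agg(n=("overlaps_peak", "size"), frac_overlap=("overlaps_peak", "mean"))
               .reset_index())
    fits = []
    classes = df["meth_class"].unique() if by_class else ["all"]
    for cls in classes:
        sub = df if cls == "all" else df[df["meth_class"] == cls]
        if sub["overlaps_peak"].nunique() < 2 or sub["cpg_count"].nunique() < 2:
            continue
        X = sm.add_constant(sub["cpg_count"].to_numpy(dtype=float))
        res = sm.GLM(sub["overlaps_peak"].to_numpy(dtype=float), X,
                     family=sm.families.Binomial()).fit()
        fits.append({"meth_class": cls, "intercept": res.params[0],
                     "slope": res.params[1], "slope_se": res.bse[1]})
    return curve, pd.DataFrame(fits)


def peak_cpg_composition(peaks: pd.DataFrame, genome: dict[str, str],
                         flank: int = 150, n_bins: int = 5,
                         random_placements: pd.DataFrame | None = None,
                         max_cpg: int = 10) -> pd.DataFrame:
    """Distribution of CpG counts (+/- ``flank`` of peak center) within peaks
    binned by enrichment, optionally against random placements.

    Returns stacked proportions: per enrichment bin (and the "random" bin if
    placements are given), the fraction of peaks with each CpG count;
    counts above ``max_cpg`` pool into the top category.
    """
    from .chip import _equal_count_bins

    def composition(df: pd.DataFrame, label) -> pd.DataFrame:
        wins = pd.DataFrame({
            "chrom": df["chrom"],
            "start": (df["center"] - flank).clip(lower=0).astype(int),
            "end": (df["center"] + flank).astype(int),
        })
        counts = np.minimum(count_cpgs_in_intervals(wins, genome), max_cpg)
        out = (pd.Series(counts).value_counts(normalize=True).sort_index()
               .rename_axis("cpg_count").reset_index(name="proportion"))
        out.insert(0, "bin", label)
        return out

    bins = _equal_count_bins(peaks["enrichment"].to_numpy(dtype=float), n_bins)
    parts = [composition(peaks[bins == b], f"enrichment_bin_{b}")
             for b in range(n_bins)]
    if random_placements is not None and len(random_placements):
        parts.insert(0, composition(random_placements, "random"))
    return pd.concat(parts, ignore_index=True)
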