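"""Force-called ChIP enrichment, simplified peak calling, filtering,
aggregate profiles, heatmap matrices and binned overlap curves.

Enrichment semantics: for a window with IP count r, input (control) count g
and library totals C_r, C_g, the enrichment estimate is

    beta_hat = max(0, (r / C_r) / (g / C_g) - 1),

i.e. coverage attributable to signal, after subtracting coverage expected
from background, relative to background.  Any value greater than 0 is
enriched; values below 1 do not imply depletion.  Significance is an
upper-tail Poisson test of r against the background expectation
g * C_r / C_g.  This is a deliberately simple single-sample model; it keeps
the estimator's semantics while replacing the replicate-aware likelihood of
full peak callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .coverage import CoverageTrack
from .intervals import overlaps_any

__all__ = [
    "PeakSet", "ProfileMatrix", "force_call", "call_peaks", "filter_peaks",
    "dedup_nearby", "aggregate_profile", "heatmap_matrix", "random_peaks",
    "overlap_by_enrichment", "mark_vs_binding_curve",
]


@dataclass
class PeakSet:
    """Peak intervals plus per-peak statistics and filter provenance."""

    peaks: pd.DataFrame  # chrom, start, end, center, [strand, enrichment, p_value, likelihood, input_coverage]
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def with_filter(self, peaks: pd.DataFrame, note: str) -> "PeakSet":
        return PeakSet(peaks.reset_index(drop=True), self.provenance + [note])


@dataclass
class ProfileMatrix:
    """Regions x positions matrix of input-normalised ratios."""

    matrix: np.ndarray
    offsets: np.ndarray
    row_order: np.ndarray       # region indices, most to least central coverage
    aggregate: np.ndarray       # ratio-of-means profile over ordered rows
    bin_width: int
    flank: int


def _poisson_calls(r, g, c_r, c_g):
    """Vectorised enrichment/p/LLR given window counts and totals.

    The p-value is the exact conditional (binomial) upper-tail test for
    comparing two Poisson rates: given the window total r + g, under the
    null r ~ Binomial(r + g, C_r / (C_r + C_g)).  Conditioning on the total
    keeps the test calibrated when the control is itself a noisy count of
    depth comparable to the IP; a plug-in Poisson test treating g as a known
    mean is anti-conservative in exactly that regime.  The likelihood-ratio
    statistic retains the one-sided Poisson form against the plug-in
    background mean.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    mu = g * (c_r / c_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(g > 0, np.maximum(0.0, (r / c_r) / (g / c_g) - 1.0), 0.0)
    q = c_r / (c_r + c_g)
    n = np.maximum(r + g, 1).astype(int)
    # mid-p: count half the probability of the observed value.  The exact
    # discrete tail is super-uniform (conservative); mid-p restores mean 0.5
    # and near-uniform calibration without hand-tuned corrections.
    p = stats.binom.sf(r, n, q) + 0.5 * stats.binom.pmf(r, n, q)
    p = np.where(r + g == 0, 1.0, p)
    p = np.where(r == 0, 1.0, p)  # r = 0 can never evidence enrichment
    with np.errstate(divide="ignore", invalid="ignore"):
        llr = np.where((r > mu) & (mu > 0), r * np.log(r / mu) - (r - mu), 0.0)
    return beta, np.clip(p, 0.0, 1.0), llr


def force_call(ip: CoverageTrack, control: CoverageTrack,
               windows: pd.DataFrame) -> pd.DataFrame:
    """Enrichment and p-values at pre-specified windows.

    ``windows`` needs chrom/start/end columns. Windows with zero input
    coverage are flagged ``informative=False`` and should be excluded
    downstream (mirrors the input-coverage filters).
    """
    c_r, c_g = ip.total, control.total
    if c_r <= 0 or c_g <= 0:
        raise ValueError("IP and control totals must be positive")
    r = np.array([ip.window_sum(c, s, e)
                  for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])])
    g = np.array([control.window_sum(c, s, e)
                  for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])])
    beta, p, llr = _poisson_calls(r, g, c_r, c_g)
    out = windows[["chrom", "start", "end"]].copy().reset_index(drop=True)
    out["ip_count"] = r
    out["input_count"] = g
    out["enrichment"] = beta
    out["p_value"] = p
    out["likelihood"] = llr
    out["informative"] = g > 0
    return out


def call_peaks(ip: CoverageTrack, control: CoverageTrack,
               pthresh: float = 1e-6, peakminsep: int = 250,
               window_halfwidth: int = 50, chroms=None) -> PeakSet:
    """Single-base peak calling.

    At every base the IP and control coverage are summed over a centred
    window (2 * window_halfwidth + 1 bp) and tested as in :func:`force_call`.
    Bases with p < pthresh are retained greedily by significance (ties
    broken leftmost), suppressing neighbours within ``peakminsep``.
    """
    c_r, c_g = ip.total, control.total
    if c_r <= 0 or c_g <= 0:
        raise ValueError("IP and control totals must be positive")
    width = 2 * window_halfwidth + 1
    rows = []
    for chrom in (chroms or ip.chromosomes):
        ipa = ip.data[chrom]
        ctl = control.values_at(chrom, 0, len(ipa))
        r = uniform_filter1d(ipa, width, mode="constant") * width
        g = uniform_filter1d(ctl, width, mode="constant") * width
        beta, p, llr = _poisson_calls(r, g, c_r, c_g)
        cand = np.flatnonzero(p < pthresh)
        if len(cand) == 0:
            continue
        # greedy by significance, leftmost on ties
        order = cand[np.lexsort((cand, p[cand]))]
        kept: list[int] = []
        taken = np.zeros(len(ipa), dtype=bool)
        for pos in order:
            if not taken[pos]:
                kept.append(pos)
                lo, hi = max(0, pos - peakminsep), min(len(ipa), pos + peakminsep + 1)
                taken[lo:hi] = True
        for pos in sorted(kept):
            rows.append((chrom, pos, pos + 1, pos, beta[pos], p[pos], llr[pos], g[pos]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "center",
                                     "enrichment", "p_value", "likelihood",
                                     "input_coverage"])
    return PeakSet(df, [f"call_peaks(pthresh={pthresh}, peakminsep={peakminsep})"])


def filter_peaks(peaks: PeakSet, promoter_marks: pd.DataFrame | None = None,
                 promoter_dist: int = 2500, min_input: float = 5,
                 drop_top_likelihood: int = 5,
                 input_quantile: float = 0.999) -> PeakSet:
    """Remove promoter-proximal, low-input, top-likelihood and extreme-input
    peaks.

    Filters, in order: center strictly within ``promoter_dist`` of a
    promoter-mark center (PRDM9-independent H3K4me3); input coverage
    <= ``min_input``; the top ``drop_top_likelihood`` peaks by likelihood;
    input coverage above its ``input_quantile`` quantile.  Distance
    boundaries are exclusive ("within 2.5 kb" means < 2500).
    """
    df = peaks.peaks.copy()
    notes = []
    if promoter_marks is not None and len(promoter_marks) and len(df):
        keep = np.ones(len(df), dtype=bool)
        centers = {c: np.sort(g["center"].to_numpy())
                   for c, g in promoter_marks.groupby("chrom")}
        for i, (chrom, center) in enumerate(zip(df["chrom"], df["center"])):
            if chrom not in centers:
                continue
            pc = centers[chrom]
            j = np.searchsorted(pc, center)
            near = min(
                abs(center - pc[j - 1]) if j > 0 else np.inf,
                abs(pc[j] - center) if j < len(pc) else np.inf,
            )
            keep[i] = near >= promoter_dist
        df = df[keep]
        notes.append(f"promoter_dist<{promoter_dist}: removed {int((~keep).sum())}")
    if "input_coverage" in df.columns and len(df):
        before = len(df)
        df = df[df["input_coverage"] > min_input]
        notes.append(f"input<= {min_input}: removed {before - len(df)}")
    if drop_top_likelihood and "likelihood" in df.columns and len(df):
        top = df["likelihood"].nlargest(drop_top_likelihood).index
        df = df.drop(index=top)
        notes.append(f"top {drop_top_likelihood} likelihood removed")
    if "input_coverage" in df.columns and len(df):
        cut = df["input_coverage"].quantile(input_quantile)
        before = len(df)
        df = df[df["input_coverage"] <= cut]
        notes.append(f"input>{input_quantile} quantile: removed {before - len(df)}")
    return peaks.with_filter(df, "; ".join(notes))


def dedup_nearby(peaks: PeakSet, min_sep: int = 4000) -> PeakSet:
    """Remove *both* members of any pair of peaks with centers within
    ``min_sep`` of one another (avoids double counting in profiles); chains
    of close peaks are removed transitively."""
    df = peaks.peaks.sort_values(["chrom", "center"]).reset_index(drop=True)
    drop = np.zeros(len(df), dtype=bool)
    for _, grp in df.groupby("chrom"):
        centers = grp["center"].to_numpy()
        close = np.diff(centers) < min_sep
        idx = grp.index.to_numpy()
        drop[idx[:-1]] |= close
        drop[idx[1:]] |= close
    return peaks.with_filter(df[~drop], f"dedup_nearby(<{min_sep}): removed {int(drop.sum())}")


def _region_matrix(track: CoverageTrack, regions: pd.DataFrame, flank: int) -> np.ndarray:
    """(n_regions, 2*flank+1) per-base values, minus-strand rows reversed,
    positions beyond the chromosome contributing 0."""
    width = 2 * flank + 1
    mat = np.zeros((len(regions), width))
    strands = regions["strand"] if "strand" in regions.columns else ["+"] * len(regions)
    for i, (chrom, center, strand) in enumerate(
            zip(regions["chrom"], regions["center"], strands)):
        vals = track.values_at(chrom, int(center) - flank, int(center) + flank + 1)
        mat[i] = vals[::-1] if strand == "-" else vals
    return mat


def aggregate_profile(ip: CoverageTrack, control: CoverageTrack,
                      regions: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Total-coverage-normalised mean IP over regions divided by the same for
    the control.

    Regions are centred (column ``center``) and optionally stranded;
    minus-strand regions are reversed before averaging, and positions
    falling off a chromosome fill with 0.
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    ip_mean = _region_matrix(ip, regions, flank).mean(axis=0) / ip.total
    ctl_mean = _region_matrix(control, regions, flank).mean(axis=0) / control.total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ctl_mean > 0, ip_mean / ctl_mean, np.nan)
    return pd.DataFrame({
        "offset": np.arange(-flank, flank + 1),
        "ip_norm": ip_mean,
        "control_norm": ctl_mean,
        "ratio": ratio,
    })


def heatmap_matrix(ip: CoverageTrack, control: CoverageTrack,
                   regions: pd.DataFrame, flank: int = 2000, bin: int = 5,
                   scale: float = 1e10,
                   quantiles: tuple[float, float] = (0.01, 0.99),
                   order_window: int = 200) -> ProfileMatrix:
    """Per-region input-normalised log-ready ratio matrix.

    Coverage is normalised by total coverage and scaled by 10^10, averaged
    into ``bin``-bp tiles, a pseudocount of 1 is added to both IP and input,
    the ratio is taken per region and values outside the 0.01-0.99 quantile
    range are thresholded.  Rows are ordered by mean IP coverage of the
    central ``order_window`` bp.
    """
    ipm = _region_matrix(ip, regions, flank)
    ctm = _region_matrix(control, regions, flank)
    width = ipm.shape[1] - (ipm.shape[1] % bin)
    def tile(m):
        return m[:, :width].reshape(len(m), width // bin, bin).mean(axis=2)
    ip_t = tile(ipm) * scale / ip.total
    ct_t = tile(ctm) * scale / control.total
    ratio = (ip_t + 1.0) / (ct_t + 1.0)
    lo, hi = np.quantile(ratio, quantiles[0]), np.quantile(ratio, quantiles[1])
    clipped = np.clip(ratio, lo, hi)
    half = order_window // 2
    central = slice(flank - half, flank + half)
    order = np.argsort(-ipm[:, central].mean(axis=1), kind="stable")
    offsets = np.arange(-flank, -flank + width, bin) + (bin - 1) / 2
    agg_ip = ip_t[order].mean(axis=0)
    agg_ct = ct_t[order].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        aggregate = np.where(agg_ct > 0, agg_ip / agg_ct, np.nan)
    return ProfileMatrix(clipped[order], offsets, order, aggregate, bin, flank)


def random_peaks(n: int, chrom_sizes: dict[str, int], min_sep: int = 4000,
                 seed: int = 72346, max_tries: int = 1000) -> PeakSet:
    """Uniform random single-base peak placements, no two centers within
    ``min_sep``, reproducible under ``seed``."""
    genome = sum(chrom_sizes.values())
    if genome < n * min_sep:
        raise ValueError("genome too small for requested placement density")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    probs = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    count = 0
    for _ in range(max_tries):
        if count >= n:
            break
        draw = n - count
        which = rng.choice(len(chroms), size=draw, p=probs)
        pos = rng.integers(0, [chrom_sizes[chroms[w]] for w in which])
        for w, p in zip(which, pos):
            c = chroms[w]
            if all(abs(p - q) >= min_sep for q in placed[c]):
                placed[c].append(int(p))
                count += 1
                if count >= n:
                    break
    if count < n:
        raise ValueError("could not place peaks at requested density")
    rows = [(c, p, p + 1, p) for c in chroms for p in sorted(placed[c])]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "center"])
    return PeakSet(df, [f"random_peaks(n={n}, seed={seed})"])


def _equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-count bin index (0..n_bins-1); sizes differ by <= 1."""
    order = np.argsort(values, kind="stable")
    bins = np.empty(len(values), dtype=int)
    bins[order] = np.floor(np.arange(len(values)) * n_bins / len(values)).astype(int)
    return bins


def _gam_fit(x: np.ndarray, y: np.ndarray, family, df_spline: int = 10):
    """Penalized B-spline GAM fit; returns fitted values for x (sorted order
    preserved)."""
    from statsmodels.gam.api import BSplines, GLMGam

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 4 or len(np.unique(y)) < 2:
        # degenerate design or constant response: fall back to the grand mean
        return np.full(len(x), y.mean())
    df_spline = min(df_spline, max(4, len(np.unique(x)) - 1))
    bs = BSplines(x[:, None], df=[df_spline], degree=[3])
    model = GLMGam(y, np.ones((len(y), 1)), smoother=bs, family=family,
                   alpha=[1.0])
    try:
        alpha = model.select_penweight()[0]
        model = GLMGam(y, np.ones((len(y), 1)), smoother=bs, family=family,
                       alpha=alpha)
    except Exception:
        pass
    res = model.fit()
    return np.asarray(res.fittedvalues)


def overlap_by_enrichment(peaks: pd.DataFrame, features: pd.DataFrame,
                          n_bins: int = 25) -> pd.DataFrame:
    """Fraction of peaks overlapping a feature set, by enrichment bin.

    Peaks are ranked by enrichment into ``n_bins`` equal-count bins; per bin
    the mean enrichment and overlap fraction are reported, with a logistic
    GAM smooth of overlap on enrichment evaluated at the bin means.
    """
    import statsmodels.api as sm

    if len(peaks) < n_bins:
        raise ValueError("fewer peaks than bins")
    hits = overlaps_any(peaks, features).astype(float)
    enr = peaks["enrichment"].to_numpy(dtype=float)
    bins = _equal_count_bins(enr, n_bins)
    df = pd.DataFrame({"bin": bins, "enrichment": enr, "hit": hits})
    out = df.groupby("bin").agg(n=("hit", "size"),
                                mean_enrichment=("enrichment", "mean"),
                                frac_overlap=("hit", "mean")).reset_index()
    fitted = _gam_fit(enr, hits, sm.families.Binomial())
    out["smooth"] = pd.DataFrame({"bin": bins, "fit": fitted}).groupby("bin")["fit"].mean().to_numpy()
    return out


def mark_vs_binding_curve(mark_a: pd.DataFrame, mark_b: pd.DataFrame,
                          strata: np.ndarray | pd.Series,
                          n_bins: int = 25,
                          log_offset: float = 0.1) -> pd.DataFrame:
    """Binned markB-enrichment as a function of markA enrichment, per stratum.

    Both marks must be force-called on identical windows (e.g. 100 bp tiles
    of the autosomes); ``strata`` labels each window (e.g. PRDM9-bound vs
    pre-existing mark).  Within each stratum, markA enrichment is cut into
    ``n_bins`` equal-count bins; per bin the mean of markB enrichment with
    +/- 2 SE and quartiles are reported, plus a Gaussian GAM smooth of markB
    on log(markA + ``log_offset``) evaluated at the bin means.
    """
    import statsmodels.api as sm

    if len(mark_a) != len(mark_b):
        raise ValueError("marks must be force-called on identical windows")
    strata = np.asarray(strata)
    rows = []
    for label in pd.unique(strata):
        sel = strata == label
        if sel.sum() == 0:
            raise ValueError(f"empty stratum {label!r}")
        if sel.sum() < n_bins:
            raise ValueError(f"stratum {label!r} smaller than n_bins")
        a = mark_a.loc[sel, "enrichment"].to_numpy(dtype=float)
        b = mark_b.loc[sel, "enrichment"].to_numpy(dtype=float)
        bins = _equal_count_bins(a, n_bins)
        fitted = _gam_fit(np.log(a + log_offset), b, sm.families.Gaussian())
        grp = pd.DataFrame({"bin": bins, "a": a, "b": b, "fit": fitted}).groupby("bin")
        agg = grp.agg(n=("b", "size"), mean_a=("a", "mean"), mean_b=("b", "mean"),
                      sd_b=("b", "std"), q25=("b", lambda v: v.quantile(0.25)),
                      q75=("b", lambda v: v.quantile(0.75)),
                      smooth=("fit", "mean")).reset_index()
        agg["se2_b"] = 2 * agg["sd_b"] / np.sqrt(agg["n"])
        agg.insert(0, "stratum", label)
        rows.append(agg.drop(columns="sd_b"))
    return pd.concat(rows, ignore_index=True)
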