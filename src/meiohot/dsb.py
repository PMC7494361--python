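"""DMC1 persistence analyses at recombination hotspots.

DMC1 ChIP SSDS signal at a hotspot reflects the product of DSB frequency
(measured by SPO11 oligos) and the time DMC1 stays bound to the resected
single-stranded DNA (repair delay).  Persistence is never observed directly;
the module reports observable consequences instead:

* the power-law exponent b of DMC1 on SPO11 (b ~ 1: repair time unrelated
  to DSB frequency; b < 1: sublinear, i.e. hotter hotspots resolve faster),
* the smooth relationship of the per-hotspot KO:WT DMC1 ratio to a
  predictor such as H3K4me3, with a Pearson r of fitted vs observed and a
  fold-range across predictor deciles,
* strand-specific profile normalisation around hotspot centers, and
* a chromosome-holdout logistic model predicting which binding sites retain
  DMC1 signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "scale_by_autosomal_mean", "bin_with_ci", "linearity_assessment",
    "ko_wt_ratio_model", "dsb_profile_normalize", "stratify_by_mark",
    "predict_dmc1_status", "LinearityResult", "RatioModelResult",
    "Dmc1PredictionResult",
]


def scale_by_autosomal_mean(table: pd.DataFrame, columns: list[str],
                            is_x_col: str = "is_x") -> pd.DataFrame:
    """Divide each named column by its autosomal mean.

    X-chromosome rows are scaled by the same (autosomal) factor so the
    X/autosome contrast is preserved; after scaling the autosomal mean of
    every named column is exactly 1.
    """
    out = table.copy()
    auto = ~out[is_x_col].astype(bool) if is_x_col in out.columns else np.ones(len(out), bool)
    if auto.sum() == 0:
        raise ValueError("no autosomal hotspots")
    for col in columns:
        mean = out.loc[auto, col].mean()
        if mean == 0:
            raise ValueError(f"zero autosomal mean in {col}")
        out[col] = out[col] / mean
    return out


def bin_with_ci(x, y, n_bins: int) -> pd.DataFrame:
    """Equal-count bins on x; per bin the mean of y with a 95% normal CI.

    Bin sizes differ by at most 1 (rank-based assignment); the CI is
    mean +/- 1.96 SE.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < n_bins:
        raise ValueError("fewer points than bins")
    from .chip import _equal_count_bins
    bins = _equal_count_bins(x, n_bins)
    df = pd.DataFrame({"bin": bins, "x": x, "y": y})
    out = df.groupby("bin").agg(n=("y", "size"), mean_x=("x", "mean"),
                                mean=("y", "mean"), sd=("y", "std")).reset_index()
    se = out["sd"] / np.sqrt(out["n"])
    out["ci_lo"] = out["mean"] - 1.96 * se
    out["ci_hi"] = out["mean"] + 1.96 * se
    return out.drop(columns="sd")


@dataclass
class LinearityResult:
    """Power-law fit log y = a + b log x with linear-vs-power comparison."""

    exponent: float
    exponent_ci: tuple[float, float]
    intercept: float
    n: int
    log_offset: float
    rss_power: float
    rss_linear: float          # RSS with the exponent fixed at 1

    #: numerical slack for CI-boundary classification on near-exact fits
    _tol = 1e-9

    @property
    def sublinear(self) -> bool:
        """True when the 95% CI for the exponent lies entirely below 1."""
        return self.exponent_ci[1] < 1.0 - self._tol

    @property
    def linear(self) -> bool:
        """True when the 95% CI for the exponent covers 1."""
        return (self.exponent_ci[0] <= 1.0 + self._tol
                and self.exponent_ci[1] >= 1.0 - self._tol)

    def summary(self) -> str:
        lo, hi = self.exponent_ci
        verdict = "sublinear" if self.sublinear else ("linear" if self.linear else "superlinear")
        return (f"log-log regression, n={self.n}\n"
                f"  exponent b = {self.exponent:.3f} (95% CI {lo:.3f}-{hi:.3f}) -> {verdict}\n"
                f"  RSS power {self.rss_power:.4g} vs slope-1 {self.rss_linear:.4g}\n"
                f"  zero offset {self.log_offset:.3g}")


def linearity_assessment(spo11, dmc1) -> LinearityResult:
    """Fit log(DMC1) = a + b log(SPO11) and compare against strict linearity.

    Zeros are offset by the smallest positive observed value before taking
    logs (recorded in the result).  b ~ 1 indicates DMC1 tracks DSB
    frequency; b < 1 (sublinear) indicates shorter DMC1 persistence at
    stronger hotspots.
    """
    import statsmodels.api as sm

    x = np.asarray(spo11, dtype=float)
    y = np.asarray(dmc1, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 hotspots")
    pos = np.concatenate([x[x > 0], y[y > 0]])
    if len(pos) == 0:
        raise ValueError("no positive values")
    offset = pos.min() if ((x <= 0).any() or (y <= 0).any()) else 0.0
    lx, ly = np.log(x + offset), np.log(y + offset)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = res.conf_int()[1]
    resid1 = ly - lx - (ly - lx).mean()  # best intercept with slope fixed at 1
    return LinearityResult(
        exponent=float(res.params[1]), exponent_ci=(float(ci[0]), float(ci[1])),
        intercept=float(res.params[0]), n=len(x), log_offset=float(offset),
        rss_power=float(res.ssr), rss_linear=float((resid1 ** 2).sum()))


@dataclass
class RatioModelResult:
    """GAM of per-hotspot KO:WT DMC1 ratio on a predictor."""

    predictor: list[str]
    r: float                 # Pearson r of fitted vs observed ratio
    fold_range: float        # smooth at top vs bottom predictor decile
    n: int
    n_excluded: int
    fitted: np.ndarray
    observed: np.ndarray

    def summary(self) -> str:
        return (f"KO:WT DMC1 ratio ~ s({' + '.join(self.predictor)}), "
                f"n={self.n} ({self.n_excluded} excluded)\n"
                f"  r (fitted vs observed) = {self.r:.3f}\n"
                f"  fold-range top/bottom decile = {self.fold_range:.2f}")


def ko_wt_ratio_model(table: pd.DataFrame, predictor: str | list[str],
                      wt_col: str = "dmc1_wt", ko_col: str = "dmc1_ko",
                      is_x_col: str = "is_x") -> RatioModelResult:
    """Smooth model of the per-hotspot KO:WT DMC1 ratio, autosomes only.

    Hotspots with non-positive WT DMC1 are excluded (the ratio is
    undefined).  The fold-range is the ratio of the mean fitted value in the
    top decile of the (first) predictor to that in the bottom decile — the
    "how many fold does relative DMC1 retention change" number.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    predictors = [predictor] if isinstance(predictor, str) else list(predictor)
    df = table
    if is_x_col in df.columns:
        df = df[~df[is_x_col].astype(bool)]
    ok = df[wt_col] > 0
    excluded = int((~ok).sum())
    df = df[ok]
    ratio = (df[ko_col] / df[wt_col]).to_numpy(dtype=float)
    X = df[predictors].to_numpy(dtype=float)
    df_spline = [10] * len(predictors)
    bs = BSplines(X, df=df_spline, degree=[3] * len(predictors))
    model = GLMGam(ratio, np.ones((len(ratio), 1)), smoother=bs,
                   family=sm.families.Gaussian(), alpha=[1.0] * len(predictors))
    try:
        alpha = model.select_penweight()[0]
        model = GLMGam(ratio, np.ones((len(ratio), 1)), smoother=bs,
                       family=sm.families.Gaussian(), alpha=alpha)
    except Exception:
        pass
    res = model.fit()
    fitted = np.asarray(res.fittedvalues)
    r = float(stats.pearsonr(fitted, ratio)[0])
    lead = X[:, 0]
    lo_cut, hi_cut = np.quantile(lead, [0.1, 0.9])
    lo_mean = fitted[lead <= lo_cut].mean()
    hi_mean = fitted[lead >= hi_cut].mean()
    fold = float(hi_mean / lo_mean) if lo_mean > 0 else np.inf
    return RatioModelResult(predictors, r, fold, len(ratio), excluded,
                            fitted, ratio)


def dsb_profile_normalize(tracks: dict[tuple[str, str], "object"],
                          region_sets: dict[str, pd.DataFrame],
                          flank_up: int = 5000, flank_down: int = 2000,
                          background: tuple[int, int] = (-5000, -3000),
                          ) -> pd.DataFrame:
    """Background-subtracted, total-normalised strand-specific DSB profiles.

    ``tracks`` maps (sample, strand) -> CoverageTrack; ``region_sets`` maps
    sample (genotype) -> centred/stranded hotspot regions.  For each
    sample-strand combination the mean per-offset coverage over that
    sample's regions is computed on offsets [-flank_up, flank_down], the
    mean over the background offsets is subtracted, and the result is
    divided by the combination's summed coverage across *all* samples'
    region sets (so profiles are comparable across genotypes).
    """
    from .chip import _region_matrix

    lo, hi = background
    if not (-flank_up <= lo < hi <= flank_down):
        raise ValueError("background window outside profile range")
    offsets = np.arange(-flank_up, flank_down + 1)
    bg_mask = (offsets >= lo) & (offsets <= hi)
    if not bg_mask.any():
        raise ValueError("empty background window")
    frames = []
    for (sample, strand), track in tracks.items():
        # off-center flanks differ up/downstream; reuse the symmetric helper
        # on the wider flank then crop
        flank = max(flank_up, flank_down)
        full = _region_matrix(track, region_sets[sample], flank)
        full_offsets = np.arange(-flank, flank + 1)
        crop = (full_offsets >= -flank_up) & (full_offsets <= flank_down)
        mat = full[:, crop]
        mean = mat.mean(axis=0)
        mean = mean - mean[bg_mask].mean()
        denom = 0.0
        for regions in region_sets.values():
            other = _region_matrix(track, regions, flank)[:, crop]
            denom += other.sum()
        if denom <= 0:
            raise ValueError(f"no coverage for {(sample, strand)}")
        frames.append(pd.DataFrame({
            "sample": sample, "strand": strand,
            "offset": offsets, "profile": mean / denom,
        }))
    return pd.concat(frames, ignore_index=True)


def stratify_by_mark(regions: pd.DataFrame, mark_values,
                     profile_fn, low_q: float = 0.50, high_q: float = 0.75,
                     ) -> pd.DataFrame:
    """Aggregate profiles for hotspots stratified by a mark's strength.

    Strata: low (< 50th percentile of the mark), high (> 75th percentile),
    medium (the rest).  ``profile_fn(regions) -> DataFrame[offset, profile]``
    computes the aggregate profile of a region subset.  Each stratum's
    profile carries a half-maximum width summary (the offset range over
    which the profile exceeds half its maximum).  If all mark values are
    identical every region falls in "medium" (degenerate split).
    """
    mark = np.asarray(mark_values, dtype=float)
    lo_cut, hi_cut = np.quantile(mark, [low_q, high_q])
    labels = np.where(mark < lo_cut, "low", np.where(mark > hi_cut, "high", "medium"))
    frames = []
    for stratum in ("low", "medium", "high"):
        sel = labels == stratum
        if sel.sum() == 0:
            continue
        prof = profile_fn(regions[sel].reset_index(drop=True)).copy()
        prof["stratum"] = stratum
        prof["n"] = int(sel.sum())
        peak = prof["profile"].max()
        above = prof.loc[prof["profile"] > peak / 2, "offset"]
        prof["half_max_width"] = float(above.max() - above.min()) if len(above) else 0.0
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)


@dataclass
class Dmc1PredictionResult:
    """Chromosome-holdout logistic model of DMC1 retention at binding sites."""

    params: pd.Series
    auroc: float
    average_precision: float
    n_train: int
    n_test: int
    test_chroms: tuple
    predictions: pd.DataFrame

    def summary(self) -> str:
        coef = "\n".join(f"    {k}: {v:+.4f}" for k, v in self.params.items())
        return (f"logistic DMC1-status model "
                f"(train n={self.n_train}, test n={self.n_test} on "
                f"chromosomes {list(self.test_chroms)})\n{coef}\n"
                f"  test AUROC = {self.auroc:.3f}\n"
                f"  test average precision = {self.average_precision:.3f}")


def trim_peaks(peaks: pd.DataFrame, max_width: int = 3000,
               trim_to: int = 800) -> pd.DataFrame:
    """Drop peaks wider than ``max_width`` and trim the rest to at most
    ``trim_to`` bp around their midpoint."""
    df = peaks.copy()
    width = df["end"] - df["start"]
    df = df[width < max_width].copy()
    mid = (df["start"] + df["end"]) // 2
    half = trim_to // 2
    wide = (df["end"] - df["start"]) > trim_to
    df.loc[wide, "start"] = (mid[wide] - half).astype(int)
    df.loc[wide, "end"] = (mid[wide] + half).astype(int)
    return df.reset_index(drop=True)


def predict_dmc1_status(binding_calls: pd.DataFrame, dmc1_peaks: pd.DataFrame,
                        predictors: list[str],
                        test_chroms: tuple = ("1", "3", "5"),
                        max_input: float = 200, min_input: float = 5,
                        max_enrichment: float = 10) -> Dmc1PredictionResult:
    """Predict whether a binding site overlaps a (trimmed) DMC1 peak.

    ``binding_calls`` holds force-called predictor enrichments at binding
    sites (chrom/start/end plus predictor and input-coverage columns).
    DMC1 peaks should already be width-filtered and trimmed
    (:func:`trim_peaks`).  Sites with input coverage <= 5, input > 200 or
    enrichment > 10 in any predictor are removed as uninformative/outliers.
    The logistic model trains on all autosomes except the held-out test
    chromosomes and is evaluated there by AUROC and average precision.
    """
    import statsmodels.api as sm
    from sklearn.metrics import average_precision_score, roc_auc_score

    from .intervals import overlaps_any

    df = binding_calls.copy()
    for col in df.columns:
        if col.startswith("input"):
            df = df[(df[col] > min_input) & (df[col] <= max_input)]
    for col in predictors:
        df = df[df[col] <= max_enrichment]
    df = df.reset_index(drop=True)
    df["target"] = overlaps_any(df, dmc1_peaks)
    chroms = df["chrom"].astype(str).str.removeprefix("chr")
    test = chroms.isin([str(c) for c in test_chroms])
    train_df, test_df = df[~test], df[test]
    if train_df["target"].nunique() < 2:
        raise ValueError("training set has a single class")
    X_train = sm.add_constant(train_df[predictors].to_numpy(dtype=float))
    X_test = sm.add_constant(test_df[predictors].to_numpy(dtype=float), has_constant="add")
    res = sm.GLM(train_df["target"].to_numpy(dtype=float), X_train,
                 family=sm.families.Binomial()).fit()
    scores = res.predict(X_test)
    y = test_df["target"].to_numpy(dtype=float)
    auroc = float(roc_auc_score(y, scores)) if len(np.unique(y)) > 1 else np.nan
    ap = float(average_precision_score(y, scores)) if len(np.unique(y)) > 1 else np.nan
    preds = test_df[["chrom", "start", "end", "target"]].copy()
    preds["score"] = np.asarray(scores)
    return Dmc1PredictionResult(
        params=pd.Series(res.params, index=["const"] + predictors),
        auroc=auroc, average_precision=ap,
        n_train=len(train_df), n_test=len(test_df),
        test_chroms=tuple(test_chroms), predictions=preds)
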