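"""Low-pass copy-number comparison.

Pipeline: fixed-width binning of read starts -> GC correction by
decile-median rescaling -> log2 ratio to the sample median -> penalized
binary segmentation -> loss/neutral/gain calls -> harmonization of
segment boundaries across samples -> hierarchical clustering and
Pearson correlation of the per-region profiles.

Segmentation accepts a split while the reduction in within-segment sum
of squares exceeds ``penalty * log(n)`` (n = number of bins on the
chromosome), which behaves like a BIC-style stopping rule and is exactly
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from . import _seq

DEFAULT_LOSS_THRESHOLD = -0.15
DEFAULT_GAIN_THRESHOLD = 0.15


@dataclass
class CnvProfile:
    """Per-sample binned profile with its segmentation.

    segments: list of (start_bin, end_bin, mean_log2), bin indices
    0-based inclusive, partitioning the bin range.
    """

    sample: str
    bins: pd.DataFrame  # chrom, start, end, gc, count
    log2_ratios: np.ndarray
    segments: list[tuple[int, int, float]]
    calls: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        covered = sorted((s, e) for s, e, _ in self.segments)
        expect = 0
        for s, e in covered:
            if s != expect:
                raise ValueError("segments do not partition the bin range")
            expect = e + 1
        if covered and expect != len(self.log2_ratios):
            raise ValueError("segments do not cover all bins")


# ---------------------------------------------------------------------------
# binning and normalisation
# ---------------------------------------------------------------------------

def bin_counts(read_starts, bin_size: int, reference: str,
               chrom: str = "chr1") -> pd.DataFrame:
    """Count 1-based read starts in fixed windows; terminal bin may be short.

    Total count is conserved.  GC per bin comes from the reference slice.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    L = len(reference)
    starts = np.asarray(read_starts, dtype=np.int64)
    if starts.size and (starts.min() < 1 or starts.max() > L):
        raise ValueError("read start outside reference")
    edges = np.arange(1, L + 1, bin_size)
    ends = np.minimum(edges + bin_size - 1, L)
    counts = np.bincount((starts - 1) // bin_size,
                         minlength=edges.size).astype(np.int64)
    codes = _seq.encode(reference)
    gc_cum = np.concatenate([[0], np.cumsum((codes == _seq.C)
                                            | (codes == _seq.G))])
    gc = (gc_cum[ends] - gc_cum[edges - 1]) / (ends - edges + 1)
    return pd.DataFrame({"chrom": chrom, "start": edges, "end": ends,
                         "gc": gc, "count": counts})


def gc_correct(binned: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Median-rescale counts within GC deciles; overall median preserved.

    Returns (corrected table, flags) where flags marks bins in a
    zero-median stratum that were left uncorrected.
    """
    if len(binned) < 20:
        raise ValueError("need >= 20 bins for GC correction")
    counts = binned["count"].to_numpy(dtype=float)
    if not counts.any():
        raise ValueError("all bin counts are zero")
    gc = binned["gc"].to_numpy()
    # decile strata of the observed GC values; degenerate (constant GC)
    # inputs collapse to one stratum and the correction is the identity
    quantiles = np.quantile(gc, np.linspace(0, 1, 11))
    strata = np.clip(np.searchsorted(quantiles, gc, side="right") - 1, 0, 9)
    overall = np.median(counts[counts > 0])
    corrected = counts.copy()
    flags = np.zeros(len(binned), dtype=bool)
    for s in np.unique(strata):
        sel = strata == s
        med = np.median(counts[sel])
        if med <= 0:
            flags[sel] = True
            continue
        corrected[sel] = counts[sel] / med * overall
    out = binned.copy()
    out["count"] = corrected
    return out, flags


def log2_ratio(corrected: pd.DataFrame | np.ndarray) -> np.ndarray:
    """log2(count / sample median); zero-count bins masked as NaN."""
    counts = (corrected["count"].to_numpy(dtype=float)
              if isinstance(corrected, pd.DataFrame)
              else np.asarray(corrected, dtype=float))
    positive = counts[counts > 0]
    if positive.size == 0 or np.median(positive) <= 0:
        raise ValueError("sample median is not positive")
    med = np.median(positive)
    with np.errstate(divide="ignore"):
        ratios = np.log2(counts / med)
    ratios[counts <= 0] = np.nan
    return ratios


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _best_split(prefix: np.ndarray, prefix_sq: np.ndarray,
                lo: int, hi: int) -> tuple[int, float]:
    """Best single change point in [lo, hi); returns (split, sse_gain).

    split is the first index of the right part.  Uses prefix sums for
    O(len) evaluation of all candidate splits.
    """
    n = hi - lo
    total = prefix[hi] - prefix[lo]
    total_sq = prefix_sq[hi] - prefix_sq[lo]
    sse_full = total_sq - total * total / n
    ks = np.arange(lo + 1, hi)
    left_n = ks - lo
    right_n = hi - ks
    left_sum = prefix[ks] - prefix[lo]
    right_sum = total - left_sum
    sse_split = (total_sq - left_sum ** 2 / left_n
                 - right_sum ** 2 / right_n)
    best = int(np.argmin(sse_split))
    return int(ks[best]), float(sse_full - sse_split[best])


def segment(values, penalty: float = 2.0) -> list[tuple[int, int, float]]:
    """Penalized recursive binary segmentation of one chromosome's bins.

    A split is accepted iff it reduces the within-segment SSE by more
    than penalty * log(n).  NaN (masked) bins are excluded from the fit
    and inherit the segment covering them.  Returns (start_bin, end_bin,
    mean_log2) with 0-based inclusive bin indices partitioning the range.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing bins")
    obs = x[ok]
    obs_idx = np.flatnonzero(ok)
    n = obs.size
    threshold = penalty * np.log(n)
    prefix = np.concatenate([[0.0], np.cumsum(obs)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(obs ** 2)])

    breaks: list[int] = []  # split points in observed-index space
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2:
            continue
        split, gain = _best_split(prefix, prefix_sq, lo, hi)
        if gain > threshold:
            breaks.append(split)
            stack.append((lo, split))
            stack.append((split, hi))
    bounds = [0] + sorted(breaks) + [n]

    segments = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mean = float(obs[lo:hi].mean())
        start_bin = int(obs_idx[lo]) if lo > 0 else 0
        end_bin = (int(obs_idx[hi] - 1) if hi < n else len(x) - 1)
        segments.append((start_bin, end_bin, mean))
    return segments


def segment_objective(values, segments, penalty: float) -> float:
    """Penalized SSE of a segmentation (for oracle comparisons)."""
    x = np.asarray(values, dtype=float)
    n = int((~np.isnan(x)).sum())
    sse = 0.0
    for s, e, _ in segments:
        seg = x[s:e + 1]
        seg = seg[~np.isnan(seg)]
        if seg.size:
            sse += float(((seg - seg.mean()) ** 2).sum())
    return sse + penalty * np.log(n) * (len(segments) - 1)


def exhaustive_segment(values, penalty: float) -> list[tuple[int, int, float]]:
    """Optimal segmentation by dynamic programming (small inputs only).

    Minimizes SSE + penalty*log(n)*(k-1) exactly; the independent oracle
    for the binary-segmentation heuristic.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("oracle expects complete signals")
    n = x.size
    cost = penalty * np.log(n)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def sse(i: int, j: int) -> float:  # [i, j)
        s = prefix[j] - prefix[i]
        return (prefix_sq[j] - prefix_sq[i]) - s * s / (j - i)

    best = np.full(n + 1, np.inf)
    back = np.zeros(n + 1, dtype=int)
    best[0] = -cost  # first segment does not pay the penalty
    for j in range(1, n + 1):
        for i in range(j):
            c = best[i] + cost + sse(i, j)
            if c < best[j]:
                best[j], back[j] = c, i
    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(back[bounds[-1]]))
    bounds.reverse()
    return [(lo, hi - 1, float(x[lo:hi].mean()))
            for lo, hi in zip(bounds[:-1], bounds[1:])]


def call_states(segments, loss: float = DEFAULT_LOSS_THRESHOLD,
                gain: float = DEFAULT_GAIN_THRESHOLD) -> list[str]:
    """Per-segment call; boundaries inclusive (mean == gain => gain)."""
    if not loss < 0 < gain:
        raise ValueError("need loss < 0 < gain")
    out = []
    for _, _, mean in segments:
        if mean <= loss:
            out.append("loss")
        elif mean >= gain:
            out.append("gain")
        else:
            out.append("neutral")
    return out


def make_profile(sample: str, binned: pd.DataFrame, penalty: float = 2.0,
                 correct_gc: bool = True) -> CnvProfile:
    """Full per-sample pipeline: GC correction, log2, segmentation, calls."""
    table = binned
    if correct_gc:
        table, _ = gc_correct(binned)
    ratios = log2_ratio(table)
    segs = segment(ratios, penalty=penalty)
    return CnvProfile(sample=sample, bins=binned, log2_ratios=ratios,
                      segments=segs, calls=call_states(segs))


# ---------------------------------------------------------------------------
# cross-sample harmonization and correlation
# ---------------------------------------------------------------------------

def harmonize_regions(profiles: list[CnvProfile],
                      loss: float = DEFAULT_LOSS_THRESHOLD,
                      gain: float = DEFAULT_GAIN_THRESHOLD,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Union-of-breakpoints region x sample matrices (mean log2, calls)."""
    if not profiles:
        raise ValueError("no profiles")
    n_bins = {len(p.log2_ratios) for p in profiles}
    if len(n_bins) != 1:
        raise ValueError("profiles are on different bin grids")
    n = n_bins.pop()
    cuts = {0, n}
    for p in profiles:
        for s, _, _ in p.segments:
            cuts.add(s)
    bounds = sorted(cuts)
    regions = list(zip(bounds[:-1], [b - 1 for b in bounds[1:]]))
    index = [f"bin{s}-{e}" for s, e in regions]
    means = pd.DataFrame(index=index,
                         columns=[p.sample for p in profiles], dtype=float)
    for p in profiles:
        for (s, e), name in zip(regions, index):
            vals = p.log2_ratios[s:e + 1]
            vals = vals[~np.isnan(vals)]
            means.loc[name, p.sample] = vals.mean() if vals.size else np.nan
    calls = means.map(lambda m: "loss" if m <= loss
                      else ("gain" if m >= gain else "neutral"))
    return means, calls


def cluster_and_correlate(region_means: pd.DataFrame,
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Average-linkage Euclidean clustering + Pearson correlation matrix.

    Returns (scipy linkage matrix over samples in column order, sample x
    sample correlation frame).  Zero-variance samples get NaN
    correlations (diagonal stays 1).
    """
    if region_means.shape[1] < 2 or region_means.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 regions")
    data = region_means.to_numpy(dtype=float).T  # samples x regions
    filled = np.where(np.isnan(data), 0.0, data)
    merge = linkage(filled, method="average", metric="euclidean")

    samples = list(region_means.columns)
    k = len(samples)
    corr = np.full((k, k), np.nan)
    sd = data.std(axis=1)
    for i in range(k):
        corr[i, i] = 1.0
        for j in range(i + 1, k):
            if sd[i] == 0 or sd[j] == 0:
                continue
            ok = ~np.isnan(data[i]) & ~np.isnan(data[j])
            if ok.sum() < 2:
                continue
            c = np.corrcoef(data[i][ok], data[j][ok])[0, 1]
            corr[i, j] = corr[j, i] = c
    return merge, pd.DataFrame(corr, index=samples, columns=samples)


def pair_merge_order_ok(merge: np.ndarray, pair_index: list[tuple[int, int]],
                        ) -> bool:
    """True when every (i, j) sample pair forms its own first-level clade."""
    n = merge.shape[0] + 1
    first_merges = set()
    for a, b, _, _ in merge:
        if a < n and b < n:
            first_merges.add(frozenset((int(a), int(b))))
    return all(frozenset(p) in first_merges for p in pair_index)
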