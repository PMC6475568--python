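"""Binned GC/mappability tracks: smoothing, thresholding, segmentation.

Chromosome profiles arrive as fixed-size bins (default 100 bp).  GC and
mappability values are fractions in [0, 1]; assembly gaps are represented
as NaN and are never suspicious.  Segmentation marks runs of bins whose
LOESS-smoothed value falls beyond a threshold, keeps runs strictly longer
than ``min_length`` bases, and double-checks each run's mean on the raw
(unsmoothed) values before emitting it as a suspicious region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "BinnedTrack",
    "ThresholdSet",
    "SuspiciousRegion",
    "loess_smooth",
    "select_gc_thresholds",
    "select_mappability_threshold",
    "segment_suspicious",
    "build_suspicious_regions",
    "read_bedgraph",
    "write_bedgraph",
    "DEFAULT_LOESS_WINDOW",
]

logger = logging.getLogger(__name__)

#: Default LOESS sliding window, in bins.  With 100 bp bins this is 700 bp:
#: wide enough to denoise per-bin jitter, narrow enough that features just
#: above the 500 bp emission floor survive smoothing with <= 1 bin of
#: boundary bleed.
DEFAULT_LOESS_WINDOW = 7


@dataclass
class BinnedTrack:
    """Per-chromosome array of fixed-size-bin values.

    Bin ``i`` covers ``[origin + i*bin_size, origin + (i+1)*bin_size)``.
    Missing bins (assembly gaps) are NaN.  Fractional tracks (GC,
    mappability) are bounded to [0, 1]; coverage-style tracks may exceed 1
    and are constructed with ``fractional=False``.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    origin: int = 0
    fractional: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be one-dimensional")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        finite = self.values[~np.isnan(self.values)]
        if self.fractional and finite.size and (
            finite.min() < 0.0 or finite.max() > 1.0
        ):
            raise ValueError("fractional track values must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_interval(self, i: int) -> GenomicInterval:
        s = self.origin + i * self.bin_size
        return GenomicInterval(self.chrom, s, s + self.bin_size)


@dataclass(frozen=True)
class ThresholdSet:
    """GC lower/upper and mappability thresholds, all fractions in [0, 1]."""

    th1: float
    th2: float
    th3: float

    def __post_init__(self) -> None:
        if not self.th1 < self.th2:
            raise ValueError(
                f"degenerate GC thresholds: th1={self.th1} must be < th2={self.th2}"
            )


Cause = Literal["gc_low", "gc_high", "low_mappability"]


@dataclass(frozen=True)
class SuspiciousRegion:
    interval: GenomicInterval
    cause: Cause
    mean_value: float


def loess_smooth(track: BinnedTrack, window_bins: int = DEFAULT_LOESS_WINDOW) -> BinnedTrack:
    """LOESS-smooth a track with a fixed sliding window.

    Each output bin is the degree-1 (local linear), tricube-weighted least
    squares fit evaluated at the bin centre, over a window of
    ``window_bins`` bins.  Missing bins are excluded from every fit and
    stay missing in the output.  Output is clipped to [0, 1] for
    fractional tracks.

    Parameters
    ----------
    track
        Input track.
    window_bins
        Odd window width in bins, >= 3.
    """
    if window_bins < 3 or window_bins % 2 == 0:
        raise ValueError("window_bins must be odd and >= 3")
    v = track.values
    n_ok = int(np.sum(~np.isnan(v)))
    if n_ok < window_bins:
        raise ValueError(
            f"track has {n_ok} non-missing bins; at least {window_bins} required"
        )
    half = window_bins // 2
    pad = np.full(half, np.nan)
    vp = np.concatenate([pad, v, pad])
    windows = np.lib.stride_tricks.sliding_window_view(vp, window_bins)

    x = np.arange(window_bins, dtype=float) - half
    # tricube weights; normalise distance by half+1 so edge bins keep weight
    w0 = (1.0 - (np.abs(x) / (half + 1.0)) ** 3) ** 3
    mask = ~np.isnan(windows)
    w = w0 * mask
    y = np.where(mask, windows, 0.0)

    s0 = w.sum(axis=1)
    s1 = (w * x).sum(axis=1)
    s2 = (w * x * x).sum(axis=1)
    t0 = (w * y).sum(axis=1)
    t1 = (w * x * y).sum(axis=1)
    denom = s0 * s2 - s1 * s1

    with np.errstate(divide="ignore", invalid="ignore"):
        fit = (s2 * t0 - s1 * t1) / denom
        fallback = t0 / s0
    # ill-conditioned local fits (e.g. a single usable point) fall back to
    # the weighted mean
    scale = np.maximum(s0 * s2, 1e-300)
    bad = ~np.isfinite(fit) | (np.abs(denom) < 1e-10 * scale)
    fit = np.where(bad, fallback, fit)
    if track.fractional:
        fit = np.clip(fit, 0.0, 1.0)
    fit[np.isnan(v)] = np.nan
    return BinnedTrack(
        chrom=track.chrom,
        bin_size=track.bin_size,
        values=fit,
        origin=track.origin,
        fractional=track.fractional,
    )


def _clean(values) -> np.ndarray:
    a = np.asarray(values, dtype=float).ravel()
    return a[~np.isnan(a)]


def select_gc_thresholds(
    values: Iterable[float], tail_fraction: float = 0.05
) -> tuple[float, float]:
    """Pick GC thresholds so each distribution tail holds ``tail_fraction``.

    ``th1`` is the empirical quantile at ``tail_fraction`` and ``th2`` the
    quantile at ``1 - tail_fraction``, using the linear-interpolation
    quantile definition.
    """
    a = _clean(values)
    if a.size < 100:
        raise ValueError(f"need >= 100 non-missing values, got {a.size}")
    if not 0.0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    th1 = float(np.quantile(a, tail_fraction))
    th2 = float(np.quantile(a, 1.0 - tail_fraction))
    if not th1 < th2:
        raise ValueError(
            "degenerate GC distribution: lower and upper tail quantiles coincide"
        )
    return th1, th2


def select_mappability_threshold(
    values: Iterable[float], right_area: float = 0.20
) -> float:
    """Pick the mappability threshold after dropping the exact-0/1 masses.

    Values exactly equal to 0 or 1 (the point masses of fully repetitive
    and fully unique sequence) are excluded; the threshold is the
    empirical quantile of the remainder at ``1 - right_area``.
    """
    a = _clean(values)
    a = a[(a != 0.0) & (a != 1.0)]
    if a.size < 100:
        raise ValueError(
            f"need >= 100 values that are not exactly 0 or 1, got {a.size}"
        )
    if not 0.0 < right_area < 1.0:
        raise ValueError("right_area must be in (0, 1)")
    return float(np.quantile(a, 1.0 - right_area))


def _runs(flags: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    padded = np.concatenate([[False], flags, [False]])
    diffs = np.flatnonzero(padded[1:] != padded[:-1])
    for i in range(0, len(diffs), 2):
        yield int(diffs[i]), int(diffs[i + 1])


def segment_suspicious(
    smoothed: BinnedTrack,
    raw: BinnedTrack,
    thresholds: ThresholdSet,
    kind: Literal["gc", "mappability"],
    min_length: int = 500,
) -> list[SuspiciousRegion]:
    """Segment a smoothed track into suspicious regions.

    Bins are suspicious when the smoothed value is below ``th1`` or above
    ``th2`` (GC) or below ``th3`` (mappability).  Maximal runs of
    consecutive suspicious bins form candidates; a candidate is emitted
    only when its span is strictly longer than ``min_length`` bases AND
    the mean of the *raw* values over the run still violates the
    threshold.  Missing bins break runs.
    """
    if kind not in ("gc", "mappability"):
        raise ValueError(f"unknown track kind {kind!r}")
    if (
        smoothed.n_bins != raw.n_bins
        or smoothed.bin_size != raw.bin_size
        or smoothed.origin != raw.origin
        or smoothed.chrom != raw.chrom
    ):
        raise ValueError("smoothed and raw tracks must share geometry")
    sv = smoothed.values
    with np.errstate(invalid="ignore"):
        if kind == "gc":
            susp = (sv < thresholds.th1) | (sv > thresholds.th2)
        else:
            susp = sv < thresholds.th3
    susp &= ~np.isnan(sv)

    regions: list[SuspiciousRegion] = []
    bs = smoothed.bin_size
    for i, j in _runs(susp):
        if (j - i) * bs <= min_length:
            continue
        seg_raw = raw.values[i:j]
        mean_raw = float(np.nanmean(seg_raw))
        if kind == "gc":
            if mean_raw < thresholds.th1:
                cause: Cause = "gc_low"
            elif mean_raw > thresholds.th2:
                cause = "gc_high"
            else:
                continue  # smoothing artifact: raw mean is unremarkable
        else:
            if mean_raw < thresholds.th3:
                cause = "low_mappability"
            else:
                continue
        iv = GenomicInterval(
            smoothed.chrom, smoothed.origin + i * bs, smoothed.origin + j * bs
        )
        regions.append(SuspiciousRegion(interval=iv, cause=cause, mean_value=mean_raw))
    return regions


def build_suspicious_regions(
    gc_regions: Sequence[SuspiciousRegion],
    map_regions: Sequence[SuspiciousRegion],
) -> list[GenomicInterval]:
    """Union of GC- and mappability-derived suspicious regions, merged and sorted."""
    return merge_intervals(
        [r.interval for r in gc_regions] + [r.interval for r in map_regions]
    )


def read_bedgraph(path, bin_size: int | None = None) -> dict[str, BinnedTrack]:
    """Read a uniform-bin bedGraph (or two-column fixed-step) file into tracks.

    bedGraph rows are ``chrom  start  end  value`` with 0-based half-open
    coordinates; every row must span exactly one bin of a single common
    bin size (inferred from the first row when *bin_size* is None).  The
    two-column variant ``position  value`` uses 0-based bin starts and
    requires an explicit *bin_size*.  Gaps between bins become NaN.
    """
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    inferred = bin_size
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) >= 4:
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                width = end - start
                if inferred is None:
                    inferred = width
                if width != inferred:
                    raise ValueError(
                        f"{path}:{ln}: bin width {width} differs from {inferred}; "
                        "uniform bins required"
                    )
            elif len(parts) == 2:
                if inferred is None:
                    raise ValueError(
                        "two-column fixed-step input requires an explicit bin_size"
                    )
                chrom = "chr1"
                start, value = int(parts[0]), float(parts[1])
            else:
                raise ValueError(f"{path}:{ln}: expected 2 or 4 columns")
            if start % inferred != 0:
                raise ValueError(f"{path}:{ln}: bin start {start} not aligned to {inferred}")
            per_chrom.setdefault(chrom, []).append((start, value))

    tracks: dict[str, BinnedTrack] = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        first = rows[0][0]
        n = (rows[-1][0] - first) // inferred + 1
        vals = np.full(n, np.nan)
        for start, value in rows:
            vals[(start - first) // inferred] = value
        tracks[chrom] = BinnedTrack(chrom=chrom, bin_size=inferred, values=vals, origin=first)
    return tracks


def write_bedgraph(track: BinnedTrack, path, mode: str = "w") -> None:
    """Write a track as bedGraph; missing bins are omitted."""
    with open(path, mode) as fh:
        bs = track.bin_size
        for i, v in enumerate(track.values):
            if np.isnan(v):
                continue
            s = track.origin + i * bs
            fh.write(f"{track.chrom}\t{s}\t{s + bs}\t{v:.6g}\n")
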