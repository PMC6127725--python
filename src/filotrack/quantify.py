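"""Inclusion filters and readouts: counts, maximum lengths, distribution fits.

Very short or fleeting reconstructions are noisy, so tracks are filtered to
those whose maximum length reaches at least 3 µm and that exist for at least
two time frames (15 s apart at the default frame interval).  Downstream
readouts are the per-frame filopodium count, the ECDF of maximum lengths,
a shifted-exponential fit of the maximum-length distribution, and two-group
rank-sum (Mann-Whitney) comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import Track

__all__ = [
    "FilterConfig",
    "CountSummary",
    "ExponentialFit",
    "GroupComparison",
    "filter_tracks",
    "count_filopodia",
    "ecdf_max_length",
    "exponential_diagnostic",
    "compare_groups",
]


@dataclass
class FilterConfig:
    """Track inclusion thresholds.

    ``min_max_length_um`` and ``min_lifetime_frames`` are closed bounds
    ("at least").  With ``strict_consecutive`` the lifetime criterion counts
    only the longest run of consecutive frames, rather than total presence.
    ``window_min`` is the quantification window in minutes.
    """

    min_max_length_um: float = 3.0
    min_lifetime_frames: int = 2
    frame_interval_s: float = 15.0
    window_min: float = 15.0
    strict_consecutive: bool = False

    def __post_init__(self) -> None:
        for name in ("min_max_length_um", "min_lifetime_frames",
                     "frame_interval_s", "window_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def window_frames(self) -> int:
        return int(round(self.window_min * 60.0 / self.frame_interval_s))


def filter_tracks(tracks: Iterable[Track], config: FilterConfig | None = None) -> list[Track]:
    """Keep tracks with max length >= 3 µm and lifetime >= 2 frames (defaults)."""
    config = config or FilterConfig()
    kept = []
    for t in tracks:
        lifetime = t.max_consecutive_frames() if config.strict_consecutive else t.lifetime_frames
        if t.max_length_um >= config.min_max_length_um and lifetime >= config.min_lifetime_frames:
            kept.append(t)
    return kept


@dataclass
class CountSummary:
    """Per-frame filopodium counts over a window, with both summary readings."""

    frames: np.ndarray           # frame indices of the window
    per_frame: np.ndarray        # filopodia present in each frame
    mean_count: float            # average per-frame count
    distinct_tracks: int         # distinct identities seen in the window


def count_filopodia(
    tracks: Sequence[Track],
    window_frames: int | None = None,
    total_frames: int | None = None,
) -> CountSummary:
    """Number of filopodia in existence in each frame of a window.

    The window starts at frame 0 and spans ``window_frames`` frames (default:
    the whole movie).  A window longer than the movie is clamped with a
    warning.  Reports both the mean per-frame count and the number of
    distinct tracks seen, since "number of filopodia in a time window" can
    be read either way.
    """
    tracks = list(tracks)
    if total_frames is None:
        total_frames = max((t.last_frame for t in tracks), default=-1) + 1
    if window_frames is None:
        window_frames = total_frames
    if window_frames > total_frames:
        warnings.warn(
            f"window of {window_frames} frames exceeds movie length {total_frames}; clamping",
            stacklevel=2,
        )
        window_frames = total_frames
    frames = np.arange(window_frames)
    per_frame = np.zeros(window_frames, dtype=int)
    distinct = 0
    for t in tracks:
        present = [f for f in t.frames if f < window_frames]
        if present:
            distinct += 1
            per_frame[present] += 1
    mean = float(per_frame.mean()) if window_frames else 0.0
    return CountSummary(frames=frames, per_frame=per_frame, mean_count=mean,
                        distinct_tracks=distinct)


def _max_length_sample(tracks_or_values) -> np.ndarray:
    vals = list(tracks_or_values)
    if vals and isinstance(vals[0], Track):
        vals = [t.max_length_um for t in vals]
    return np.asarray(vals, dtype=float)


def ecdf_max_length(tracks_or_values) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of maximum lengths: (sorted values, cumulative proportions).

    Each point gives the proportion of filopodia with that maximum length or
    less; the curve is right-continuous and reaches 1 at the sample maximum.
    """
    values = _max_length_sample(tracks_or_values)
    if values.size == 0:
        raise ValueError("need at least one track for an ECDF")
    x = np.sort(values)
    props = np.arange(1, len(x) + 1) / len(x)
    return x, props


@dataclass
class ExponentialFit:
    """Shifted-exponential fit of maximum lengths above an offset."""

    rate_per_um: float
    offset_um: float
    n: int
    ks_statistic: float
    ks_pvalue: float  # computed against the fitted law; biased optimistic


def exponential_diagnostic(
    tracks_or_values,
    offset_um: float = 3.0,
    min_n: int = 10,
) -> ExponentialFit:
    """Fit Exp(rate) to max lengths in excess of ``offset_um``.

    Maximum lengths of filopodia are approximately exponentially distributed
    above the reconstruction cut-off (many short, gradually fewer long); the
    maximum-likelihood rate is 1 / mean excess.  The Kolmogorov-Smirnov
    distance against the fitted law is reported as a goodness-of-fit
    diagnostic.
    """
    values = _max_length_sample(tracks_or_values)
    values = values[values >= offset_um]
    if len(values) < min_n:
        raise ValueError(f"need at least {min_n} values at or above the offset")
    mean_excess = float(np.mean(values - offset_um))
    if mean_excess <= 0:
        raise ValueError("degenerate sample: no excess over the offset")
    rate = 1.0 / mean_excess
    ks = stats.kstest(values, "expon", args=(offset_um, mean_excess))
    return ExponentialFit(
        rate_per_um=rate,
        offset_um=offset_um,
        n=len(values),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


def compare_groups(sample_a, sample_b) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two samples (counts or lengths).

    Uses the exact null distribution when both samples have at most 20
    observations, otherwise the normal approximation with tie correction.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        n_a=a.size,
        n_b=b.size,
    )
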