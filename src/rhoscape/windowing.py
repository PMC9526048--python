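"""Windowing of interval maps, unit conversion and the log transform.

Windows are half-open ``[k*w, (k+1)*w)`` anchored at ``start_offset``
(default 0).  Window means are coverage-weighted so averaging is
conservative: the bp-weighted sum of window means equals the bp-weighted sum
of interval rates over the covered span.
"""

from __future__ import annotations

import numpy as np

from .core import GeneAnnotation, IntervalRateMap, RhoscapeError, WindowedTrack, merge_intervals

#: Offset added before taking logs, far below any plausible rho/bp, so
#: zero-rate windows stay finite while ranks are preserved.
LOG_EPSILON = 1e-8


def window_average(
    rate_map: IntervalRateMap, window_bp: int, start_offset: int = 0
) -> WindowedTrack:
    """Coverage-weighted window means of a piecewise-constant rate map.

    Each window's value is ``sum(rho_i * overlap_i) / sum(overlap_i)`` over
    the intervals intersecting it; windows with zero covered bp are NaN.  The
    last, possibly partial, window is kept.
    """
    if window_bp <= 0:
        raise RhoscapeError("window_bp must be positive")
    if len(rate_map) == 0:
        raise RhoscapeError("empty interval map")
    span_end = int(rate_map.ends[-1])
    n_windows = max(1, int(np.ceil((span_end - start_offset) / window_bp)))
    weighted = np.zeros(n_windows)
    covered = np.zeros(n_windows)
    starts = rate_map.starts
    ends = rate_map.ends
    rho = rate_map.rho
    for s, e, r in zip(starts, ends, rho):
        w0 = max(0, (s - start_offset) // window_bp)
        w1 = (e - 1 - start_offset) // window_bp
        for w in range(int(w0), int(w1) + 1):
            win_lo = start_offset + w * window_bp
            win_hi = win_lo + window_bp
            overlap = min(e, win_hi) - max(s, win_lo)
            if overlap > 0:
                weighted[w] += r * overlap
                covered[w] += overlap
    values = np.full(n_windows, np.nan)
    mask = covered > 0
    values[mask] = weighted[mask] / covered[mask]
    return WindowedTrack(
        arm=rate_map.arm,
        window_bp=window_bp,
        values=values,
        units="rho/bp",
        start_offset=start_offset,
    )


def rho_to_cm_mb(track: WindowedTrack, arm_total_cM: float) -> WindowedTrack:
    """Rescale a rho/bp track to cM/Mb by matching the arm's total map length.

    A single per-arm constant ``k = arm_total_cM / sum(value_w * window_Mb)``
    multiplies every window, so after conversion the covered windows sum to
    the arm's genetic length.  Being a positive scaling, ranks (and hence any
    rank correlation) are untouched.
    """
    if track.units != "rho/bp":
        raise RhoscapeError(f"expected rho/bp track, got {track.units}")
    window_mb = track.window_bp / 1e6
    vals = track.values
    total = np.nansum(vals) * window_mb
    if not total > 0:
        raise RhoscapeError(
            "track has zero total rho; cannot match a positive cM target"
        )
    k = arm_total_cM / total
    return track.with_values(vals * k, units="cM/Mb")


def log_transform(track: WindowedTrack) -> WindowedTrack:
    """Natural log with a small offset: ``ln(value + 1e-8)``; NaN stays NaN."""
    vals = track.values
    if np.any(vals[~np.isnan(vals)] < 0):
        raise RhoscapeError("negative value in track; log transform undefined")
    return track.with_values(np.log(vals + LOG_EPSILON), units="log-units")


def bin_gene_content(
    annotation: GeneAnnotation, arm: str, arm_len: int, window_bp: int
) -> WindowedTrack:
    """Per-window proportion of exonic bp (overlapping exons merged)."""
    if window_bp <= 0:
        raise RhoscapeError("window_bp must be positive")
    exons = merge_intervals(annotation.exons_on(arm))
    for s, e in exons:
        if e > arm_len:
            raise RhoscapeError(f"exon ({s}, {e}) extends beyond arm end {arm_len}")
    n_windows = max(1, int(np.ceil(arm_len / window_bp)))
    exonic = np.zeros(n_windows)
    for s, e in exons:
        w0 = s // window_bp
        w1 = (e - 1) // window_bp
        for w in range(w0, w1 + 1):
            win_lo = w * window_bp
            win_hi = win_lo + window_bp
            exonic[w] += max(0, min(e, win_hi) - max(s, win_lo))
    return WindowedTrack(
        arm=arm,
        window_bp=window_bp,
        values=exonic / window_bp,
        units="proportion",
    )


def map_mean_rate(rate_map: IntervalRateMap) -> float:
    """Length-weighted mean rho/bp of the whole map."""
    return float((rate_map.rho * rate_map.lengths).sum() / rate_map.lengths.sum())
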