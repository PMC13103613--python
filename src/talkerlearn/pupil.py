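"""Trial-level pupillometry preprocessing.

Pipeline order: restrict to the -500..4000 ms analysis window, downsample to
50 Hz by non-overlapping block means, reject trials with more than 15% of
samples blink-masked (strictly greater), widen each blink gap by 120 ms per
side and fill it by linear interpolation, then express the post-onset trace
as percent change from the mean of the 500 ms pre-stimulus baseline.
Because downsampling precedes screening, the 15% criterion counts 50 Hz
bins; a flag allows screening at the source rate instead.
"""

from __future__ import annotations

import numpy as np

from .io_config import PupilTrace, StudyConfig

__all__ = [
    "window_trace",
    "downsample",
    "screen_blinks",
    "interpolate_blinks",
    "baseline_normalize",
    "preprocess_all",
]


def window_trace(
    trace: PupilTrace, window_ms: tuple[float, float] = (-500.0, 4000.0)
) -> PupilTrace:
    """Restrict a trace to the analysis window [start, end).

    Start-inclusive, end-exclusive; raises if the trace does not cover the
    full window.  Already-windowed traces pass through unchanged.
    """
    lo, hi = window_ms
    t = trace.time_ms
    dt = 1000.0 / trace.rate_hz
    if t[0] > lo or t[-1] < hi - dt:
        raise ValueError(
            f"trace for trial {trace.key} covers {t[0]:g}..{t[-1]:g} ms, "
            f"not the full window {lo:g}..{hi:g} ms"
        )
    keep = (t >= lo) & (t < hi)
    return trace.copy(
        time_ms=t[keep], samples=trace.samples[keep], is_blink=trace.is_blink[keep]
    )


def downsample(trace: PupilTrace, target_hz: float = 50.0) -> PupilTrace:
    """Downsample by non-overlapping block means.

    The source rate must be an integer multiple of the target.  Each output
    bin takes the mean of its source samples (missing samples excluded; an
    all-missing bin stays missing), the bin-start timestamp, and a blink
    flag that is true if any source sample in the bin was blink-masked.
    """
    ratio = trace.rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"source rate {trace.rate_hz} Hz is not an integer multiple of "
            f"target {target_hz} Hz"
        )
    ratio = int(round(ratio))
    if ratio == 1:
        return trace.copy()
    n_bins = len(trace.samples) // ratio
    x = trace.samples[: n_bins * ratio].reshape(n_bins, ratio)
    m = trace.is_blink[: n_bins * ratio].reshape(n_bins, ratio)
    valid = ~np.isnan(x)
    counts = valid.sum(axis=1)
    sums = np.nansum(np.where(valid, x, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return trace.copy(
        time_ms=trace.time_ms[: n_bins * ratio : ratio].copy(),
        samples=means,
        is_blink=m.any(axis=1),
        rate_hz=target_hz,
    )


def screen_blinks(trace: PupilTrace, threshold: float = 0.15) -> bool:
    """True (keep) unless the blink fraction strictly exceeds the threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return trace.blink_fraction() <= threshold


def interpolate_blinks(trace: PupilTrace, pad_ms: float = 120.0) -> PupilTrace:
    """Fill blink gaps, widened by ``pad_ms`` per side, by linear interpolation.

    Interpolation anchors are the nearest valid samples outside the widened
    gap; gaps touching the trace edge are filled by nearest-value extension.
    The output has no missing samples and a cleared blink mask.
    """
    mask = trace.is_blink | np.isnan(trace.samples)
    if mask.all():
        raise ValueError(
            f"trace for trial {trace.key} is entirely blink-masked"
        )
    if not mask.any():
        return trace.copy()
    pad = int(round(pad_ms * trace.rate_hz / 1000.0))
    if pad > 0:
        # widen each contiguous blink run by `pad` samples per side
        kernel = np.ones(2 * pad + 1)
        wide = np.convolve(mask.astype(float), kernel, mode="same") > 0
    else:
        wide = mask.copy()
    valid = ~wide
    if not valid.any():
        raise ValueError(
            f"trace for trial {trace.key} has no valid samples after "
            "gap widening"
        )
    t = trace.time_ms
    filled = np.interp(t, t[valid], trace.samples[valid])
    return trace.copy(
        samples=filled, is_blink=np.zeros(len(filled), dtype=bool)
    )


def baseline_normalize(
    trace: PupilTrace, baseline_window_ms: float = 500.0
) -> PupilTrace:
    """Percent change from the pre-stimulus baseline, restricted to t >= 0.

    baseline = mean over [-baseline_window, 0); output(t) =
    100 * (sample - baseline) / baseline for t in [0, end); the baseline
    window itself is dropped.
    """
    t = trace.time_ms
    base_mask = (t >= -baseline_window_ms) & (t < 0)
    if not base_mask.any():
        raise ValueError(
            f"trace for trial {trace.key} lacks baseline samples"
        )
    if np.isnan(trace.samples).any():
        raise ValueError(
            f"trace for trial {trace.key} has missing samples; interpolate "
            "before normalizing"
        )
    baseline = float(trace.samples[base_mask].mean())
    if baseline <= 0:
        raise ValueError(
            f"non-positive baseline ({baseline:g}) for trial {trace.key}"
        )
    keep = t >= 0
    pct = 100.0 * (trace.samples[keep] - baseline) / baseline
    return trace.copy(
        time_ms=t[keep],
        samples=pct,
        is_blink=trace.is_blink[keep],
        state="preprocessed",
    )


def preprocess_all(
    traces,
    config: StudyConfig | None = None,
    screen_at_source_rate: bool = False,
) -> tuple[list[PupilTrace], dict]:
    """Window -> downsample -> blink screen -> interpolate -> normalize.

    Per-trial failures are collected in the report rather than raised.  The
    report lists rejection percentages overall and per language x block.
    """
    config = config or StudyConfig()
    kept: list[PupilTrace] = []
    n_rejected = 0
    errors: list[str] = []
    counts: dict[tuple, list[int]] = {}
    for trace in traces:
        cond = (trace.language, trace.block)
        counts.setdefault(cond, [0, 0])
        counts[cond][1] += 1
        try:
            tr = window_trace(trace, config.pupil_window_ms)
            if screen_at_source_rate and not screen_blinks(
                tr, config.blink_threshold
            ):
                n_rejected += 1
                counts[cond][0] += 1
                continue
            tr = downsample(tr, config.downsample_hz)
            if not screen_at_source_rate and not screen_blinks(
                tr, config.blink_threshold
            ):
                n_rejected += 1
                counts[cond][0] += 1
                continue
            tr = interpolate_blinks(tr, config.interp_pad_ms)
            tr = baseline_normalize(tr, config.baseline_window_ms)
            kept.append(tr)
        except ValueError as exc:
            errors.append(str(exc))
    n_total = sum(c[1] for c in counts.values())
    report = {
        "n_total": int(n_total),
        "n_kept": len(kept),
        "n_rejected": int(n_rejected),
        "n_errors": len(errors),
        "pct_rejected": float(100.0 * n_rejected / n_total) if n_total else 0.0,
        "per_condition": {
            f"{lang}/block{blk}": {
                "n": c[1],
                "rejected": c[0],
                "pct": 100.0 * c[0] / c[1],
            }
            for (lang, blk), c in sorted(counts.items())
        },
        "errors": errors,
    }
    return kept, report
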