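"""Candidate CRE discovery from aggregate per-bp accessibility.

The aggregate trace is the fraction of covering fibers accessible at each
position (a documented stand-in for an ML accessibility score — the
peak-calling and per-read stages operate identically on it). Peaks are
local maxima with minimum width 20 bp and minimum height one fifth of the
window maximum; sub-100 bp peaks are expanded symmetrically to 100 bp
around the summit and overlapping peaks merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import Fiber, Interval, covered_fraction, merge_intervals


@dataclass
class CREPeak:
    start: int
    end: int
    summit: int
    height: float
    label: str = ""
    gene_id: str = ""

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def width(self) -> int:
        return self.end - self.start


def aggregate_trace(
    fibers_accessible: list[tuple[Interval, list[Interval]]],
    window: Interval,
) -> np.ndarray:
    """Per-bp accessibility fraction over `window`.

    Each entry of `fibers_accessible` is (fiber span, accessible intervals).
    Positions covered by no fiber are NaN; all-zero coverage raises.
    """
    lo, hi = window
    n = hi - lo
    cov = np.zeros(n)
    acc = np.zeros(n)
    for span, regions in fibers_accessible:
        s, e = max(span[0], lo), min(span[1], hi)
        if e > s:
            cov[s - lo : e - lo] += 1
        for rs, re in regions:
            rs, re = max(rs, lo), min(re, hi)
            if re > rs:
                acc[rs - lo : re - lo] += 1
    if not cov.any():
        raise ValueError("no fiber covers any position of the window")
    with np.errstate(invalid="ignore", divide="ignore"):
        trace = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    return trace


def preprocess_trace(
    trace: np.ndarray,
    smooth: int = 51,
    subtract_baseline: bool = True,
) -> np.ndarray:
    """Smooth an accessibility-fraction trace and remove its baseline.

    Raw accessibility fractions carry a high background (linker gaps between
    nucleosomes), unlike the near-zero background of an ML regulatory-element
    score. A moving average plus median subtraction (clipped at zero) restores
    the background contrast the height criterion of `call_peaks` assumes.
    """
    clean = np.nan_to_num(np.asarray(trace, dtype=float), nan=0.0)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        clean = np.convolve(clean, kernel, mode="same")
    if subtract_baseline:
        clean = np.clip(clean - np.median(clean), 0.0, None)
    return clean


def call_peaks(
    trace: np.ndarray,
    window: Interval,
    min_width: int = 20,
    height_frac: float = 0.2,
    min_peak_size: int = 100,
) -> list[CREPeak]:
    """Local-maximum peak calling on an aggregate accessibility trace.

    Coordinates of returned peaks are genomic (offset by ``window[0]``).
    """
    lo, hi = window
    clean = np.nan_to_num(np.asarray(trace, dtype=float), nan=0.0)
    if clean.max() <= 0:
        return []
    min_height = clean.max() * height_frac
    with warnings.catch_warnings():
        # zero-width plateau candidates are filtered by the width criterion
        warnings.filterwarnings("ignore", message="some peaks have a width of 0")
        idx, props = find_peaks(clean, height=min_height, width=min_width)
    peaks: list[CREPeak] = []
    for i, p in enumerate(idx):
        s = int(np.floor(props["left_ips"][i]))
        e = int(np.ceil(props["right_ips"][i])) + 1
        summit = int(p)
        if e - s < min_peak_size:
            half = min_peak_size // 2
            s = summit - half
            e = s + min_peak_size
            # clip at window edges, preserving width where possible
            if s < 0:
                s, e = 0, min(min_peak_size, len(clean))
            if e > len(clean):
                e = len(clean)
                s = max(0, e - min_peak_size)
        peaks.append(
            CREPeak(s + lo, e + lo, summit + lo, float(clean[summit]))
        )
    return _merge_peaks(peaks)


def _merge_peaks(peaks: list[CREPeak]) -> list[CREPeak]:
    if not peaks:
        return []
    peaks = sorted(peaks, key=lambda p: p.start)
    merged: list[CREPeak] = [peaks[0]]
    for p in peaks[1:]:
        last = merged[-1]
        if p.start < last.end:
            top = p if p.height > last.height else last
            merged[-1] = CREPeak(
                last.start, max(last.end, p.end), top.summit, top.height,
                last.label, last.gene_id,
            )
        else:
            merged.append(p)
    return merged


def read_cre_accessibility(
    fiber_span: Interval,
    accessible: list[Interval],
    peak: CREPeak,
    threshold: float = 0.5,
) -> bool | None:
    """Binary per-read CRE accessibility call.

    True iff >= `threshold` of the peak's bp fall inside the fiber's
    accessible regions; None when the fiber does not span the peak
    (excluded from downstream matrices).
    """
    if not (fiber_span[0] <= peak.start and fiber_span[1] >= peak.end):
        return None
    return covered_fraction(accessible, peak.interval) >= threshold


def access_matrix(
    fibers_accessible: list[tuple[str, Interval, list[Interval]]],
    peaks: list[CREPeak],
    threshold: float = 0.5,
) -> tuple[list[str], np.ndarray]:
    """Per-read CRE accessibility matrix over fibers spanning every peak.

    Returns (fiber ids, matrix of 0/1 with one column per peak).
    """
    ids, rows = [], []
    for fiber_id, span, regions in fibers_accessible:
        calls = [read_cre_accessibility(span, regions, p, threshold) for p in peaks]
        if any(c is None for c in calls):
            continue
        ids.append(fiber_id)
        rows.append([int(c) for c in calls])
    return ids, np.asarray(rows, dtype=int).reshape(len(ids), len(peaks))
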