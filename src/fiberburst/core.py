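"""Shared genomic record types and interval arithmetic.

All coordinates are 0-based half-open (BED convention) throughout the
package; genomic and fiber-relative coordinates never mix within one
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Interval = tuple[int, int]

#: default distance from the TSS at which the gene body starts (pause region
#: is [TSS, TSS+200), matching the pause-site window used for track deciles)
BODY_OFFSET = 200
#: termination region extends this far past the annotated gene end
TERMINATION_LENGTH = 500
#: half-width of the promoter window centred on the TSS
PROMOTER_HALFWIDTH = 100
#: pause window downstream of the TSS
PAUSE_WINDOW = 50
#: window over which nucleosome eviction is assessed (from body start)
EVICTION_WINDOW = 1500


# ---------------------------------------------------------------------------
# interval helpers


def interval_length(iv: Interval) -> int:
    return max(0, iv[1] - iv[0])


def total_length(intervals) -> int:
    return sum(interval_length(iv) for iv in intervals)


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlaps(a: Interval, b: Interval) -> bool:
    return overlap_length(a, b) > 0


def merge_intervals(intervals) -> list[Interval]:
    """Merge overlapping or touching intervals into a sorted disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def complement(intervals, span: Interval) -> list[Interval]:
    """Gaps of `span` not covered by `intervals` (merged internally)."""
    out: list[Interval] = []
    cursor = span[0]
    for s, e in merge_intervals(intervals):
        s, e = max(s, span[0]), min(e, span[1])
        if e <= s:
            continue
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < span[1]:
        out.append((cursor, span[1]))
    return out


def covered_length(intervals, window: Interval) -> int:
    """Number of bp of `window` covered by the (possibly overlapping) intervals."""
    return total_length(
        (max(s, window[0]), min(e, window[1])) for s, e in merge_intervals(intervals)
    )


def covered_fraction(intervals, window: Interval) -> float:
    w = interval_length(window)
    if w == 0:
        return 0.0
    return covered_length(intervals, window) / w


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class Fiber:
    """One sequenced chromatin molecule with its per-position methylation calls.

    `methylated` holds fiber-relative offsets (ascending) of positions called
    methylated; only A/T reference positions ever carry calls.
    """

    fiber_id: str
    chrom: str
    start: int
    end: int
    strand: str
    methylated: tuple[int, ...] = ()

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.fiber_id}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.fiber_id}: strand must be + or -")
        length = self.end - self.start
        for off in self.methylated:
            if not 0 <= off < length:
                raise ValueError(
                    f"{self.fiber_id}: methylated offset {off} outside fiber of "
                    f"length {length}"
                )

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start

    def methylated_genomic(self) -> np.ndarray:
        return np.asarray(self.methylated, dtype=int) + self.start


@dataclass(frozen=True)
class GeneModel:
    """Annotated gene with strand-aware derived windows.

    `tss` and `tes` are genomic positions; for a minus-strand gene the TSS is
    the higher coordinate and "downstream" means decreasing coordinates.
    """

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.strand == "+" and self.tes <= self.tss:
            raise ValueError("plus-strand gene needs tes > tss")
        if self.strand == "-" and self.tes >= self.tss:
            raise ValueError("minus-strand gene needs tes < tss")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    def span(self) -> Interval:
        """Genomic interval [TSS, TES) irrespective of strand."""
        return (min(self.tss, self.tes), max(self.tss, self.tes))

    def promoter_window(self, halfwidth: int = PROMOTER_HALFWIDTH) -> Interval:
        return (self.tss - halfwidth, self.tss + halfwidth)

    def pause_window(self, width: int = PAUSE_WINDOW) -> Interval:
        if self.strand == "+":
            return (self.tss, self.tss + width)
        return (self.tss - width, self.tss)

    def body(self, offset: int = BODY_OFFSET) -> Interval:
        if self.strand == "+":
            return (min(self.tss + offset, self.tes), self.tes)
        return (self.tes, max(self.tss - offset, self.tes))

    def termination_region(self, length: int = TERMINATION_LENGTH) -> Interval:
        if self.strand == "+":
            return (self.tes, self.tes + length)
        return (self.tes - length, self.tes)

    def upstream_window(self, size: int) -> Interval:
        if self.strand == "+":
            return (self.tss - size, self.tss)
        return (self.tss, self.tss + size)

    def eviction_window(self, max_len: int = EVICTION_WINDOW,
                        body_offset: int = BODY_OFFSET) -> Interval:
        """First `max_len` bp of the gene body (shorter if the body is)."""
        b = self.body(body_offset)
        w = min(max_len, interval_length(b))
        if self.strand == "+":
            return (b[0], b[0] + w)
        return (b[1] - w, b[1])


@dataclass(frozen=True)
class CRE:
    """Candidate cis-regulatory element interval attached to a gene."""

    label: str
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"CRE {self.label}: end must exceed start")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class ClassifiedFootprint:
    """A decoded inaccessible segment with an assigned molecular identity."""

    fiber_id: str
    chrom: str
    start: int
    end: int
    klass: str  # nucleosome | polII | PIC | TF | unclassified
    evidence: str = ""

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start
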