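"""Assign molecular identities to decoded footprints.

Size/overlap rules, applied in precedence order PIC > Pol II > TF >
nucleosome (configurable):

* PIC       — 20-40 bp overlapping a TATA box, or 60-80 bp overlapping a TSS
* Pol II    — 40-60 bp overlapping nonzero nascent-transcription coverage
* TF        — <90 bp with no nascent-transcription overlap
* nucleosome — >90 bp, unless the TF-rescue rule re-labels a 90-200 bp
  footprint supported by >=50 reads carrying subnucleosomal footprints that
  align exactly with each of its ends

Accessible regions per fiber are the complement of nucleosome-class
footprints only; TF/Pol II/PIC footprints do not interrupt accessibility.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import (
    ClassifiedFootprint,
    Fiber,
    Interval,
    complement,
    overlaps,
)

log = logging.getLogger(__name__)

SUBNUCLEOSOMAL = 90  # bp; footprints strictly below this count as subnucleosomal


@dataclass
class ClassifyConfig:
    polII_size: tuple[int, int] = (40, 60)        # inclusive
    pic_tata_size: tuple[int, int] = (20, 40)     # inclusive
    pic_tss_size: tuple[int, int] = (60, 80)      # inclusive
    nucleosome_min: int = 90                      # exclusive (>90 bp)
    tf_rescue_range: tuple[int, int] = (90, 200)  # exclusive both ends
    tf_rescue_support: int = 50
    proseq_min_signal: float = 0.0                # coverage must exceed this
    rescue_joint: bool = False  # require the same reads to match both ends
    precedence: tuple[str, ...] = ("PIC", "polII", "TF")


class BoundarySupportIndex:
    """Counts, per exact coordinate, reads carrying subnucleosomal footprints
    starting (or ending) there. Used by the TF-rescue rule."""

    def __init__(self, footprints_by_fiber: dict[str, list[Interval]]):
        self.start_reads: dict[int, set[str]] = {}
        self.end_reads: dict[int, set[str]] = {}
        for fiber_id, fps in footprints_by_fiber.items():
            for s, e in fps:
                if e - s < SUBNUCLEOSOMAL:
                    self.start_reads.setdefault(s, set()).add(fiber_id)
                    self.end_reads.setdefault(e, set()).add(fiber_id)

    def support(self, iv: Interval, joint: bool = False) -> int:
        starts = self.start_reads.get(iv[0], set())
        ends = self.end_reads.get(iv[1], set())
        if joint:
            return len(starts & ends)
        return min(len(starts), len(ends))


def tf_rescue(
    fp: Interval,
    index: BoundarySupportIndex,
    min_support: int = 50,
    joint: bool = False,
) -> bool:
    """True iff a 90-200 bp footprint has exact-boundary subnucleosomal
    support from >= `min_support` reads at each end."""
    length = fp[1] - fp[0]
    lo, hi = 90, 200
    if not (lo < length < hi):
        return False
    return index.support(fp, joint=joint) >= min_support


def _proseq_overlap(track: np.ndarray | None, iv: Interval, min_signal: float) -> bool:
    if track is None:
        return False
    s, e = max(iv[0], 0), min(iv[1], len(track))
    if e <= s:
        return False
    return bool((track[s:e] > min_signal).any())


def classify_footprint(
    fp: Interval,
    fiber_id: str,
    chrom: str,
    proseq_track: np.ndarray | None,
    tata_sites: list[Interval],
    tss_sites: list[Interval],
    rescue_index: BoundarySupportIndex | None = None,
    config: ClassifyConfig | None = None,
) -> ClassifiedFootprint:
    cfg = config or ClassifyConfig()
    length = fp[1] - fp[0]

    def try_pic():
        lo, hi = cfg.pic_tata_size
        if lo <= length <= hi and any(overlaps(fp, t) for t in tata_sites):
            return f"{lo}-{hi}bp+TATA"
        lo, hi = cfg.pic_tss_size
        if lo <= length <= hi and any(overlaps(fp, t) for t in tss_sites):
            return f"{lo}-{hi}bp+TSS"
        return None

    def try_polii():
        lo, hi = cfg.polII_size
        if lo <= length <= hi and _proseq_overlap(proseq_track, fp, cfg.proseq_min_signal):
            return f"{lo}-{hi}bp+PROseq"
        return None

    def try_tf():
        if length < SUBNUCLEOSOMAL and not _proseq_overlap(
            proseq_track, fp, cfg.proseq_min_signal
        ):
            return "<90bp,no-PROseq"
        return None

    rules = {"PIC": try_pic, "polII": try_polii, "TF": try_tf}
    for name in cfg.precedence:
        tag = rules[name]()
        if tag is not None:
            return ClassifiedFootprint(fiber_id, chrom, fp[0], fp[1], name, tag)

    if length > cfg.nucleosome_min:
        if rescue_index is not None and tf_rescue(
            fp, rescue_index, cfg.tf_rescue_support, cfg.rescue_joint
        ):
            n = rescue_index.support(fp, joint=cfg.rescue_joint)
            return ClassifiedFootprint(
                fiber_id, chrom, fp[0], fp[1], "TF", f"TF-rescue:n={n}"
            )
        return ClassifiedFootprint(fiber_id, chrom, fp[0], fp[1], "nucleosome", ">90bp")

    return ClassifiedFootprint(fiber_id, chrom, fp[0], fp[1], "unclassified", "")


def classify_fiber_footprints(
    fiber: Fiber,
    footprints: list[Interval],
    proseq_track: np.ndarray | None,
    tata_sites: list[Interval],
    tss_sites: list[Interval],
    rescue_index: BoundarySupportIndex | None = None,
    config: ClassifyConfig | None = None,
) -> list[ClassifiedFootprint]:
    if proseq_track is None:
        log.warning("no nascent-transcription track: Pol II calls disabled")
    return [
        classify_footprint(
            fp,
            fiber.fiber_id,
            fiber.chrom,
            proseq_track,
            tata_sites,
            tss_sites,
            rescue_index,
            config,
        )
        for fp in sorted(footprints)
    ]


def accessible_regions(
    fiber: Fiber, classified: list[ClassifiedFootprint]
) -> list[Interval]:
    """Complement of nucleosome-class footprints within the fiber span."""
    nucs = [cf.interval for cf in classified if cf.klass == "nucleosome"]
    return complement(nucs, fiber.span)


def class_counts(classified: list[ClassifiedFootprint]) -> Counter:
    return Counter(cf.klass for cf in classified)
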