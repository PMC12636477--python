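"""PWM motif scanning with single-fiber footprint filtering.

Position frequency matrices are normalized with a pseudocount (default 0.8)
against a background distribution and converted to log2-odds position
weight matrices. Sequences are scanned base-by-base on both strands; per
position, scores are combined across a TF's motif variants by taking the
maximum, then thresholded (default >= 2.0). Hits are optionally filtered to
those overlapping a TF-class footprint on at least 5% of spanning fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Interval, overlaps

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
UNIFORM_BG = {b: 0.25 for b in BASES}
DEFAULT_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.8

#: default genome-wide activator / repressor motif sets
ACTIVATORS = ("bcd", "cad", "dl", "vfl")
REPRESSORS = ("hb", "Kr", "run", "odd")


@dataclass
class PWM:
    tf: str
    matrix: np.ndarray  # (length, 4) log2-odds
    name: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 1:
            raise ValueError("empty PWM")
        if not np.isfinite(self.matrix).all():
            raise ValueError("PWM entries must be finite (check pseudocount)")

    def __len__(self):
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


@dataclass
class MotifHit:
    tf: str
    pos: int
    strand: str
    score: float
    length: int

    @property
    def interval(self) -> Interval:
        return (self.pos, self.pos + self.length)


@dataclass
class MotifProfile:
    tf: str
    scores: np.ndarray  # per start position, max over variants and strands
    hits: list[MotifHit] = field(default_factory=list)


def pwm_from_pfm(
    pfm: np.ndarray,
    tf: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: dict[str, float] | None = None,
    name: str = "",
) -> PWM:
    """Log2-odds PWM from a (length, 4) or (4, length) counts matrix.

    Cell value: ``log2(((count + pc) / (colsum + 4*pc)) / background)``.
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or 4 not in pfm.shape:
        raise ValueError("PFM must have a base axis of size 4")
    if pfm.shape[0] == 4 and pfm.shape[1] != 4:
        pfm = pfm.T
    if pfm.size == 0 or pfm.shape[0] == 0:
        raise ValueError("PFM has no columns")
    if (pfm < 0).any():
        raise ValueError("PFM counts must be non-negative")
    if pseudocount <= 0 and (pfm == 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    bg = background or UNIFORM_BG
    bg_vec = np.array([bg[b] for b in BASES])
    colsum = pfm.sum(axis=1, keepdims=True)
    probs = (pfm + pseudocount) / (colsum + 4.0 * pseudocount)
    return PWM(tf, np.log2(probs / bg_vec), name or tf)


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, -1) for b in seq.upper()], dtype=int)


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    return m[::-1, ::-1]


def _variant_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score of the motif placed at each start position (length len(seq);
    -inf where the motif does not fit or covers a non-ACGT base)."""
    n, L = len(codes), matrix.shape[0]
    out = np.full(n, -np.inf)
    if n < L:
        return out
    n_pos = n - L + 1
    acc = np.zeros(n_pos)
    bad = np.zeros(n_pos, dtype=bool)
    for i in range(L):
        window = codes[i : i + n_pos]
        bad |= window < 0
        acc += matrix[i, np.clip(window, 0, 3)]
    acc[bad] = -np.inf
    out[:n_pos] = acc
    return out


def scan_sequence(
    seq: str,
    pwms: list[PWM],
    threshold: float = DEFAULT_THRESHOLD,
) -> MotifProfile:
    """Scan both strands with all of one TF's motif variants.

    Per start position the score is the max over variants and strands;
    positions scoring >= `threshold` become hits (strand/length taken from
    the best-scoring variant).
    """
    if not pwms:
        raise ValueError("no PWMs supplied")
    tfs = {p.tf for p in pwms}
    if len(tfs) > 1:
        raise ValueError(f"scan_sequence takes one TF's variants, got {sorted(tfs)}")
    tf = pwms[0].tf
    codes = _encode(seq)
    n = len(codes)
    best = np.full(n, -np.inf)
    best_len = np.zeros(n, dtype=int)
    best_strand = np.full(n, "+", dtype="<U1")
    for pwm in pwms:
        for strand, matrix in (("+", pwm.matrix), ("-", _revcomp_matrix(pwm.matrix))):
            s = _variant_scores(codes, matrix)
            upd = s > best
            best[upd] = s[upd]
            best_len[upd] = len(pwm)
            best_strand[upd] = strand
    hits = [
        MotifHit(tf, int(p), str(best_strand[p]), float(best[p]), int(best_len[p]))
        for p in np.nonzero(best >= threshold)[0]
    ]
    return MotifProfile(tf, best, hits)


def footprint_filter(
    profile: MotifProfile,
    fibers: list[tuple[Interval, list[Interval]]],
    min_fraction: float = 0.05,
) -> MotifProfile:
    """Keep hits overlapping a TF-class footprint on >= `min_fraction` of
    spanning fibers.

    `fibers` holds (fiber span, TF footprint intervals) in the same
    coordinate system as the profile. With no spanning fibers all hits are
    removed (warning).
    """
    import logging

    kept = []
    for hit in profile.hits:
        spanning = [
            fps
            for span, fps in fibers
            if span[0] <= hit.interval[0] and span[1] >= hit.interval[1]
        ]
        if not spanning:
            continue
        n_support = sum(
            1 for fps in spanning if any(overlaps(hit.interval, fp) for fp in fps)
        )
        if n_support / len(spanning) >= min_fraction:
            kept.append(hit)
    if not any(
        span[0] <= h.interval[0] and span[1] >= h.interval[1]
        for h in profile.hits
        for span, _ in fibers
    ) and profile.hits:
        logging.getLogger(__name__).warning(
            "%s: no fiber spans any hit; all hits removed", profile.tf
        )
    return MotifProfile(profile.tf, profile.scores, kept)


def cre_enrichment(
    profiles: dict[str, MotifProfile],
    cres: list[tuple[str, Interval]],
    scan_region: Interval,
) -> dict[str, dict[str, float]]:
    """Per-CRE, per-TF sum of retained hit intensities.

    CREs must lie within the scanned region; hit positions are relative to
    ``scan_region[0]``.
    """
    lo, hi = scan_region
    out: dict[str, dict[str, float]] = {}
    for label, (s, e) in cres:
        if s < lo or e > hi:
            raise ValueError(f"CRE {label} [{s},{e}) outside scanned region")
        row = {}
        for tf, profile in profiles.items():
            row[tf] = float(
                sum(h.score for h in profile.hits if s - lo <= h.pos < e - lo)
            )
        out[label] = row
    return out


def motif_balance(act_sum: float, rep_sum: float) -> float:
    """min/max ratio of summed activator vs repressor intensity; 0/0 -> 0."""
    act_sum, rep_sum = max(act_sum, 0.0), max(rep_sum, 0.0)
    hi = max(act_sum, rep_sum)
    if hi == 0:
        return 0.0
    return min(act_sum, rep_sum) / hi


def cre_balance(
    enrichment: dict[str, dict[str, float]],
    activators=ACTIVATORS,
    repressors=REPRESSORS,
) -> dict[str, float]:
    """Per-CRE activator/repressor balance from an enrichment matrix."""
    if set(activators) & set(repressors):
        raise ValueError("activator and repressor sets must be disjoint")
    out = {}
    for label, row in enrichment.items():
        act = sum(row.get(tf, 0.0) for tf in activators)
        rep = sum(row.get(tf, 0.0) for tf in repressors)
        out[label] = motif_balance(act, rep)
    return out
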