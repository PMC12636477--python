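"""Per-fiber transcription-state calling and burst kinetics.

Convoys are groups of two or more Pol II footprints within a gene body
separated edge-to-edge by at most 100 bp. State flags follow the strict
definition block (promoter/pause flags carry "no polymerase" exclusivity
clauses); burst classes split nucleosome-evicted fibers into active (>=1
convoy) and refractory (none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    BODY_OFFSET,
    EVICTION_WINDOW,
    PAUSE_WINDOW,
    PROMOTER_HALFWIDTH,
    TERMINATION_LENGTH,
    ClassifiedFootprint,
    Fiber,
    GeneModel,
    Interval,
    covered_fraction,
    covered_length,
    interval_length,
    overlaps,
)

log = logging.getLogger(__name__)

MAX_CONVOY_GAP = 100  # bp, edge-to-edge


@dataclass
class Convoy:
    fiber_id: str
    members: list[Interval]  # ordered Pol II footprint intervals
    center_spacings: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a convoy has at least two members")
        self.center_spacings = [
            (b[0] + b[1]) / 2 - (a[0] + a[1]) / 2
            for a, b in zip(self.members[:-1], self.members[1:])
        ]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> Interval:
        return (self.members[0][0], self.members[-1][1])


def detect_convoys(
    polII_footprints: list[Interval],
    gene_body: Interval,
    fiber_id: str = "",
    max_gap: int = MAX_CONVOY_GAP,
    gap_mode: str = "edge",
) -> list[Convoy]:
    """Chain Pol II footprints overlapping the gene body into convoys.

    Single-linkage by gap <= `max_gap`; singletons are not convoys.
    `gap_mode` "edge" measures end-of-one to start-of-next; "center"
    measures center-to-center.
    """
    fps = sorted(fp for fp in polII_footprints if overlaps(fp, gene_body))
    convoys: list[Convoy] = []
    group: list[Interval] = []
    for fp in fps:
        if not group:
            group = [fp]
            continue
        prev = group[-1]
        if gap_mode == "edge":
            gap = fp[0] - prev[1]
        elif gap_mode == "center":
            gap = (fp[0] + fp[1]) / 2 - (prev[0] + prev[1]) / 2
        else:
            raise ValueError(f"unknown gap_mode {gap_mode!r}")
        if gap <= max_gap:
            group.append(fp)
        else:
            if len(group) >= 2:
                convoys.append(Convoy(fiber_id, group))
            group = [fp]
    if len(group) >= 2:
        convoys.append(Convoy(fiber_id, group))
    return convoys


@dataclass
class StateCall:
    """Per-fiber, per-gene transcription-state flags and burst bookkeeping.

    Flags are evaluated independently; a flag is None when the fiber does
    not span the region it is assessed over (excluded from denominators).
    """

    fiber_id: str
    gene_id: str
    accessible_promoter: bool | None = None
    paused: bool | None = None
    elongating: bool | None = None
    hyperburst: bool | None = None
    terminating: bool | None = None
    nucleosome_eviction_fraction: float = 0.0
    n_polII: int = 0
    n_convoys: int = 0
    burst_class: str = "none"  # active | refractory | none

    FLAGS = ("accessible_promoter", "paused", "elongating", "hyperburst", "terminating")


def _spans(fiber: Fiber, iv: Interval) -> bool:
    return fiber.start <= iv[0] and fiber.end >= iv[1]


def assign_state(
    fiber: Fiber,
    gene: GeneModel,
    classified: list[ClassifiedFootprint],
    accessible: list[Interval],
    strict: bool = True,
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
    pause_window: int = PAUSE_WINDOW,
    body_offset: int = BODY_OFFSET,
    termination_length: int = TERMINATION_LENGTH,
    max_gap: int = MAX_CONVOY_GAP,
) -> StateCall:
    """Evaluate the five state flags for one fiber against one gene.

    `strict` enables the "no polymerase" exclusivity clauses on the
    promoter and pause flags (the definition block used for regression);
    disabling it reproduces the looser first-pass definitions.
    """
    call = StateCall(fiber.fiber_id, gene.gene_id)
    polII = [cf.interval for cf in classified if cf.klass == "polII"]
    nucs = [cf.interval for cf in classified if cf.klass == "nucleosome"]
    gene_span = gene.span()
    body = gene.body(body_offset)
    term = gene.termination_region(termination_length)
    pausew = gene.pause_window(pause_window)
    promw = gene.promoter_window(promoter_halfwidth)

    polII_on_gene = [fp for fp in polII if overlaps(fp, gene_span)]
    polII_in_body = [fp for fp in polII if overlaps(fp, body)]
    polII_in_term = [fp for fp in polII if overlaps(fp, term)]
    polII_in_pause = [fp for fp in polII if overlaps(fp, pausew)]

    if _spans(fiber, promw):
        open_bp = covered_length(accessible, promw)
        ok = open_bp >= 100
        if strict:
            ok = ok and not polII_on_gene
        call.accessible_promoter = ok

    if _spans(fiber, pausew):
        if polII_in_pause:
            mean_size = float(np.mean([interval_length(fp) for fp in polII_in_pause]))
            ok = 40 <= mean_size <= 60
            if strict:
                others = [fp for fp in polII_on_gene + polII_in_term
                          if fp not in polII_in_pause]
                ok = ok and not others
            call.paused = ok
        else:
            call.paused = False

    if _spans(fiber, body):
        call.elongating = len(polII_in_body) > 0
        call.hyperburst = covered_fraction(accessible, body) >= 0.5

    if _spans(fiber, term):
        call.terminating = len(polII_in_term) > 0

    evw = gene.eviction_window(EVICTION_WINDOW, body_offset)
    if _spans(fiber, evw):
        call.nucleosome_eviction_fraction = 1.0 - covered_fraction(nucs, evw)

    call.n_polII = len(polII_on_gene) + len(
        [fp for fp in polII_in_term if not overlaps(fp, gene_span)]
    )
    convoys = detect_convoys(polII, body, fiber.fiber_id, max_gap=max_gap)
    call.n_convoys = len(convoys)
    call.burst_class = classify_burst(call)
    return call


def classify_burst(call: StateCall, eviction_threshold: float = 0.5) -> str:
    """active / refractory / none from eviction fraction and convoy count."""
    if call.nucleosome_eviction_fraction >= eviction_threshold:
        return "active" if call.n_convoys >= 1 else "refractory"
    return "none"


def state_label(call: StateCall) -> str:
    """Collapse independent flags to a single label (used for ground-truth
    round-trips); priority: hyperburst/refractory > elongating > paused >
    terminating > off."""
    if call.hyperburst:
        return "hyperburst" if call.n_convoys >= 1 else "refractory"
    if call.elongating:
        return "elongating"
    if call.paused:
        return "poised"
    if call.terminating:
        return "terminating"
    return "off"


# ---------------------------------------------------------------------------
# kinetics


@dataclass
class KineticsSummary:
    gene_id: str
    on_rate: float
    amplitude: float
    on_rate_ci: tuple[float, float]
    amplitude_ci: tuple[float, float]
    per_bin: dict[str, dict] = field(default_factory=dict)
    flank_occupancy: dict[str, dict] | None = None
    degenerate: bool = False


def _bootstrap_ci(values: np.ndarray, statistic, n_boot: int, rng) -> tuple[float, float]:
    n = len(values)
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        stats_[b] = statistic(values[idx])
    lo, hi = np.percentile(stats_, [2.5, 97.5])
    return float(lo), float(hi)


def kinetics(
    gene: GeneModel,
    state_calls: list[StateCall],
    eviction_bins: list[tuple[float, float]] | None = None,
    convoys_by_fiber: dict[str, list[Convoy]] | None = None,
    nucleosomes_by_fiber: dict[str, list[Interval]] | None = None,
    fiber_spans: dict[str, Interval] | None = None,
    flank: int = 300,
    n_boot: int = 1000,
    seed: int = 0,
) -> KineticsSummary:
    """Gene-level burst kinetics.

    On-rate is the fraction of fibers with at least one convoy; amplitude is
    the mean Pol II footprint count per fiber. Both are reported overall and
    per nucleosome-eviction bin, with 95% percentile CIs from `n_boot`
    bootstrap resamplings of fibers and two-sided Mann-Whitney U p-values
    between adjacent bins (on per-fiber Pol II counts). When convoy and
    nucleosome footprint inventories are supplied, mean nucleosome occupancy
    over `flank` bp upstream/downstream of each convoy (promoter window
    excluded) is reported with bootstrap CIs.
    """
    rng = np.random.default_rng(seed)
    has_convoy = np.array([c.n_convoys >= 1 for c in state_calls], dtype=float)
    n_pol = np.array([c.n_polII for c in state_calls], dtype=float)
    evic = np.array([c.nucleosome_eviction_fraction for c in state_calls])
    if len(state_calls) == 0:
        raise ValueError("no state calls")

    on_rate = float(has_convoy.mean())
    amplitude = float(n_pol.mean())
    degenerate = len(set(has_convoy)) < 2
    on_ci = _bootstrap_ci(has_convoy, np.mean, n_boot, rng)
    amp_ci = _bootstrap_ci(n_pol, np.mean, n_boot, rng)
    if degenerate:
        log.warning("%s: all fibers share one convoy class; CI degenerate", gene.gene_id)

    per_bin: dict[str, dict] = {}
    if eviction_bins:
        prev_counts = None
        for lo, hi in eviction_bins:
            mask = (evic >= lo) & (evic < hi)
            key = f"[{lo:g},{hi:g})"
            if mask.sum() == 0:
                continue
            entry = {
                "n": int(mask.sum()),
                "on_rate": float(has_convoy[mask].mean()),
                "amplitude": float(n_pol[mask].mean()),
                "on_rate_ci": _bootstrap_ci(has_convoy[mask], np.mean, n_boot, rng),
                "amplitude_ci": _bootstrap_ci(n_pol[mask], np.mean, n_boot, rng),
            }
            if prev_counts is not None and len(prev_counts) and mask.sum():
                try:
                    u = stats.mannwhitneyu(
                        prev_counts, n_pol[mask], alternative="two-sided"
                    )
                    entry["p_vs_previous_bin"] = float(u.pvalue)
                except ValueError:
                    entry["p_vs_previous_bin"] = float("nan")
            prev_counts = n_pol[mask]
            per_bin[key] = entry

    flank_occ = None
    if convoys_by_fiber is not None and nucleosomes_by_fiber is not None:
        flank_occ = _flank_occupancy(
            gene, convoys_by_fiber, nucleosomes_by_fiber, fiber_spans or {},
            flank, n_boot, rng,
        )

    return KineticsSummary(
        gene.gene_id, on_rate, amplitude, on_ci, amp_ci, per_bin, flank_occ, degenerate
    )


def _flank_occupancy(gene, convoys_by_fiber, nucleosomes_by_fiber, fiber_spans,
                     flank, n_boot, rng):
    promw = gene.promoter_window()
    sides = {"upstream": [], "downstream": []}
    for fiber_id, convoys in convoys_by_fiber.items():
        nucs = nucleosomes_by_fiber.get(fiber_id, [])
        span = fiber_spans.get(fiber_id)
        for convoy in convoys:
            cs, ce = convoy.span
            for side, win in (
                ("upstream", (cs - flank, cs)),
                ("downstream", (ce, ce + flank)),
            ):
                if span is not None:
                    win = (max(win[0], span[0]), min(win[1], span[1]))
                # promoter region excluded from the assessed window
                pieces = [
                    iv
                    for iv in _subtract(win, promw)
                    if interval_length(iv) > 0
                ]
                tot = sum(interval_length(iv) for iv in pieces)
                if tot == 0:
                    continue
                cov = sum(covered_length(nucs, iv) for iv in pieces)
                sides[side].append(cov / tot)
    out = {}
    for side, vals in sides.items():
        arr = np.asarray(vals)
        if len(arr) == 0:
            out[side] = {"mean": float("nan"), "ci": (float("nan"), float("nan")), "n": 0}
        else:
            out[side] = {
                "mean": float(arr.mean()),
                "ci": _bootstrap_ci(arr, np.mean, n_boot, rng),
                "n": len(arr),
            }
    return out


def _subtract(iv: Interval, minus: Interval) -> list[Interval]:
    if iv[1] <= iv[0]:
        return []
    if not overlaps(iv, minus):
        return [iv]
    out = []
    if iv[0] < minus[0]:
        out.append((iv[0], minus[0]))
    if minus[1] < iv[1]:
        out.append((minus[1], iv[1]))
    return out


# ---------------------------------------------------------------------------
# live-imaging on-rate via Gaussian mixture


def gmm_on_rate(
    values: np.ndarray,
    posterior: float = 0.99,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-component 1-D Gaussian mixture threshold and active fraction.

    Fits by EM, then returns the smallest value at which the posterior of
    the high-mean component reaches `posterior`, and the fraction of
    measurements above that threshold.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(values, dtype=float).ravel()
    if len(np.unique(values)) < 2:
        raise ValueError("need at least two distinct values to fit a mixture")
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(values[:, None])
    means = gm.means_.ravel()
    if abs(means[0] - means[1]) < 1e-9:
        raise ValueError(f"mixture components collapsed (means {means})")
    if min(gm.weights_) < 1e-6:
        raise ValueError(f"mixture degenerate: weights {gm.weights_}")
    hi = int(np.argmax(means))
    grid = np.linspace(values.min(), values.max(), 20001)
    post = gm.predict_proba(grid[:, None])[:, hi]
    above = np.nonzero(post >= posterior)[0]
    if len(above) == 0:
        raise ValueError("no value reaches the posterior cutoff")
    threshold = float(grid[above[0]])
    active_fraction = float((values > threshold).mean())
    return threshold, active_fraction


# ---------------------------------------------------------------------------
# external-track concordance


def decile_concordance(
    gene_scores: dict[str, float],
    fiber_occupancies: dict[str, float],
    n_bins: int = 10,
) -> "np.ndarray":
    """Mean fiber occupancy per equal-count decile of external track signal.

    Genes are ranked by track signal (stable order for ties) and cut into
    `n_bins` equal-count bins; returns the mean occupancy per bin in
    ascending-signal order.
    """
    genes = sorted(gene_scores)
    if len(genes) < n_bins:
        raise ValueError(f"need >= {n_bins} genes")
    scores = np.array([gene_scores[g] for g in genes])
    occ = np.array([fiber_occupancies[g] for g in genes])
    order = np.argsort(scores, kind="stable")
    chunks = np.array_split(order, n_bins)
    return np.array([occ[c].mean() for c in chunks])
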