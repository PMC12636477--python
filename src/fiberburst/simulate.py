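"""Ground-truth fiber simulator.

Generates a reference genome, gene/CRE annotations, methylation-marked
fibers with planted nucleosome/Pol II/PIC/TF footprints, a matching
nascent-transcription coverage track, and two-population fluorescence
traces. Every downstream stage can therefore be verified against planted
truth; at degenerate methylation rates (1/0) footprint recovery is exact.

States and their planted structure:

* off         — fully nucleosome-tiled, no Pol II
* poised      — open promoter, PIC at the TATA box, one Pol II-sized
                footprint in the pause window, nothing in the body
* elongating  — open promoter, isolated Pol II singletons in the body
                (pairwise gaps > the convoy threshold)
* hyperburst  — gene body evicted of nucleosomes, Pol II convoys planted
                with configurable edge-to-edge gaps, PIC present
* refractory  — same eviction and upstream CRE accessibility as hyperburst
                but no Pol II and no PIC
* terminating — one Pol II just past the annotated gene end

Coordinates are 0-based half-open; genes are planted on the plus strand.
Methylation is simulated only at A/T positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BODY_OFFSET,
    PROMOTER_HALFWIDTH,
    CRE,
    Fiber,
    GeneModel,
    Interval,
    complement,
    covered_fraction,
    interval_length,
    merge_intervals,
    overlaps,
)

log = logging.getLogger(__name__)

STATES = ("off", "poised", "elongating", "hyperburst", "refractory", "terminating")

#: states simulated with a nucleosome-free promoter window
OPEN_PROMOTER_STATES = frozenset({"poised", "elongating", "hyperburst", "refractory"})
#: states simulated with a PIC footprint at the TATA box
PIC_STATES = frozenset({"poised", "elongating", "hyperburst"})

_DEFAULT_P_STATE = {
    "off": 0.30,
    "poised": 0.15,
    "elongating": 0.20,
    "hyperburst": 0.15,
    "refractory": 0.10,
    "terminating": 0.10,
}

_DEFAULT_CRE_LAYOUT = [
    # (offset from TSS, width, accessibility probability per state)
    (-6000, 200, {"off": 0.05, "poised": 0.3, "elongating": 0.5,
                  "hyperburst": 0.95, "refractory": 0.9, "terminating": 0.2}),
    (-3500, 150, {"off": 0.05, "poised": 0.5, "elongating": 0.6,
                  "hyperburst": 0.9, "refractory": 0.85, "terminating": 0.3}),
    (-1200, 150, {"off": 0.1, "poised": 0.7, "elongating": 0.7,
                   "hyperburst": 0.9, "refractory": 0.8, "terminating": 0.4}),
]


@dataclass
class SimConfig:
    genome_length: int = 40000
    n_genes: int = 1
    gene_length: int = 2000
    n_fibers_per_gene: int = 50
    nucleosome_size: int = 147
    linker_mean: int = 30
    linker_min: int = 5
    linker_max: int = 90
    polII_size_range: tuple[int, int] = (40, 60)
    convoy_gap_range: tuple[int, int] = (10, 20)
    p_state: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_P_STATE))
    cre_layout: list = field(default_factory=lambda: [tuple(t) for t in _DEFAULT_CRE_LAYOUT])
    meth_rate_accessible: float | dict[str, float] = 0.8
    meth_rate_inaccessible: float | dict[str, float] = 0.05
    upstream_window: int = 9000
    downstream_margin: int = 500
    gene_spacing: int = 1000
    tf_footprint_prob: float = 0.7
    tf_size_range: tuple[int, int] = (15, 40)
    body_offset: int = BODY_OFFSET
    seed: int = 0

    def __post_init__(self):
        if set(self.p_state) != set(STATES):
            raise ValueError(f"p_state must cover exactly {STATES}")
        probs = np.array([self.p_state[s] for s in STATES])
        if (probs < 0).any() or (probs > 1).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("p_state entries must be probabilities summing to 1")
        if self.nucleosome_size <= 90:
            raise ValueError("nucleosome_size must exceed 90 bp")
        lo, hi = self.polII_size_range
        if not (40 <= lo <= hi <= 60):
            raise ValueError("polII_size_range must lie within [40, 60]")
        glo, ghi = self.convoy_gap_range
        if not (0 < glo <= ghi <= 100):
            raise ValueError("convoy_gap_range must lie within (0, 100]")
        if not (self.linker_min <= self.linker_mean <= self.linker_max):
            raise ValueError("linker_mean must lie within [linker_min, linker_max]")
        for offset, width, p_access in self.cre_layout:
            if offset + width > -PROMOTER_HALFWIDTH - self.tf_size_range[1]:
                raise ValueError(
                    f"CRE at offset {offset} reaches into the promoter window"
                )
            if offset < -self.upstream_window:
                raise ValueError(
                    f"CRE offset {offset} outside the {self.upstream_window} bp "
                    "upstream window"
                )
            for p in self._access_probs(p_access).values():
                if not 0 <= p <= 1:
                    raise ValueError("CRE accessibility probabilities must be in [0,1]")

    @staticmethod
    def _access_probs(p_access) -> dict[str, float]:
        if isinstance(p_access, dict):
            return {s: float(p_access.get(s, 0.0)) for s in STATES}
        return {s: float(p_access) for s in STATES}

    def meth_rate(self, accessible: bool, kmer: str) -> float:
        table = self.meth_rate_accessible if accessible else self.meth_rate_inaccessible
        if isinstance(table, dict):
            return table.get(kmer, table.get(kmer[len(kmer) // 2], 0.0))
        return float(table)


@dataclass
class FiberTruth:
    fiber_id: str
    chrom: str
    start: int
    end: int
    strand: str
    planted_footprints: list[tuple[int, int, str]]
    true_state: str
    true_cre_access: dict[str, bool]

    def footprints_of(self, klass: str) -> list[Interval]:
        return [(s, e) for s, e, k in self.planted_footprints if k == klass]


@dataclass
class SimResult:
    config: SimConfig
    sequence: str
    chrom: str
    genes: list[GeneModel]
    cres: list[CRE]
    tata_sites: list[Interval]
    tss_sites: list[Interval]
    truths: list[FiberTruth]
    fibers: list[Fiber]
    proseq: np.ndarray


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[str, list[GeneModel], list[CRE], list[Interval], list[Interval]]:
    """Reference sequence plus gene, CRE, TATA and TSS annotations.

    Genes are laid out on the plus strand, each preceded by its full
    upstream regulatory window; a TATA box (TATAAA planted in the sequence)
    sits 30 bp upstream of each TSS.
    """
    rng = rng or np.random.default_rng(config.seed)
    slot = (
        config.upstream_window
        + config.gene_length
        + config.downstream_margin
        + config.gene_spacing
    )
    if config.genome_length < config.n_genes * slot:
        raise ValueError(
            f"genome_length {config.genome_length} too small for "
            f"{config.n_genes} genes needing {slot} bp each (would overlap)"
        )
    seq = rng.choice(list("ACGT"), size=config.genome_length)
    genes, cres, tata_sites, tss_sites = [], [], [], []
    for g in range(config.n_genes):
        tss = g * slot + config.upstream_window
        gene = GeneModel(f"gene{g}", "chrSim", tss, tss + config.gene_length, "+")
        genes.append(gene)
        seq[tss - 30 : tss - 24] = list("TATAAA")
        tata_sites.append((tss - 30, tss - 24))
        tss_sites.append((tss, tss + 1))
        intervals = []
        for i, (offset, width, _p) in enumerate(config.cre_layout):
            cre = CRE(f"{gene.gene_id}_cre{i}", gene.gene_id, "chrSim",
                      tss + offset, tss + offset + width)
            if any(overlaps(cre.interval, iv) for iv in intervals):
                raise ValueError("cre_layout intervals overlap")
            intervals.append(cre.interval)
            cres.append(cre)
    return "".join(seq), genes, cres, tata_sites, tss_sites


# ---------------------------------------------------------------------------
# fibers


def _sample_linker(config: SimConfig, rng) -> int:
    p = 1.0 / max(config.linker_mean - config.linker_min + 1, 1)
    raw = config.linker_min + rng.geometric(p) - 1
    return int(min(raw, config.linker_max))


def _sample_polII_size(config: SimConfig, rng) -> int:
    lo, hi = config.polII_size_range
    return int(rng.integers(lo, hi + 1))


def _place_singletons(body: Interval, n: int, config: SimConfig, rng,
                      min_gap: int = 150) -> list[Interval]:
    """Pol II singletons in the body with pairwise edge gaps > the convoy
    threshold so they never chain."""
    placed: list[Interval] = []
    for _ in range(200):
        if len(placed) >= n:
            break
        size = _sample_polII_size(config, rng)
        if body[1] - body[0] <= size:
            break
        s = int(rng.integers(body[0], body[1] - size))
        iv = (s, s + size)
        if all(abs(iv[0] - q[1]) > min_gap and abs(q[0] - iv[1]) > min_gap
               for q in placed):
            placed.append(iv)
    return sorted(placed)


def _place_convoys(window: Interval, n_convoys: int, config: SimConfig, rng
                   ) -> list[list[Interval]]:
    """Convoys of 2-4 Pol II footprints with edge gaps from convoy_gap_range,
    separated from each other by > 100 bp."""
    convoys: list[list[Interval]] = []
    cursor = window[0]
    for _ in range(n_convoys):
        size = int(rng.integers(2, 5))
        members = []
        pos = cursor + int(rng.integers(0, 50))
        for _m in range(size):
            w = _sample_polII_size(config, rng)
            if pos + w > window[1]:
                break
            members.append((pos, pos + w))
            gap = int(rng.integers(config.convoy_gap_range[0],
                                   config.convoy_gap_range[1] + 1))
            pos = pos + w + gap
        if len(members) >= 2:
            convoys.append(members)
        cursor = pos + 150  # > convoy threshold, keeps convoys distinct
        if cursor >= window[1]:
            break
    return convoys


def simulate_fiber(
    gene: GeneModel,
    state: str,
    config: SimConfig,
    rng: np.random.Generator,
    sequence: str,
    cres: list[CRE],
    tata_sites: list[Interval],
    fiber_id: str = "fiber",
) -> tuple[FiberTruth, Fiber]:
    """One fiber spanning the gene's regulatory window, with planted
    footprints consistent with `state` and Bernoulli methylation calls."""
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}")
    start = gene.tss - config.upstream_window
    end = gene.tes + config.downstream_margin
    span = (start, end)
    body = gene.body(config.body_offset)

    protected: list[Interval] = []  # forced accessible, no nucleosomes
    footprints: list[tuple[int, int, str]] = []

    if state in OPEN_PROMOTER_STATES:
        protected.append(gene.promoter_window())

    my_cres = [c for c in cres if c.gene_id == gene.gene_id]
    cre_access: dict[str, bool] = {}
    for cre, (offset, width, p_access) in zip(my_cres, config.cre_layout):
        p = SimConfig._access_probs(p_access)[state]
        accessible = bool(rng.random() < p)
        cre_access[cre.label] = accessible
        if accessible:
            protected.append(cre.interval)
            if rng.random() < config.tf_footprint_prob:
                tf_size = int(rng.integers(*config.tf_size_range))
                if cre.end - cre.start > tf_size:
                    s = int(rng.integers(cre.start, cre.end - tf_size))
                    footprints.append((s, s + tf_size, "TF"))

    if state in ("hyperburst", "refractory"):
        protected.append(body)  # full-body eviction (>50% of the 1.5 kb window)

    if state == "poised":
        size = _sample_polII_size(config, rng)
        s = gene.tss + 5
        footprints.append((s, s + size, "polII"))
        protected.append((s - 5, s + size + 5))
    elif state == "elongating":
        n = 1 + int(rng.random() < 0.4)
        for iv in _place_singletons(body, n, config, rng):
            footprints.append((iv[0], iv[1], "polII"))
            protected.append((iv[0] - 5, iv[1] + 5))
    elif state == "hyperburst":
        evw = gene.eviction_window(body_offset=config.body_offset)
        for convoy in _place_convoys(evw, int(rng.integers(1, 3)), config, rng):
            for iv in convoy:
                footprints.append((iv[0], iv[1], "polII"))
    elif state == "terminating":
        term = gene.termination_region()
        size = _sample_polII_size(config, rng)
        s = int(rng.integers(term[0] + 10, term[1] - size))
        footprints.append((s, s + size, "polII"))
        protected.append((s - 5, s + size + 5))

    if state in PIC_STATES:
        tata = next(t for t in tata_sites if overlaps(t, (gene.tss - 60, gene.tss)))
        pic = (tata[0] - 5, tata[0] + 25)  # 30 bp over the TATA box
        footprints.append((pic[0], pic[1], "PIC"))
        protected.append((pic[0] - 5, pic[1] + 5))

    blocked = merge_intervals(
        protected + [(s, e) for s, e, _ in footprints]
    )
    footprints.extend(
        (s, e, "nucleosome")
        for s, e in _tile_nucleosomes(span, blocked, config, rng)
    )
    footprints.sort()

    truth = FiberTruth(fiber_id, gene.chrom, start, end, "+",
                       footprints, state, cre_access)
    _check_truth(truth, gene, config)

    meth = _draw_methylation(span, footprints, sequence, config, rng)
    fiber = Fiber(fiber_id, gene.chrom, start, end, "+", tuple(meth))
    return truth, fiber


def _tile_nucleosomes(span: Interval, blocked: list[Interval],
                      config: SimConfig, rng) -> list[Interval]:
    """Left-to-right tiling with sampled linkers, skipping blocked intervals."""
    nucs = []
    pos = span[0] + _sample_linker(config, rng) - config.linker_min
    nsize = config.nucleosome_size
    while pos + nsize <= span[1]:
        iv = (pos, pos + nsize)
        hit = next((b for b in blocked if overlaps(iv, b)), None)
        if hit is not None:
            # re-tile tightly after an obstacle so planted footprints do not
            # open large spurious accessible gaps
            pos = hit[1] + config.linker_min
            continue
        nucs.append(iv)
        pos += nsize + _sample_linker(config, rng)
    return nucs


def _check_truth(truth: FiberTruth, gene: GeneModel, config: SimConfig) -> None:
    ivs = sorted((s, e) for s, e, _ in truth.planted_footprints)
    for a, b in zip(ivs[:-1], ivs[1:]):
        if a[1] > b[0]:
            raise AssertionError(f"planted footprints overlap: {a} vs {b}")
    if truth.true_state in ("hyperburst", "refractory"):
        evw = gene.eviction_window(body_offset=config.body_offset)
        occ = covered_fraction(truth.footprints_of("nucleosome"), evw)
        if occ >= 0.5:
            raise AssertionError("hyperburst fiber with >=50% eviction-window occupancy")


def _draw_methylation(span, footprints, sequence, config, rng) -> list[int]:
    n = span[1] - span[0]
    sub = np.array(list(sequence[span[0] : span[1]].upper()))
    offsets = np.nonzero((sub == "A") | (sub == "T"))[0]
    accessible = np.ones(n, dtype=bool)
    for s, e, _ in footprints:
        accessible[max(s - span[0], 0) : max(e - span[0], 0)] = False
    flat = not (
        isinstance(config.meth_rate_accessible, dict)
        or isinstance(config.meth_rate_inaccessible, dict)
    )
    if flat:
        rates = np.where(
            accessible[offsets],
            float(config.meth_rate_accessible),
            float(config.meth_rate_inaccessible),
        )
    else:
        rates = np.empty(len(offsets))
        for i, off in enumerate(offsets):
            g = span[0] + int(off)
            kmer = sequence[g - 3 : g + 4].upper() if g >= 3 else "N" * 7
            rates[i] = config.meth_rate(bool(accessible[off]), kmer)
    draws = rng.random(len(offsets))
    return [int(o) for o in offsets[draws < rates]]


# ---------------------------------------------------------------------------
# dataset


def simulate_dataset(config: SimConfig) -> SimResult:
    """Fully deterministic dataset for the configured seed."""
    rng = np.random.default_rng(config.seed)
    sequence, genes, cres, tata_sites, tss_sites = simulate_genome(config, rng)
    truths, fibers = [], []
    p = np.array([config.p_state[s] for s in STATES])
    for gene in genes:
        for i in range(config.n_fibers_per_gene):
            state = STATES[rng.choice(len(STATES), p=p)]
            truth, fiber = simulate_fiber(
                gene, state, config, rng, sequence, cres, tata_sites,
                fiber_id=f"{gene.gene_id}_f{i}",
            )
            truths.append(truth)
            fibers.append(fiber)
    proseq = simulate_proseq(config.genome_length, truths)
    return SimResult(config, sequence, "chrSim", genes, cres, tata_sites,
                     tss_sites, truths, fibers, proseq)


def simulate_proseq(
    genome_length: int,
    truths: list[FiberTruth],
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-bp count of planted Pol II footprints covering each position,
    plus optional uniform noise."""
    track = np.zeros(genome_length)
    for truth in truths:
        for s, e in truth.footprints_of("polII"):
            track[max(s, 0) : min(e, genome_length)] += 1
    if noise_level > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        track += rng.uniform(0, noise_level, genome_length)
    return track


def simulate_fluorescence(
    n_cells: int,
    n_timepoints: int,
    active_fraction: float,
    mu_off: float,
    mu_on: float,
    sd: float,
    seed: int = 0,
):
    """Two-population fluorescence trace table.

    Each measurement is drawn from a two-component Gaussian mixture with
    mixing weight `active_fraction` on the high component; truth labels are
    retained in the `active` column. Returns a pandas DataFrame with
    columns cell_id, timepoint, value, active.
    """
    import pandas as pd

    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0 <= active_fraction <= 1:
        raise ValueError("active_fraction must lie in [0, 1]")
    if mu_on <= mu_off:
        raise ValueError("mu_on must exceed mu_off")
    rng = np.random.default_rng(seed)
    n = n_cells * n_timepoints
    active = rng.random(n) < active_fraction
    values = rng.normal(np.where(active, mu_on, mu_off), sd)
    return pd.DataFrame(
        {
            "cell_id": np.repeat([f"cell{i}" for i in range(n_cells)], n_timepoints),
            "timepoint": np.tile(np.arange(n_timepoints), n_cells),
            "value": values,
            "active": active.astype(int),
        }
    )
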