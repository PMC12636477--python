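"""Two-state (accessible/inaccessible) HMM decoding of per-fiber methylation.

Emissions are conditioned on the 7-mer sequence context (center base plus
+/- 3 bp) of each A/T position. Non-A/T positions carry no methylation call
and are skipped by the chain; decoded state runs are then projected back
onto genomic coordinates so segments tile the full fiber span.

All chain arithmetic is in log space: fibers are tens of kb long and
linear-space products underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Fiber, Interval

log = logging.getLogger(__name__)

ACCESSIBLE, INACCESSIBLE = 0, 1
STATE_NAMES = ("accessible", "inaccessible")
_AT = frozenset("AT")


# ---------------------------------------------------------------------------
# emissions


@dataclass
class EmissionTable:
    """Context-conditioned methylation probabilities per hidden state.

    `table` maps a 7-mer (uppercase, center base A or T) to
    (P(methylated | accessible), P(methylated | inaccessible)). Lookups fall
    back 7-mer -> center base -> global rate; each fallback is logged once.
    """

    table: dict[str, tuple[float, float]]
    center_rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    global_rate: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        self._warned: set[str] = set()
        for k, (pa, pi) in self.table.items():
            if not (0.0 < pa < 1.0 and 0.0 < pi < 1.0):
                raise ValueError(
                    f"emission probabilities for {k!r} must lie in (0,1); "
                    f"got ({pa}, {pi}) — apply smoothing"
                )

    @classmethod
    def flat(cls, p_accessible: float, p_inaccessible: float) -> "EmissionTable":
        """Context-independent table (same rate for every 7-mer)."""
        rate = (float(p_accessible), float(p_inaccessible))
        return cls(table={}, center_rates={"A": rate, "T": rate}, global_rate=rate)

    def lookup(self, kmer: str) -> tuple[float, float]:
        kmer = kmer.upper()
        if kmer in self.table:
            return self.table[kmer]
        center = kmer[len(kmer) // 2] if kmer else ""
        if center in self.center_rates:
            if kmer not in self._warned:
                self._warned.add(kmer)
                log.debug("7-mer %s not in table; falling back to center base", kmer)
            return self.center_rates[center]
        if kmer not in self._warned:
            self._warned.add(kmer)
            log.debug("context %s unresolvable; falling back to global rate", kmer)
        return self.global_rate


def build_emission_table(
    accessible_counts: dict[str, tuple[int, int]],
    inaccessible_counts: dict[str, tuple[int, int]],
    pseudocount: float = 1.0,
) -> EmissionTable:
    """Estimate context-conditioned methylation rates from two control sets.

    Each control supplies, per 7-mer, (methylated, total) observation counts:
    one from fully accessible (dechromatinized) DNA, one from unmethylated
    (untreated) DNA. Rates are smoothed as
    ``(methylated + pseudocount) / (total + 2 * pseudocount)``.

    A 7-mer present in only one control falls back to center-base rates.
    """
    if not accessible_counts or not inaccessible_counts:
        raise ValueError("both control count sets must be non-empty")

    def rate(counts, k):
        m, t = counts[k]
        return (m + pseudocount) / (t + 2.0 * pseudocount)

    def center_rate(counts):
        agg: dict[str, list[int]] = {}
        for k, (m, t) in counts.items():
            c = k[len(k) // 2]
            agg.setdefault(c, [0, 0])
            agg[c][0] += m
            agg[c][1] += t
        return {
            c: (m + pseudocount) / (t + 2.0 * pseudocount) for c, (m, t) in agg.items()
        }

    shared = set(accessible_counts) & set(inaccessible_counts)
    dropped = (set(accessible_counts) | set(inaccessible_counts)) - shared
    if dropped:
        log.info(
            "%d 7-mers present in only one control; center-base fallback applies",
            len(dropped),
        )
    table = {
        k: (rate(accessible_counts, k), rate(inaccessible_counts, k)) for k in shared
    }

    acc_c, inacc_c = center_rate(accessible_counts), center_rate(inaccessible_counts)
    centers = {
        c: (acc_c[c], inacc_c[c]) for c in set(acc_c) & set(inacc_c)
    }
    am = sum(m for m, _ in accessible_counts.values())
    at = sum(t for _, t in accessible_counts.values())
    im = sum(m for m, _ in inaccessible_counts.values())
    it = sum(t for _, t in inaccessible_counts.values())
    glob = (
        (am + pseudocount) / (at + 2.0 * pseudocount),
        (im + pseudocount) / (it + 2.0 * pseudocount),
    )
    return EmissionTable(table=table, center_rates=centers, global_rate=glob)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class HMMParams:
    """Start probabilities, 2x2 transition matrix and an emission table."""

    start: np.ndarray
    transitions: np.ndarray
    emissions: EmissionTable
    converged: bool = True

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.start.shape != (2,) or self.transitions.shape != (2, 2):
            raise ValueError("expected 2-state parameters")
        if not np.isclose(self.start.sum(), 1.0):
            raise ValueError("start probabilities must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if (self.start <= 0).any() or (self.transitions <= 0).any():
            raise ValueError("all probabilities must be positive")


@dataclass(frozen=True)
class FootprintSegment:
    start: int
    end: int
    state: str  # "accessible" | "inaccessible"


# ---------------------------------------------------------------------------
# observation extraction


def informative_positions(fiber: Fiber, sequence: str) -> tuple[np.ndarray, list[str]]:
    """Fiber-relative offsets of A/T positions and their 7-mer contexts.

    `sequence` is the reference sequence of the fiber's chromosome. Contexts
    at chromosome edges are padded with N (resolved via fallback).
    """
    offsets = []
    kmers = []
    meth = set(fiber.methylated)
    for off in range(len(fiber)):
        g = fiber.start + off
        base = sequence[g].upper() if 0 <= g < len(sequence) else "N"
        if base not in _AT:
            if off in meth:
                raise ValueError(
                    f"{fiber.fiber_id}: methylation call at non-A/T offset {off}"
                )
            continue
        lo, hi = g - 3, g + 4
        kmer = "".join(
            sequence[p].upper() if 0 <= p < len(sequence) else "N"
            for p in range(lo, hi)
        )
        offsets.append(off)
        kmers.append(kmer)
    return np.asarray(offsets, dtype=int), kmers


def _log_emissions(
    fiber: Fiber, offsets: np.ndarray, kmers: list[str], emissions: EmissionTable
) -> np.ndarray:
    """(n_positions, 2) log P(observation | state) at each informative position."""
    meth = np.zeros(len(offsets), dtype=bool)
    meth_set = set(fiber.methylated)
    for i, off in enumerate(offsets):
        meth[i] = off in meth_set
    out = np.empty((len(offsets), 2))
    for i, kmer in enumerate(kmers):
        pa, pi = emissions.lookup(kmer)
        if meth[i]:
            out[i, ACCESSIBLE] = np.log(pa)
            out[i, INACCESSIBLE] = np.log(pi)
        else:
            out[i, ACCESSIBLE] = np.log1p(-pa)
            out[i, INACCESSIBLE] = np.log1p(-pi)
    return out


# ---------------------------------------------------------------------------
# decoding


def viterbi_path(logB: np.ndarray, params: HMMParams) -> np.ndarray:
    """MAP state sequence over the informative-position chain."""
    n = logB.shape[0]
    log_pi = np.log(params.start)
    log_T = np.log(params.transitions)
    delta = log_pi + logB[0]
    back = np.zeros((n, 2), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + log_T  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + logB[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def forward_backward(logB: np.ndarray, params: HMMParams):
    """Scaled forward-backward.

    Returns (posteriors (n,2), log-likelihood, alpha_hat, beta_hat, scales)
    where alpha_hat/beta_hat are the per-step normalized quantities.
    """
    n = logB.shape[0]
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    logB_max = logB.max(axis=1)
    T = params.transitions
    alpha = np.empty((n, 2))
    scales = np.empty(n)
    alpha[0] = params.start * B[0]
    scales[0] = alpha[0].sum()
    alpha[0] /= scales[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ T) * B[t]
        scales[t] = alpha[t].sum()
        alpha[t] /= scales[t]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (T @ (B[t + 1] * beta[t + 1])) / scales[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.log(scales).sum() + logB_max.sum())
    return post, loglik, alpha, beta, scales


def _states_to_segments(
    fiber: Fiber, offsets: np.ndarray, path: np.ndarray
) -> list[FootprintSegment]:
    """Project per-informative-position states to segments tiling the fiber.

    State changes between informative positions place the boundary at the
    midpoint of the uninformative gap (the exact change point is
    unobservable there); positions outside the informative range adopt the
    nearest state.
    """
    segments: list[FootprintSegment] = []
    boundaries = [fiber.start]
    states = [int(path[0])]
    for i in range(1, len(path)):
        if path[i] != path[i - 1]:
            prev_g, next_g = int(offsets[i - 1]), int(offsets[i])
            boundaries.append(fiber.start + (prev_g + 1 + next_g + 1) // 2)
            states.append(int(path[i]))
    boundaries.append(fiber.end)
    for s, lo, hi in zip(states, boundaries[:-1], boundaries[1:]):
        segments.append(FootprintSegment(lo, hi, STATE_NAMES[s]))
    return segments


def decode_fiber(
    fiber: Fiber,
    sequence: str,
    params: HMMParams,
    decoder: str = "viterbi",
) -> list[FootprintSegment]:
    """Decode one fiber into alternating accessible/inaccessible segments.

    `decoder` is "viterbi" (MAP path, default) or "posterior" (per-position
    argmax of forward-backward posteriors). A fiber with zero informative
    positions decodes to a single segment in the prior-dominant state.
    """
    offsets, kmers = informative_positions(fiber, sequence)
    if len(offsets) == 0:
        log.warning("%s: no informative positions; prior-dominant segment", fiber.fiber_id)
        s = int(np.argmax(params.start))
        return [FootprintSegment(fiber.start, fiber.end, STATE_NAMES[s])]
    logB = _log_emissions(fiber, offsets, kmers, params.emissions)
    if decoder == "viterbi":
        path = viterbi_path(logB, params)
    elif decoder == "posterior":
        post, _, _, _, _ = forward_backward(logB, params)
        path = np.argmax(post, axis=1)
    else:
        raise ValueError(f"unknown decoder {decoder!r}")
    return _states_to_segments(fiber, offsets, path)


def footprints_from_path(
    segments: list[FootprintSegment],
) -> tuple[list[Interval], list[Interval]]:
    """Split a decoded segment path into (footprints, accessible gaps).

    Footprints are the maximal inaccessible runs.
    """
    fps = [(s.start, s.end) for s in segments if s.state == "inaccessible"]
    gaps = [(s.start, s.end) for s in segments if s.state == "accessible"]
    return fps, gaps


# ---------------------------------------------------------------------------
# training


def train_hmm(
    fibers: list[Fiber],
    sequence: str,
    emissions: EmissionTable,
    n_restarts: int = 3,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> HMMParams:
    """Baum-Welch EM over start/transition probabilities, emissions fixed.

    Each restart is initialized from flat Dirichlet (all-ones) draws; the
    highest-likelihood restart wins. If EM fails to converge within
    `max_iter` the best iterate is returned with ``converged=False``.
    """
    obs = []
    for f in fibers:
        offsets, kmers = informative_positions(f, sequence)
        if len(offsets) >= 2:
            obs.append(_log_emissions(f, offsets, kmers, emissions))
    if not obs:
        raise ValueError("need at least one fiber with >=2 informative positions")

    rng = np.random.default_rng(seed)
    best: HMMParams | None = None
    best_ll = -np.inf
    for _ in range(n_restarts):
        pi = rng.dirichlet(np.ones(2))
        T = np.vstack([rng.dirichlet(np.ones(2)) for _ in range(2)])
        pi = np.clip(pi, 1e-6, None)
        T = np.clip(T, 1e-6, None)
        pi /= pi.sum()
        T /= T.sum(axis=1, keepdims=True)
        params = HMMParams(pi, T, emissions)
        prev_ll = -np.inf
        converged = False
        for _it in range(max_iter):
            ll, pi_new, T_new = _em_step(obs, params)
            params = HMMParams(pi_new, T_new, emissions)
            if ll - prev_ll < tol and _it > 0:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        if not converged:
            log.warning("EM did not converge in %d iterations", max_iter)
        if prev_ll > best_ll:
            best_ll = prev_ll
            params.converged = converged
            best = params
    assert best is not None
    return best


def _em_step(obs: list[np.ndarray], params: HMMParams):
    """One Baum-Welch E+M step; returns (loglik under current params, pi, T)."""
    T = params.transitions
    gamma0 = np.zeros(2)
    xi_sum = np.zeros((2, 2))
    gamma_sum = np.zeros(2)
    total_ll = 0.0
    for logB in obs:
        post, ll, alpha, beta, scales = forward_backward(logB, params)
        total_ll += ll
        gamma0 += post[0]
        B = np.exp(logB - logB.max(axis=1, keepdims=True))
        n = logB.shape[0]
        for t in range(n - 1):
            xi = (
                alpha[t][:, None]
                * T
                * (B[t + 1] * beta[t + 1])[None, :]
                / scales[t + 1]
            )
            xi_sum += xi
        gamma_sum += post[:-1].sum(axis=0)
    pi_new = gamma0 / gamma0.sum()
    T_new = xi_sum / np.maximum(gamma_sum[:, None], 1e-300)
    pi_new = np.clip(pi_new, 1e-9, None)
    T_new = np.clip(T_new, 1e-9, None)
    pi_new /= pi_new.sum()
    T_new /= T_new.sum(axis=1, keepdims=True)
    return total_ll, pi_new, T_new


def em_loglik_trace(
    fibers: list[Fiber],
    sequence: str,
    params0: HMMParams,
    n_iter: int = 20,
) -> list[float]:
    """Log-likelihood before each EM step starting from `params0` (for checks)."""
    obs = []
    for f in fibers:
        offsets, kmers = informative_positions(f, sequence)
        if len(offsets) >= 2:
            obs.append(_log_emissions(f, offsets, kmers, params0.emissions))
    trace = []
    params = params0
    for _ in range(n_iter):
        ll, pi, T = _em_step(obs, params)
        trace.append(ll)
        params = HMMParams(pi, T, params.emissions)
    return trace
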