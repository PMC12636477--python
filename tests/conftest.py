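import numpy as np
import pytest

from fiberburst import classify, hmm
from fiberburst.pipeline import default_hmm_params
from fiberburst.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def degenerate_sim():
    """Small dataset at near-degenerate methylation rates: footprint recovery
    is essentially exact, so planted truth round-trips through the decoder."""
    cfg = SimConfig(
        seed=11,
        n_fibers_per_gene=30,
        meth_rate_accessible=0.999,
        meth_rate_inaccessible=0.001,
        linker_min=10,
        convoy_gap_range=(10, 20),
        polII_size_range=(45, 55),  # margin for +-1 bp decode jitter
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def degenerate_decoded(degenerate_sim):
    """Decoded + classified footprints for the degenerate dataset."""
    sim = degenerate_sim
    params = default_hmm_params(0.999, 0.001, stay=0.99)
    fp_by_fiber = {}
    for fiber in sim.fibers:
        segs = hmm.decode_fiber(fiber, sim.sequence, params)
        fps, _ = hmm.footprints_from_path(segs)
        fp_by_fiber[fiber.fiber_id] = fps
    index = classify.BoundarySupportIndex(fp_by_fiber)
    classified = {
        fiber.fiber_id: classify.classify_fiber_footprints(
            fiber,
            fp_by_fiber[fiber.fiber_id],
            sim.proseq,
            sim.tata_sites,
            sim.tss_sites,
            index,
        )
        for fiber in sim.fibers
    }
    return fp_by_fiber, classified


def brute_force_viterbi(logB: np.ndarray, start: np.ndarray, T: np.ndarray):
    """Exhaustive argmax over all 2^L state paths (oracle)."""
    n = logB.shape[0]
    log_pi, log_T = np.log(start), np.log(T)
    best_score, best_path = -np.inf, None
    for mask in range(2**n):
        path = [(mask >> t) & 1 for t in range(n)]
        score = log_pi[path[0]] + logB[0, path[0]]
        for t in range(1, n):
            score += log_T[path[t - 1], path[t]] + logB[t, path[t]]
        if score > best_score:
            best_score, best_path = score, path
    return best_score, best_path
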