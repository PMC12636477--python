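"""File-driven pipeline stages and the end-to-end runner.

Each stage reads its inputs from the configured output directory (written
by earlier stages), so stages are individually re-runnable and idempotent
for a fixed seed. `run_pipeline` chains them and halts with the failing
stage's name on error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as classify_mod
from . import hmm, motifs as motifs_mod, peaks as peaks_mod, regress, states as states_mod
from . import trajectory as traj_mod
from .core import Fiber, GeneModel
from .io import (
    PipelineConfig,
    read_bed6,
    read_bedgraph,
    read_fasta,
    read_fiber_table,
    read_genes_gff3,
    read_jaspar_pfms,
    write_bed6,
    write_bedgraph,
    write_fasta,
    write_fiber_table,
    write_genes_gff3,
)
from .simulate import SimConfig, simulate_dataset, simulate_fluorescence

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "footprints",
    "classify",
    "states",
    "peaks",
    "regress",
    "trajectory",
    "motifs",
)


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    params = dict(cfg.simulate)
    fluor_params = params.pop("fluorescence", {})
    sim = simulate_dataset(SimConfig(seed=cfg.seed, **params))
    write_fasta(out / "reference.fa", {sim.chrom: sim.sequence})
    write_genes_gff3(out / "genes.gff3", sim.genes)
    write_bed6(
        out / "cres.bed",
        [(c.chrom, c.start, c.end, c.label, 0, "+") for c in sim.cres],
    )
    write_bed6(
        out / "tata.bed",
        [(sim.chrom, s, e, f"tata{i}", 0, "+") for i, (s, e) in enumerate(sim.tata_sites)],
    )
    write_bed6(
        out / "tss.bed",
        [(sim.chrom, s, e, f"tss{i}", 0, "+") for i, (s, e) in enumerate(sim.tss_sites)],
    )
    write_fiber_table(out / "fibers.tsv", sim.fibers, seed=cfg.seed, params=params)
    truth_rows = [
        {
            "fiber_id": t.fiber_id,
            "chrom": t.chrom,
            "start": t.start,
            "end": t.end,
            "strand": t.strand,
            "true_state": t.true_state,
            "footprints": ";".join(f"{s}-{e}:{k}" for s, e, k in t.planted_footprints),
            "cre_access": ";".join(
                f"{k}={int(v)}" for k, v in sorted(t.true_cre_access.items())
            ),
        }
        for t in sim.truths
    ]
    _write_tsv(out / "truth.tsv", pd.DataFrame(truth_rows))
    write_bedgraph(out / "proseq.bedgraph", sim.chrom, sim.proseq)
    fluor = simulate_fluorescence(
        n_cells=fluor_params.get("n_cells", 200),
        n_timepoints=fluor_params.get("n_timepoints", 20),
        active_fraction=fluor_params.get("active_fraction", 0.16),
        mu_off=fluor_params.get("mu_off", 0.0),
        mu_on=fluor_params.get("mu_on", 10.0),
        sd=fluor_params.get("sd", 1.0),
        seed=cfg.seed,
    )
    _write_tsv(out / "fluorescence.tsv", fluor)
    return {"fibers": len(sim.fibers), "genes": len(sim.genes), "cres": len(sim.cres)}


def default_hmm_params(
    p_accessible: float = 0.8,
    p_inaccessible: float = 0.05,
    stay: float = 0.99,
) -> hmm.HMMParams:
    """Flat-emission sticky-transition parameters used when no trained model
    is supplied."""
    emissions = hmm.EmissionTable.flat(p_accessible, p_inaccessible)
    T = np.array([[stay, 1 - stay], [1 - stay, stay]])
    return hmm.HMMParams(np.array([0.5, 0.5]), T, emissions)


def stage_footprints(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    p = cfg.footprints
    fibers = read_fiber_table(out / "fibers.tsv")
    sequence = next(iter(read_fasta(out / "reference.fa").values()))
    params = default_hmm_params(
        p.get("p_accessible", 0.8), p.get("p_inaccessible", 0.05), p.get("stay", 0.99)
    )
    if p.get("train", False):
        params = hmm.train_hmm(
            fibers, sequence, params.emissions,
            n_restarts=p.get("restarts", 3), seed=cfg.seed,
        )
    decoder = p.get("decoder", "viterbi")
    seg_rows, bed_rows = [], []
    for fiber in fibers:
        segments = hmm.decode_fiber(fiber, sequence, params, decoder=decoder)
        for seg in segments:
            seg_rows.append(
                {
                    "fiber_id": fiber.fiber_id,
                    "chrom": fiber.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "state": seg.state,
                }
            )
            if seg.state == "inaccessible":
                bed_rows.append(
                    (fiber.chrom, seg.start, seg.end, fiber.fiber_id,
                     min(seg.end - seg.start, 1000), fiber.strand)
                )
    _write_tsv(out / "segments.tsv", pd.DataFrame(seg_rows))
    write_bed6(out / "footprints.bed", bed_rows)
    return {"fibers": len(fibers), "footprints": len(bed_rows)}


def _load_segments(out: Path):
    seg = pd.read_csv(out / "segments.tsv", sep="\t")
    footprints: dict[str, list] = {}
    spans: dict[str, tuple] = {}
    for fiber_id, grp in seg.groupby("fiber_id", sort=False):
        footprints[fiber_id] = [
            (int(r.start), int(r.end))
            for r in grp.itertuples()
            if r.state == "inaccessible"
        ]
        spans[fiber_id] = (int(grp.start.min()), int(grp.end.max()))
    chroms = dict(zip(seg.fiber_id, seg.chrom))
    return footprints, spans, chroms


def stage_classify(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    footprints, spans, chroms = _load_segments(out)
    sequence = next(iter(read_fasta(out / "reference.fa").values()))
    proseq = read_bedgraph(out / "proseq.bedgraph", len(sequence))
    tata = [(s, e) for _, s, e, *_ in read_bed6(out / "tata.bed")]
    tss = [(s, e) for _, s, e, *_ in read_bed6(out / "tss.bed")]
    ccfg = classify_mod.ClassifyConfig(
        tf_rescue_support=cfg.classify.get("tf_rescue_support", 50),
        proseq_min_signal=cfg.classify.get("proseq_min_signal", 0.0),
    )
    index = classify_mod.BoundarySupportIndex(footprints)
    rows = []
    for fiber_id, fps in footprints.items():
        for fp in fps:
            cf = classify_mod.classify_footprint(
                fp, fiber_id, chroms[fiber_id], proseq, tata, tss, index, ccfg
            )
            rows.append(
                {
                    "fiber_id": cf.fiber_id,
                    "chrom": cf.chrom,
                    "start": cf.start,
                    "end": cf.end,
                    "class": cf.klass,
                    "evidence": cf.evidence,
                }
            )
    _write_tsv(out / "classified.tsv", pd.DataFrame(rows))
    return {"classified": len(rows)}


def _load_classified(out: Path):
    df = pd.read_csv(out / "classified.tsv", sep="\t", keep_default_na=False)
    df = df.rename(columns={"class": "klass"})
    by_fiber: dict[str, list] = {}
    for r in df.itertuples():
        by_fiber.setdefault(r.fiber_id, []).append(
            classify_mod.ClassifiedFootprint(
                r.fiber_id, r.chrom, int(r.start), int(r.end), r.klass, r.evidence
            )
        )
    return by_fiber


def stage_states(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    genes = read_genes_gff3(out / "genes.gff3")
    by_fiber = _load_classified(out)
    _, spans, _ = _load_segments(out)
    p = cfg.states
    call_rows, convoy_rows = [], []
    kin_all = {}
    for gene in genes:
        calls = []
        conv_by_fiber, nuc_by_fiber, span_by_fiber = {}, {}, {}
        for fiber_id, classified in by_fiber.items():
            span = spans[fiber_id]
            if not (span[0] <= gene.span()[0] and span[1] >= gene.span()[1]):
                continue
            fiber = Fiber(fiber_id, gene.chrom, span[0], span[1], "+")
            accessible = classify_mod.accessible_regions(fiber, classified)
            call = states_mod.assign_state(
                fiber, gene, classified, accessible,
                strict=p.get("strict", True),
                max_gap=p.get("max_gap", 100),
            )
            calls.append(call)
            polII = [cf.interval for cf in classified if cf.klass == "polII"]
            convs = states_mod.detect_convoys(
                polII, gene.body(), fiber_id, max_gap=p.get("max_gap", 100)
            )
            conv_by_fiber[fiber_id] = convs
            nuc_by_fiber[fiber_id] = [
                cf.interval for cf in classified if cf.klass == "nucleosome"
            ]
            span_by_fiber[fiber_id] = span
            for c in convs:
                convoy_rows.append(
                    (gene.chrom, c.span[0], c.span[1],
                     f"{fiber_id}:n={c.size}", min(c.size * 100, 1000), "+")
                )
            call_rows.append(
                {
                    "fiber_id": fiber_id,
                    "gene_id": gene.gene_id,
                    **{
                        flag: ("" if getattr(call, flag) is None else int(getattr(call, flag)))
                        for flag in states_mod.StateCall.FLAGS
                    },
                    "eviction_fraction": call.nucleosome_eviction_fraction,
                    "n_polII": call.n_polII,
                    "n_convoys": call.n_convoys,
                    "burst_class": call.burst_class,
                }
            )
        if calls:
            bins = [(0.0, 0.4), (0.4, 0.8), (0.8, 1.01)]
            kin = states_mod.kinetics(
                gene, calls, eviction_bins=bins,
                convoys_by_fiber=conv_by_fiber,
                nucleosomes_by_fiber=nuc_by_fiber,
                fiber_spans=span_by_fiber,
                n_boot=p.get("bootstrap_reps", 1000),
                seed=cfg.seed,
            )
            kin_all[gene.gene_id] = asdict(kin)
    fluor_path = out / "fluorescence.tsv"
    if fluor_path.exists():
        fluor = pd.read_csv(fluor_path, sep="\t")
        try:
            thr, frac = states_mod.gmm_on_rate(fluor["value"].values, seed=cfg.seed)
            kin_all["_fluorescence"] = {"threshold": thr, "active_fraction": frac}
        except ValueError as exc:
            log.warning("fluorescence GMM failed: %s", exc)
    _write_tsv(out / "state_calls.tsv", pd.DataFrame(call_rows))
    write_bed6(out / "convoys.bed", convoy_rows)
    (out / "kinetics.json").write_text(json.dumps(kin_all, indent=2, default=list))
    return {"state_calls": len(call_rows), "convoys": len(convoy_rows)}


def stage_peaks(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    genes = read_genes_gff3(out / "genes.gff3")
    by_fiber = _load_classified(out)
    _, spans, _ = _load_segments(out)
    p = cfg.peaks
    window_size = p.get("window", 10000)
    peak_rows = []
    matrices = {}
    for gene in genes:
        win = gene.upstream_window(window_size)
        win = (max(win[0], 0), win[1])
        entries = []
        for fiber_id, classified in by_fiber.items():
            span = spans[fiber_id]
            fiber = Fiber(fiber_id, gene.chrom, span[0], span[1], "+")
            acc = classify_mod.accessible_regions(fiber, classified)
            entries.append((fiber_id, span, acc))
        overlapping = [
            (fid, sp, acc) for fid, sp, acc in entries
            if sp[0] < win[1] and sp[1] > win[0]
        ]
        if not overlapping:
            continue
        trace = peaks_mod.aggregate_trace([(sp, acc) for _, sp, acc in overlapping], win)
        trace = peaks_mod.preprocess_trace(
            trace,
            smooth=p.get("smooth", 51),
            subtract_baseline=p.get("subtract_baseline", True),
        )
        found = peaks_mod.call_peaks(
            trace, win,
            min_width=p.get("min_width", 20),
            height_frac=p.get("height_frac", 0.2),
        )
        for i, pk in enumerate(found):
            pk.label = f"{gene.gene_id}_P{i}"
            pk.gene_id = gene.gene_id
            peak_rows.append(
                (gene.chrom, pk.start, pk.end, pk.label, round(pk.height * 1000), "+")
            )
        ids, mat = peaks_mod.access_matrix(
            overlapping, found, threshold=p.get("access_threshold", 0.5)
        )
        if found:
            matrices[gene.gene_id] = pd.DataFrame(
                mat, index=pd.Index(ids, name="fiber_id"),
                columns=[pk.label for pk in found],
            )
    write_bed6(out / "peaks.bed", peak_rows)
    if matrices:
        combined = pd.concat(matrices.values(), axis=0)
        combined.reset_index().to_csv(out / "access_matrix.tsv", sep="\t", index=False)
    else:
        (out / "access_matrix.tsv").write_text("fiber_id\n")
    return {"peaks": len(peak_rows)}


def stage_regress(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    p = cfg.regress
    calls = pd.read_csv(out / "state_calls.tsv", sep="\t")
    access = pd.read_csv(out / "access_matrix.tsv", sep="\t").set_index("fiber_id")
    genes = read_genes_gff3(out / "genes.gff3")
    cre_bed = read_bed6(out / "peaks.bed")
    feature_window = p.get("feature_window", 9000)
    eval_rows, coef_rows, drop_rows, syn_rows = [], [], [], []
    for gene in genes:
        gcalls = calls[calls.gene_id == gene.gene_id].set_index("fiber_id")
        win = gene.upstream_window(feature_window)
        feats = [
            name for _, s, e, name, _, _ in cre_bed
            if name in access.columns and s < win[1] and e > win[0]
            and name.startswith(gene.gene_id)
        ]
        if not feats:
            continue
        shared = [f for f in gcalls.index if f in access.index]
        X_df = access.loc[shared, feats]
        flags = {
            flag: [
                None if pd.isna(v) else bool(v)
                for v in gcalls.loc[shared, flag]
            ]
            for flag in states_mod.StateCall.FLAGS
        }
        per_state = regress.build_feature_matrix(X_df.values, feats, flags)
        for state, (X, y) in per_state.items():
            try:
                model, ev = regress.fit_and_evaluate(
                    X, y, k=p.get("k_folds", 5),
                    n_permutations=p.get("n_perm", 50),
                    seed=cfg.seed, gene_id=gene.gene_id, state=state,
                    feature_names=feats,
                )
            except ValueError as exc:
                log.info("%s/%s skipped: %s", gene.gene_id, state, exc)
                continue
            eval_rows.append(
                {
                    "gene_id": gene.gene_id, "state": state, "n": len(y),
                    "auc": ev.auc, "average_precision": ev.average_precision,
                    "delta_auc": ev.delta_auc,
                    "null_mean": float(ev.null_aucs.mean()),
                    "null_sd": float(ev.null_aucs.std()),
                    "k": ev.k_used,
                }
            )
            for name, beta in zip(model.feature_names, model.coefficients):
                coef_rows.append(
                    {"gene_id": gene.gene_id, "state": state,
                     "feature": name, "coefficient": beta}
                )
            for name, d in ev.dropout_delta_auc.items():
                drop_rows.append(
                    {"gene_id": gene.gene_id, "state": state,
                     "feature": name, "delta_auc": d,
                     "single_auc": ev.single_feature_aucs[name]}
                )
            folds = regress.make_folds(y, p.get("k_folds", 5), cfg.seed)
            ks = tuple(k for k in p.get("synergy_k", [2]) if k <= X.shape[1])
            if ks:
                for res in regress.synergy_scan(
                    X, y, folds, feats, ev.auc, ev.dropout_delta_auc,
                    ks=ks, seed=cfg.seed,
                ):
                    syn_rows.append(
                        {"gene_id": gene.gene_id, "state": state,
                         "subset": "+".join(res.subset), "k": res.k,
                         "synergy": res.synergy,
                         "delta_auc_subset": res.delta_auc_subset}
                    )
    _write_tsv(out / "regression.tsv", pd.DataFrame(eval_rows))
    _write_tsv(out / "coefficients.tsv", pd.DataFrame(coef_rows))
    _write_tsv(out / "dropout.tsv", pd.DataFrame(drop_rows))
    _write_tsv(out / "synergy.tsv", pd.DataFrame(syn_rows))
    return {"models": len(eval_rows)}


def stage_trajectory(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    p = cfg.trajectory
    access = pd.read_csv(out / "access_matrix.tsv", sep="\t").set_index("fiber_id")
    elements = p.get("elements") or list(access.columns)
    if not elements:
        (out / "combos.tsv").write_text("vector\tcount\n")
        (out / "routes.tsv").write_text("rank\tsupport\tnodes\n")
        return {"nodes": 0, "routes": 0}
    vectors = [tuple(int(v) for v in row) for row in access[elements].values]
    nodes = traj_mod.tabulate_combos(
        vectors, min_support_fraction=p.get("min_support", 0.01)
    )
    _write_tsv(
        out / "combos.tsv",
        pd.DataFrame(
            {"vector": ["".join(map(str, n.vector)) for n in nodes],
             "count": [n.count for n in nodes]}
        ),
    )
    n_el = len(elements)
    initial = tuple(p.get("initial", [0] * n_el))
    peak = tuple(p.get("peak", [1] * n_el))
    terminals = [tuple(t) for t in p.get(
        "terminals",
        [[1 if j == i else 0 for j in range(n_el)] for i in range(n_el)],
    )]
    try:
        routes = traj_mod.enumerate_routes(nodes, initial, peak, terminals)
    except ValueError as exc:
        log.warning("trajectory anchors unavailable: %s", exc)
        routes = []
    _write_tsv(
        out / "routes.tsv",
        pd.DataFrame(
            {
                "rank": range(1, len(routes) + 1),
                "support": [r.support for r in routes],
                "nodes": [
                    ">".join("".join(map(str, v)) for v in r.nodes) for r in routes
                ],
            }
        ),
    )
    if routes:
        read_vectors = dict(zip(access.index, vectors))
        staged = traj_mod.annotate_stages(routes[0], read_vectors)
        _write_tsv(
            out / "stages.tsv",
            pd.DataFrame(
                [{"stage": k, "n_fibers": len(v)} for k, v in staged.items()]
            ),
        )
    return {"nodes": len(nodes), "routes": len(routes)}


def stage_motifs(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    p = cfg.motifs
    sequence = next(iter(read_fasta(out / "reference.fa").values()))
    genes = read_genes_gff3(out / "genes.gff3")
    cre_bed = read_bed6(out / "cres.bed")
    by_fiber = _load_classified(out)
    _, spans, _ = _load_segments(out)
    pfm_path = p.get("pfm_file")
    if pfm_path is None:
        from importlib.resources import files

        pfm_path = str(files("fiberburst.data") / "pfms.jaspar")
    pfms_by_tf: dict[str, list] = {}
    for name, counts in read_jaspar_pfms(pfm_path):
        tf = name.split(".")[0]
        pfms_by_tf.setdefault(tf, []).append(
            motifs_mod.pwm_from_pfm(counts, tf, p.get("pseudocount", 0.8), name=name)
        )
    threshold = p.get("threshold", 2.0)
    min_frac = p.get("min_footprint_frac", 0.05)
    hit_rows, enr_rows, bal_rows = [], [], []
    for gene in genes:
        region = gene.upstream_window(p.get("window", 9000))
        region = (max(region[0], 0), region[1])
        seq = sequence[region[0] : region[1]]
        fiber_tfs = []
        for fiber_id, classified in by_fiber.items():
            span = spans[fiber_id]
            tf_fps = [
                (cf.start - region[0], cf.end - region[0])
                for cf in classified
                if cf.klass == "TF" and cf.start < region[1] and cf.end > region[0]
            ]
            fiber_tfs.append(((span[0] - region[0], span[1] - region[0]), tf_fps))
        profiles = {}
        for tf, pwms in pfms_by_tf.items():
            prof = motifs_mod.scan_sequence(seq, pwms, threshold=threshold)
            prof = motifs_mod.footprint_filter(prof, fiber_tfs, min_fraction=min_frac)
            profiles[tf] = prof
            for hit in prof.hits:
                hit_rows.append(
                    (gene.chrom, region[0] + hit.pos,
                     region[0] + hit.pos + hit.length, tf,
                     min(round(hit.score * 100), 1000), hit.strand)
                )
        gene_cres = [
            (name, (s, e)) for _, s, e, name, _, _ in cre_bed
            if region[0] <= s and e <= region[1]
        ]
        enrichment = motifs_mod.cre_enrichment(profiles, gene_cres, region)
        acts = tuple(t for t in motifs_mod.ACTIVATORS if t in pfms_by_tf)
        reps = tuple(t for t in motifs_mod.REPRESSORS if t in pfms_by_tf)
        balance = motifs_mod.cre_balance(enrichment, acts, reps)
        for label, row in enrichment.items():
            for tf, v in row.items():
                enr_rows.append({"cre": label, "tf": tf, "intensity": v})
            bal_rows.append({"cre": label, "balance": balance[label]})
    write_bed6(out / "motif_hits.bed", hit_rows)
    _write_tsv(out / "motif_enrichment.tsv", pd.DataFrame(enr_rows))
    _write_tsv(out / "motif_balance.tsv", pd.DataFrame(bal_rows))
    return {"hits": len(hit_rows)}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "footprints": stage_footprints,
    "classify": stage_classify,
    "states": stage_states,
    "peaks": stage_peaks,
    "regress": stage_regress,
    "trajectory": stage_trajectory,
    "motifs": stage_motifs,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> int:
    """Execute the requested stages in order; returns 0 on success.

    A stage failure halts the pipeline and re-raises with the stage name.
    The effective configuration and a machine-readable run summary are
    written alongside the outputs.
    """
    out = _out(cfg)
    cfg.write(out / "config_used.yaml")
    summary: dict[str, dict] = {"seed": {"value": cfg.seed}}
    for stage in stages:
        log.info("stage %s starting", stage)
        try:
            counts = STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc
        summary[stage] = counts
        log.info("stage %s done: %s", stage, counts)
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return 0
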