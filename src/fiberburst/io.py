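"""Readers and writers for the pipeline's on-disk formats.

All genomic records use 0-based half-open coordinates and always carry a
strand column. Stochastic outputs carry a ``# seed=... params=<hash>``
header comment for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CRE, Fiber, GeneModel, Interval

log = logging.getLogger(__name__)

FIBER_COLUMNS = ["fiber_id", "chrom", "start", "end", "strand", "methylated_offsets"]


def params_hash(params: dict) -> str:
    return hashlib.md5(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _provenance_line(seed: int | None, params: dict | None) -> str | None:
    if seed is None:
        return None
    return f"# seed={seed} params={params_hash(params or {})}"


# ---------------------------------------------------------------------------
# fiber methylation TSV


def write_fiber_table(
    path, fibers: list[Fiber], seed: int | None = None, params: dict | None = None
) -> None:
    """Fiber table: one row per fiber, methylated offsets comma-separated,
    fiber-relative, ascending."""
    lines = []
    prov = _provenance_line(seed, params)
    if prov:
        lines.append(prov)
    lines.append("\t".join(FIBER_COLUMNS))
    for f in fibers:
        offs = ",".join(str(o) for o in f.methylated)
        lines.append(f"{f.fiber_id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{offs}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fiber_table(path) -> list[Fiber]:
    """Parse and validate a fiber methylation TSV.

    Malformed rows raise with their line number.
    """
    fibers = []
    header = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header != FIBER_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {FIBER_COLUMNS}, got {header}"
                    )
                continue
            parts = line.split("\t")
            if len(parts) not in (5, 6):
                raise ValueError(f"{path}:{lineno}: expected 5-6 columns")
            fiber_id, chrom, start, end, strand = parts[:5]
            offs_field = parts[5] if len(parts) == 6 else ""
            try:
                start_i, end_i = int(start), int(end)
                offs = tuple(int(x) for x in offs_field.split(",") if x != "")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if any(b < a for a, b in zip(offs[:-1], offs[1:])):
                raise ValueError(f"{path}:{lineno}: offsets must be ascending")
            try:
                fibers.append(Fiber(fiber_id, chrom, start_i, end_i, strand, offs))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if header is None:
        raise ValueError(f"{path}: empty file")
    return fibers


# ---------------------------------------------------------------------------
# FASTA / BED / GFF3 / bedGraph


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed6(path, records: list[tuple], header: str | None = None) -> None:
    """records: (chrom, start, end, name, score, strand); score clipped to
    the UCSC 0-1000 range."""
    lines = [header] if header else []
    for chrom, start, end, name, score, strand in records:
        score = int(min(max(round(score), 0), 1000))
        lines.append(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed6(path) -> list[tuple]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        c, s, e, n, sc, st = line.split("\t")[:6]
        out.append((c, int(s), int(e), n, float(sc), st))
    return out


def write_genes_gff3(path, genes: list[GeneModel]) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lo, hi = g.span()
        lines.append(
            f"{g.chrom}\tfiberburst\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genes_gff3(path) -> list[GeneModel]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, ftype, start, end, _score, strand, _frame, attrs = line.split("\t")
        if ftype != "gene":
            continue
        gene_id = dict(kv.split("=") for kv in attrs.split(";"))["ID"]
        lo, hi = int(start) - 1, int(end)
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        genes.append(GeneModel(gene_id, chrom, tss, tes, strand))
    return genes


def write_bedgraph(path, chrom: str, track: np.ndarray,
                   header: str | None = None) -> None:
    """Run-length-compressed bedGraph of a per-bp track (zero runs skipped)."""
    lines = [header] if header else []
    track = np.asarray(track)
    if len(track):
        change = np.nonzero(np.diff(track))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(track)]])
        for s, e in zip(starts, ends):
            v = track[s]
            if v != 0:
                val = int(v) if float(v).is_integer() else float(v)
                lines.append(f"{chrom}\t{s}\t{e}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bedgraph(path, length: int, chrom: str | None = None) -> np.ndarray:
    track = np.zeros(length)
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        c, s, e, v = line.split("\t")
        if chrom is not None and c != chrom:
            continue
        track[int(s) : int(e)] = float(v)
    return track


# ---------------------------------------------------------------------------
# JASPAR PFMs


def read_jaspar_pfms(path) -> list[tuple[str, np.ndarray]]:
    """(name, (length, 4) counts matrix) per motif in a JASPAR-format file."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            out.append((m.name, counts))
    return out


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Validated stage parameters; unknown keys are rejected."""

    outdir: str = "fiberburst_out"
    seed: int = 0
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    footprints: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    states: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    regress: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    motifs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
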