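# fiberburst

Single-molecule chromatin-fiber analysis: decode methylation-marked fibers
into protein footprints with a two-state sequence-context HMM, classify
footprints (nucleosome / Pol II / PIC / TF), detect Pol II convoys and
hyperburst/refractory transcription states, discover candidate CREs from
aggregate accessibility, model per-fiber transcription state from CRE
accessibility with L1 logistic regression (dropout ΔAUC and subset
synergy), order CRE-accessibility combinations into regulatory
trajectories, and scan CRE sequences for footprint-supported TF motifs.

A fully deterministic synthetic-fiber generator plants ground-truth
nucleosome arrays, Pol II convoys, PIC/TF footprints, state-dependent CRE
accessibility, a matching nascent-transcription coverage track, and
two-population fluorescence traces, so every stage is verifiable against
planted truth without any external data.

## Layout

| module | role |
| --- | --- |
| `fiberburst.simulate` | ground-truth genomes, fibers, tracks, fluorescence |
| `fiberburst.hmm` | two-state context-conditioned footprint HMM (Viterbi / posterior, Baum–Welch) |
| `fiberburst.classify` | footprint identity rules incl. TF-rescue of merged footprints |
| `fiberburst.states` | convoys, state flags, burst classes, kinetics, GMM on-rate, decile concordance |
| `fiberburst.peaks` | aggregate accessibility traces and CRE peak calling |
| `fiberburst.regress` | per-state logistic models, OOF AUC, permutation nulls, dropout ΔAUC, synergy |
| `fiberburst.trajectory` | CRE-combination graph and route enumeration |
| `fiberburst.motifs` | log-odds PWM scanning with single-fiber footprint filtering |
| `fiberburst.io` / `fiberburst.pipeline` / `fiberburst.cli` | formats, stage orchestration, CLI |

## CLI

One subcommand per stage plus `run` for the whole pipeline; every
subcommand takes `--config` (YAML), `--seed`, and `--outdir`:

```sh
fiberburst run --seed 1 --outdir out/
fiberburst simulate --config config.yaml --seed 1 --outdir out/
```

Example config:

```yaml
seed: 1
outdir: out
simulate:
  n_fibers_per_gene: 50
states:
  bootstrap_reps: 1000
regress:
  k_folds: 5
  n_perm: 50
```

All genomic records are 0-based half-open (BED convention). The canonical
fiber input is a TSV (`fiber_id chrom start end strand
methylated_offsets`) with comma-separated fiber-relative methylated
positions; reference FASTA, gene GFF3, CRE/TSS/TATA BED6, and
nascent-transcription bedGraph round out the inputs. Stage outputs are
plain TSV/BED/JSON and are byte-identical across reruns for a fixed seed.

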