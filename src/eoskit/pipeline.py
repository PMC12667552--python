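"""End-to-end orchestration: simulate -> extract -> analyze -> consensus -> decode.

A :class:`RunConfig` selects stages and carries every parameter; each run
writes per-stage artifacts plus a single flat key-value summary and a
copy of the resolved configuration, so any stage can be re-run from its
predecessor's output with identical results.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import consensus as consensus_mod
from . import read_processing, simulate
from .simulate import ErrorModel, ReadLayout, SimulationRun
from .storage_codec import BaseMap

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    out_dir: str
    # stage selection
    do_simulate: bool = True
    do_extract: bool = True
    do_analyze: bool = True
    do_consensus: bool = True
    do_decode: bool = True
    # simulation
    target: str = ""
    n_reads: int = 1000
    seed: int | None = None
    p_del: float = 0.0
    p_sub: float = 0.0
    p_ins: float = 0.0
    seq_error_rate: float = 0.0
    read_format: str = "fasta"
    # inputs when simulation is disabled
    reads_path: str | None = None
    # layout / codec
    anchor5: str | None = None
    tail_length: int = 20
    base_map: str = "GTCA"
    # consensus
    consensus_mode: str = "conditional"  # or "global"

    def layout(self) -> ReadLayout:
        if self.anchor5 is None:
            return ReadLayout(tail_length=self.tail_length)
        return ReadLayout(anchor5=self.anchor5, tail_length=self.tail_length)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and write artifacts.

    Returns the summary dictionary (also written to ``summary.json`` in
    ``out_dir`` together with the resolved config). Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    timings: dict[str, float] = {}

    if cfg.do_simulate and cfg.seed is None:
        raise PipelineError("simulate: a seed is mandatory when simulation is enabled")
    if cfg.do_simulate and not cfg.target:
        raise PipelineError("simulate: a target sequence is required")
    if cfg.do_decode and not cfg.do_consensus:
        raise PipelineError("decode: requires the consensus stage (no consensus input)")

    def _stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"{name}: {exc}") from exc

        return _Timer()

    reads = None
    reads_path = Path(cfg.reads_path) if cfg.reads_path else None
    if cfg.do_simulate:
        with _stage("simulate"):
            run = SimulationRun(
                target=cfg.target,
                n_reads=cfg.n_reads,
                seed=cfg.seed,
                model=ErrorModel(
                    p_del=cfg.p_del,
                    p_sub=cfg.p_sub,
                    p_ins=cfg.p_ins,
                    seq_error_rate=cfg.seq_error_rate,
                ),
                layout=cfg.layout(),
            )
            reads = simulate.simulate_run(run)
            ext = "fq" if cfg.read_format == "fastq" else "fa"
            reads_path = out / f"reads.{ext}"
            simulate.write_reads(reads, reads_path, cfg.read_format)
            summary["n_reads_simulated"] = len(reads)
            summary["seed"] = cfg.seed

    payloads = None
    if cfg.do_extract:
        with _stage("extract"):
            if reads is not None:
                records = [(r.read_id, r.sequence) for r in reads]
            elif reads_path is not None:
                records = simulate.read_sequences(reads_path)
            else:
                raise PipelineError("extract: no reads available (enable simulate or set reads_path)")
            payloads, n_absent = read_processing.extract_payloads(records, cfg.layout())
            pd.DataFrame(
                [(p.read_id, p.strand, p.payload) for p in payloads],
                columns=["read_id", "strand", "payload"],
            ).to_csv(out / "payloads.tsv", sep="\t", index=False)
            summary["n_extracted"] = len(payloads)
            summary["n_unmatched"] = n_absent

    if cfg.do_analyze:
        with _stage("analyze"):
            if payloads is None:
                raise PipelineError("analyze: extraction stage must run first")
            if not cfg.target:
                raise PipelineError("analyze: a target sequence is required")
            metrics = read_processing.compute_metrics(payloads, cfg.target)
            read_processing.write_metrics(metrics, out / "metrics.tsv")
            summary.update(
                {
                    k: v
                    for k, v in metrics.as_dict().items()
                    if k not in ("target",)
                }
            )

    cons = None
    if cfg.do_consensus:
        with _stage("consensus"):
            if payloads is None:
                raise PipelineError("consensus: extraction stage must run first")
            if cfg.consensus_mode == "global":
                cons = consensus_mod.global_majority(payloads)
            else:
                length = len(cfg.target) if cfg.target else max(
                    len(p.payload) for p in payloads
                )
                cons = consensus_mod.conditional_consensus(payloads, length)
            with open(out / "consensus.fa", "w") as fh:
                fh.write(f">consensus {cons.method}\n{cons.consensus}\n")
            cons.per_position_counts.to_csv(out / "consensus_counts.tsv", sep="\t")
            summary["consensus"] = cons.consensus
            summary["consensus_ties"] = list(cons.tie_flags)

    if cfg.do_decode:
        with _stage("decode"):
            message = consensus_mod.decode_information(cons, BaseMap(cfg.base_map))
            (out / "message.bin").write_bytes(message)
            summary["decoded_n_bytes"] = len(message)
            summary["decoded_hex"] = message.hex()

    summary["stage_seconds"] = timings
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=2) + "\n")
    return summary
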