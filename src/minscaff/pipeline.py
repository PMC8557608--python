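"""Pipeline orchestration: correction then scaffolding, with a manifest.

``run_pipeline`` wires the stages together on disk: the correction stage
reads the draft and long reads, cuts putative misassemblies and writes the
corrected FASTA plus a BED of breakpoints; the scaffolding stage maps the
reads to the (corrected) draft, builds and filters the scaffold graph,
sweeps the layout threshold and writes scaffolds FASTA, AGP, the DOT graph
and a layout report.  Identical config and inputs give byte-identical
outputs: nothing here depends on wall-clock or hash order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from . import seqio
from .correction import correct_assembly, write_breakpoints_bed
from .graph import ScaffoldGraph, build_graph, filter_noisy, write_dot
from .layout import LayoutParams, ScaffoldPath, emit_scaffolds, select_threshold
from .mapping import filter_runs, map_read
from .pairing import PairingParams, infer_pairs
from .seqio import SeqRecord
from .sketch import SketchParams, build_assembly_index, sketch_sequence

log = logging.getLogger("minscaff")


@dataclass
class PipelineConfig:
    draft_path: str
    reads_path: str
    G: int
    out_prefix: str = "minscaff_out"
    k: int = 32
    w: int = 100
    z: int = 1000
    f: int = 10
    a: int = 1
    fragment_size: int = 500
    span: Optional[int] = None  # None -> 0.25 x coverage
    dist: Optional[int] = None  # None -> median read length
    min_gap: int = 20
    n_min: int = 1
    n_max: int = 50
    seed: int = 0
    stages: tuple[str, ...] = ("correct", "scaffold")

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("stages must be non-empty")
        bad = set(self.stages) - {"correct", "scaffold"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.G <= 0:
            raise ValueError("G must be positive")


@dataclass
class ScaffoldResult:
    paths: list[ScaffoldPath]
    records: list[SeqRecord]
    graph: ScaffoldGraph
    n_star: int
    report: list[tuple[int, int, int]]


def scaffold_assembly(
    contigs: Sequence[SeqRecord],
    reads: Sequence[SeqRecord],
    G: int,
    k: int = 32,
    w: int = 100,
    z: int = 1000,
    f: int = 10,
    a: int = 1,
    min_gap: int = 20,
    n_sweep: Optional[Sequence[int]] = None,
) -> ScaffoldResult:
    """The full scaffolding stage as a library call.

    Sketch and index the contigs, map and pair every read, tally the
    scaffold graph, drop noisy (under-anchored) edges, pick the support
    threshold by NG50 sweep and emit scaffold sequences.
    """
    params = SketchParams(k=k, w=w)
    pparams = PairingParams(f=f, a=a)
    index = build_assembly_index(contigs, params)
    lengths = index.contig_lengths
    pairs = []
    for read in reads:
        sk = sketch_sequence(read, params)
        mapping = filter_runs(map_read(sk, index), z, lengths)
        pairs.extend(infer_pairs(mapping, lengths, k, pparams))
    graph = filter_noisy(build_graph(pairs, lengths), a)
    lparams = LayoutParams(
        G=G,
        n_sweep=tuple(n_sweep) if n_sweep is not None else tuple(range(1, 51)),
        min_gap=min_gap,
    )
    n_star, paths, report = select_threshold(graph, lparams)
    records = emit_scaffolds(paths, contigs, min_gap=min_gap)
    return ScaffoldResult(paths, records, graph, n_star, report)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return (and write) the output manifest."""
    t0 = time.time()
    draft = seqio.read_seq_file(config.draft_path)
    reads = seqio.read_seq_file(config.reads_path)
    if not draft:
        raise ValueError(f"no contigs in {config.draft_path}")
    min_contig = min(len(c.seq) for c in draft)
    if config.k >= min_contig:
        raise ValueError(f"k={config.k} >= smallest contig length ({min_contig})")

    prefix = config.out_prefix
    artifacts: dict[str, dict] = {}
    manifest: dict = {"config": asdict(config), "artifacts": artifacts}
    contigs = draft

    if "correct" in config.stages:
        t = time.time()
        result = correct_assembly(
            draft,
            reads,
            config.G,
            fragment_size=config.fragment_size,
            span=config.span,
            dist=config.dist,
        )
        contigs = result.contigs
        corrected_path = f"{prefix}.corrected.fa"
        bed_path = f"{prefix}.breakpoints.bed"
        seqio.write_fasta(contigs, corrected_path)
        write_breakpoints_bed(result.breakpoints, bed_path)
        artifacts["corrected_fasta"] = {"path": corrected_path, "sha256": _sha256(corrected_path)}
        artifacts["breakpoints_bed"] = {"path": bed_path, "sha256": _sha256(bed_path)}
        manifest["correction"] = {
            "n_breakpoints": len(result.breakpoints),
            "span": result.params.span,
            "dist": result.params.dist,
            "dropped_fragments": result.dropped,
        }
        log.info(
            "stage=correct wall=%.1fs span=%d dist=%d breakpoints=%d",
            time.time() - t, result.params.span, result.params.dist, len(result.breakpoints),
        )

    if "scaffold" in config.stages:
        t = time.time()
        res = scaffold_assembly(
            contigs,
            reads,
            config.G,
            k=config.k,
            w=config.w,
            z=config.z,
            f=config.f,
            a=config.a,
            min_gap=config.min_gap,
            n_sweep=range(config.n_min, config.n_max + 1),
        )
        fa_path = f"{prefix}.scaffolds.fa"
        agp_path = f"{prefix}.scaffolds.agp"
        dot_path = f"{prefix}.graph.dot"
        tsv_path = f"{prefix}.layout.tsv"
        seqio.write_fasta(res.records, fa_path)
        seqio.write_agp(
            res.paths,
            {c.id: len(c.seq) for c in contigs},
            agp_path,
            object_ids=[r.id for r in res.records],
            min_gap=config.min_gap,
        )
        write_dot(res.graph, dot_path)
        with open(tsv_path, "w") as out:
            out.write("n\tng50\tn_paths\n")
            for n, ng, np_ in res.report:
                out.write(f"{n}\t{ng}\t{np_}\n")
        for name, path in [
            ("scaffolds_fasta", fa_path),
            ("scaffolds_agp", agp_path),
            ("graph_dot", dot_path),
            ("layout_report", tsv_path),
        ]:
            artifacts[name] = {"path": path, "sha256": _sha256(path)}
        manifest["scaffolding"] = {
            "n_star": res.n_star,
            "n_paths": len(res.paths),
            "n_scaffolds": len(res.records),
        }
        log.info("stage=scaffold wall=%.1fs n*=%d paths=%d", time.time() - t, res.n_star, len(res.paths))

    log.info("pipeline done wall=%.1fs", time.time() - t0)
    # wall time goes to the log, not the manifest: outputs stay byte-identical
    manifest_path = f"{prefix}.manifest.json"
    with open(manifest_path, "w") as out:
        json.dump(manifest, out, indent=2, default=list)
    return manifest
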