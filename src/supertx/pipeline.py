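"""Stage orchestration with hash-based resumability.

Unlike pipeline front ends that shell out to aligners and assemblers, the
stages here consume those tools' *file outputs* (GTF, FASTA, PSL, SAM)
named in the configuration.  Each stage records its input hashes,
parameters and output hashes in ``manifest.json``; a rerun with unchanged
inputs is a no-op.  Per-stage record counts (genes in/out, contigs per
fate, fragments assigned) are logged and stored in the manifest so a
summary table can be produced for any dataset.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from . import clustering, summarize
from .flatten import (
    flat_to_gene_models,
    flatten_cds_annotation,
    flatten_genes,
    merge_annotations,
)
from .build import (
    build_genome_supertranscripts,
    read_supertranscriptome,
    write_supertranscriptome,
)
from .config import PipelineConfig
from .io import read_fasta, read_fragments, read_gtf, read_psl, write_gtf
from .merge import merge_all
from .models import FATE_CHIMERIC, FATE_KNOWN, FATE_NOVEL, FATE_UNMATCHED, Block

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("flatten", "build_st", "cluster", "merge", "blocks", "count")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path_str: Optional[str], what: str, stage: str, hint: str) -> Path:
    if not path_str:
        raise PipelineError(f"stage {stage!r} needs {what}; {hint}")
    p = Path(path_str)
    if not p.exists():
        raise PipelineError(f"stage {stage!r}: {what} {p} does not exist; {hint}")
    return p


class _Runner:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )

    def out(self, name: str) -> Path:
        return self.outdir / name

    def _fresh(self, stage: str, inputs: dict, params: dict) -> bool:
        entry = self.manifest.get(stage)
        if not entry:
            return False
        if entry["inputs"] != inputs or entry["params"] != params:
            return False
        for path, digest in entry["outputs"].items():
            if not Path(path).exists() or _sha256(Path(path)) != digest:
                return False
        return True

    def run_stage(self, stage: str, inputs: Sequence[Path], params: dict, fn) -> bool:
        """Run one stage unless its manifest entry is current.  Returns True
        when the stage actually executed."""
        in_hashes = {str(p): _sha256(p) for p in inputs}
        params = {k: str(v) for k, v in params.items()}
        if self._fresh(stage, in_hashes, params):
            logger.info("stage %s: up to date, skipping", stage)
            return False
        logger.info("stage %s: running", stage)
        outputs, stats = fn()
        self.manifest[stage] = {
            "inputs": in_hashes,
            "params": params,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "stats": stats,
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        for k, v in stats.items():
            logger.info("stage %s: %s = %s", stage, k, v)
        return True


def _stage_flatten(r: _Runner):
    cfg = r.cfg
    annotation = _require(cfg.annotation, "annotation", "flatten", "set 'annotation'")
    inputs = [annotation]
    assembled_path = None
    if cfg.assembled_gtf:
        assembled_path = _require(
            cfg.assembled_gtf, "assembled_gtf", "flatten", "set 'assembled_gtf'"
        )
        inputs.append(assembled_path)

    def fn():
        reference = read_gtf(annotation, source="reference")
        assembled = read_gtf(assembled_path, source="assembled") if assembled_path else []
        combined = merge_annotations(reference, assembled)
        flat = flatten_genes(combined)
        write_gtf(combined, r.out("combined.gtf"))
        write_gtf(flat_to_gene_models(flat), r.out("flat.gtf"))
        stats = {
            "reference_genes": len(reference),
            "assembled_genes": len(assembled),
            "combined_genes": len(combined),
            "flat_genes": len(flat),
            "flat_exons": sum(len(f.exons) for f in flat),
            "flat_bases": sum(f.exonic_length for f in flat),
        }
        return [r.out("combined.gtf"), r.out("flat.gtf")], stats

    return r.run_stage("flatten", inputs, {}, fn)


def _stage_build_st(r: _Runner):
    cfg = r.cfg
    flat_gtf = _require(str(r.out("flat.gtf")), "flat.gtf", "build_st", "run stage 'flatten' first")
    genome = _require(cfg.genome, "genome", "build_st", "set 'genome'")
    rel_gtf = _require(
        cfg.annotation_related_species,
        "annotation_related_species",
        "build_st",
        "set 'annotation_related_species'",
    )
    rel_genome = _require(
        cfg.genome_related_species,
        "genome_related_species",
        "build_st",
        "set 'genome_related_species'",
    )

    def fn():
        flat = flatten_genes(read_gtf(flat_gtf))
        sts = build_genome_supertranscripts(flat, genome)
        write_supertranscriptome(sts, r.out("genome_st.fasta"), r.out("genome_st_blocks.gtf"))
        related_flat = flatten_cds_annotation(read_gtf(rel_gtf, feature="CDS"))
        related_sts = build_genome_supertranscripts(related_flat, rel_genome)
        write_supertranscriptome(related_sts, r.out("related_st.fasta"))
        stats = {
            "genome_supertranscripts": len(sts),
            "genome_st_bases": sum(len(s) for s in sts),
            "related_supertranscripts": len(related_sts),
        }
        return [
            r.out("genome_st.fasta"),
            r.out("genome_st_blocks.gtf"),
            r.out("related_st.fasta"),
        ], stats

    return r.run_stage("build_st", [flat_gtf, genome, rel_gtf, rel_genome], {}, fn)


def _stage_cluster(r: _Runner):
    cfg = r.cfg
    psl_genome = _require(cfg.psl_genome, "psl_genome", "cluster", "set 'psl_genome'")
    psl_related = _require(cfg.psl_related, "psl_related", "cluster", "set 'psl_related'")
    contig_fasta = _require(cfg.contig_fasta, "contig_fasta", "cluster", "set 'contig_fasta'")
    f = cfg.hit_filter
    params = {
        "min_identity": f.min_identity,
        "min_aligned_fraction": f.min_aligned_fraction,
        "min_aligned_bases": f.min_aligned_bases,
    }

    def fn():
        assignments = clustering.cluster_contigs(
            read_psl(psl_genome),
            read_psl(psl_related),
            f,
            contig_ids=list(read_fasta(contig_fasta)),
        )
        clustering.write_assignments(assignments, r.out("cluster_table.tsv"))
        fates = {fate: 0 for fate in (FATE_KNOWN, FATE_NOVEL, FATE_CHIMERIC, FATE_UNMATCHED)}
        for a in assignments:
            fates[a.fate] += 1
        stats = {"contigs": len(assignments), **{f"contigs_{k}": v for k, v in fates.items()}}
        return [r.out("cluster_table.tsv")], stats

    return r.run_stage("cluster", [psl_genome, psl_related, contig_fasta], params, fn)


def _stage_merge(r: _Runner):
    cfg = r.cfg
    table = _require(
        str(r.out("cluster_table.tsv")), "cluster_table.tsv", "merge", "run stage 'cluster' first"
    )
    flat_gtf = _require(str(r.out("flat.gtf")), "flat.gtf", "merge", "run stage 'flatten' first")
    genome = _require(cfg.genome, "genome", "merge", "set 'genome'")
    contig_fasta = _require(cfg.contig_fasta, "contig_fasta", "merge", "set 'contig_fasta'")

    def fn():
        flat = flatten_genes(read_gtf(flat_gtf))
        sts = build_genome_supertranscripts(flat, genome)
        assignments = clustering.read_assignments(table)
        clusters = clustering.build_clusters(assignments, sts, contig_fasta)
        merged = merge_all(clusters, min_anchor=cfg.min_anchor)
        write_supertranscriptome(merged, r.out("merged_st.fasta"), r.out("merged_st_blocks.gtf"))
        inserted = sum(
            len(b) for st in merged for b in st.blocks if b.inserted
        )
        stats = {
            "clusters": len(clusters),
            "supertranscripts": len(merged),
            "merged_bases": sum(len(s) for s in merged),
            "inserted_bases": inserted,
        }
        return [r.out("merged_st.fasta"), r.out("merged_st_blocks.gtf")], stats

    return r.run_stage(
        "merge", [table, flat_gtf, genome, contig_fasta], {"min_anchor": cfg.min_anchor}, fn
    )


def _read_all_samples(cfg: PipelineConfig, stage: str):
    if not cfg.sam_files:
        raise PipelineError(
            f"stage {stage!r} needs read alignments; set 'sam_files' to one SAM per sample"
        )
    out = {}
    for sample, path in zip(cfg.sample_names, cfg.sam_files):
        p = _require(path, f"SAM file {path}", stage, "check 'sam_files'")
        out[sample] = read_fragments(p)
    return out


def _stage_blocks(r: _Runner):
    cfg = r.cfg
    merged_fasta = _require(
        str(r.out("merged_st.fasta")), "merged_st.fasta", "blocks", "run stage 'merge' first"
    )
    sams = [Path(p) for p in cfg.sam_files]
    if not sams:
        raise PipelineError("stage 'blocks' needs read alignments; set 'sam_files'")
    for p in sams:
        _require(str(p), f"SAM file {p}", "blocks", "check 'sam_files'")

    def fn():
        st_lengths = {st.gene_id: len(st) for st in read_supertranscriptome(merged_fasta)}
        by_sample = _read_all_samples(cfg, "blocks")
        pooled = [f for frags in by_sample.values() for f in frags]
        junctions = summarize.collect_junctions(pooled, min_support=cfg.min_support)
        blocks = summarize.segment_blocks(st_lengths, junctions)
        with open(r.out("junctions.tsv"), "w") as fh:
            fh.write("st_id\tstart\tend\tread_support\n")
            for j in junctions:
                fh.write(f"{j.st_id}\t{j.start}\t{j.end}\t{j.read_support}\n")
        summarize.write_blocks_gtf(blocks, r.out("blocks.gtf"))
        stats = {
            "junctions": len(junctions),
            "blocks": len(blocks),
            "supertranscripts": len(st_lengths),
        }
        return [r.out("junctions.tsv"), r.out("blocks.gtf")], stats

    return r.run_stage(
        "blocks", [merged_fasta, *sams], {"min_support": cfg.min_support}, fn
    )


def read_blocks_gtf(path) -> list[Block]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.strip().split(" ", 1) for kv in fields[8].split(";") if kv.strip()
            )
            block_id = attrs["block_id"].strip('"')
            blocks.append(Block(fields[0], int(fields[3]), int(fields[4]), block_id))
    return blocks


def _stage_count(r: _Runner):
    cfg = r.cfg
    merged_fasta = _require(
        str(r.out("merged_st.fasta")), "merged_st.fasta", "count", "run stage 'merge' first"
    )
    blocks_gtf = _require(
        str(r.out("blocks.gtf")), "blocks.gtf", "count", "run stage 'blocks' first"
    )
    sams = [Path(p) for p in cfg.sam_files]
    if not sams:
        raise PipelineError("stage 'count' needs read alignments; set 'sam_files'")

    def fn():
        st_lengths = {st.gene_id: len(st) for st in read_supertranscriptome(merged_fasta)}
        by_sample = _read_all_samples(cfg, "count")
        gene_feats = summarize.gene_features(st_lengths)
        gene_ct = summarize.count_fragments(by_sample, gene_feats)
        summarize.write_counts(gene_ct, r.out("gene_counts.tsv"), gene_feats)
        blocks = read_blocks_gtf(blocks_gtf)
        block_feats = summarize.block_features(blocks)
        block_ct = summarize.count_fragments(by_sample, block_feats)
        summarize.write_counts(block_ct, r.out("block_counts.tsv"), block_feats)
        stats = {
            "samples": len(by_sample),
            "fragments_assigned_genes": int(gene_ct.summary.loc["assigned"].sum()),
            "fragments_total": int(gene_ct.summary.sum().sum()),
        }
        return [
            r.out("gene_counts.tsv"),
            Path(str(r.out("gene_counts.tsv")) + ".summary"),
            r.out("block_counts.tsv"),
            Path(str(r.out("block_counts.tsv")) + ".summary"),
        ], stats

    return r.run_stage("count", [merged_fasta, blocks_gtf, *sams], {}, fn)


_STAGE_FN = {
    "flatten": _stage_flatten,
    "build_st": _stage_build_st,
    "cluster": _stage_cluster,
    "merge": _stage_merge,
    "blocks": _stage_blocks,
    "count": _stage_count,
}


def run_pipeline(
    cfg: PipelineConfig, stages: Optional[Sequence[str]] = None
) -> dict:
    """Run the requested stages (default: all) in dependency order.

    Returns the manifest.  Stages whose recorded inputs, parameters and
    outputs are unchanged are skipped, so a rerun on an unmodified world is
    a no-op.

    Raises
    ------
    PipelineError
        When a stage's inputs are missing, naming the stage (or config key)
        to provide first.
    """
    if stages is None:
        stages = STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}; valid stages are {list(STAGES)}")
    runner = _Runner(cfg)
    for stage in STAGES:
        if stage in stages:
            _STAGE_FN[stage](runner)
    return runner.manifest
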