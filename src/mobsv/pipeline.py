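"""End-to-end pipeline: simulate (optional) → classify → call → report.

``run_pipeline`` executes the whole chain deterministically from a
:class:`PipelineConfig`, writing ``insertions.tsv``, ``deletions.tsv``,
``report.tsv`` and ``run.log`` (all effective parameters and the seed)
into the output directory.  Inputs come either from a built-in
simulation scenario or from user-supplied SAM + FASTA + annotation
files.  TSV coordinates are 1-based inclusive; everything internal is
0-based half-open.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import annotate as ann
from . import classify as cls
from . import deletions as dels
from . import insertions as ins
from .genome import ReferenceGenome, TruthEvent, plant_events
from .liftover import project_ideal_alignments
from .scenarios import get_scenario
from .simulate import SimConfig, simulate_read_pairs, write_fastq

logger = logging.getLogger("mobsv")


@dataclass
class PipelineConfig:
    """Effective parameter set for one run (CLI flags > config file >
    these defaults)."""

    # inputs: either a scenario name, or explicit files
    scenario: str | None = None
    sam: str | None = None
    reference: str | None = None
    is_catalog: str | None = None
    annotations: str | None = None
    outdir: str = "mobsv_out"
    # simulation
    coverage: float = 50.0
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    seed: int = 17
    min_anchor: int = 20
    # classification
    k_sd: float = 5.0
    min_mapq: int = 20
    min_model_pairs: int = 500
    # insertion calling
    window: int = 200
    step: int = 50
    alpha: float = 0.01
    lam_min: float = 0.05
    min_support: int = 4
    max_gap: int | None = None  # default: insert_mean + 3*insert_sd
    # deletion calling
    min_event_size: int = 200
    cluster_gap: int | None = None  # default: one model sigma

    def effective_max_gap(self, model: cls.InsertSizeModel | None = None) -> int:
        if self.max_gap is not None:
            return self.max_gap
        if model is not None:
            return int(round(model.median + 3 * model.sigma))
        return int(round(self.insert_mean + 3 * self.insert_sd))


def write_fasta(genome_or_catalog, path: str) -> None:
    if isinstance(genome_or_catalog, ReferenceGenome):
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in genome_or_catalog.replicons.items()
        ]
    else:
        records = [
            SeqRecord(Seq(e.sequence), id=e.name, description="")
            for e in genome_or_catalog
        ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def write_truth_json(events: list[TruthEvent], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=1)
        fh.write("\n")


def read_truth_json(path: str) -> list[TruthEvent]:
    with open(path) as fh:
        return [TruthEvent.from_dict(d) for d in json.load(fh)]


def simulate_scenario(cfg: PipelineConfig, outdir: str) -> dict[str, str]:
    """Build the scenario, plant events, simulate reads and project
    ideal alignments.  Returns the paths of everything written."""
    scen = get_scenario(cfg.scenario)
    mutated, truth = plant_events(scen.genome, scen.events, scen.catalog)
    sim_cfg = SimConfig(
        coverage=cfg.coverage,
        read_len=cfg.read_len,
        insert_mean=cfg.insert_mean,
        insert_sd=cfg.insert_sd,
        error_rate=cfg.error_rate,
        seed=cfg.seed,
    )
    pairs = simulate_read_pairs(mutated, sim_cfg)
    paths = {
        "reference": os.path.join(outdir, "reference.fasta"),
        "mutated": os.path.join(outdir, "mutated.fasta"),
        "catalog": os.path.join(outdir, "is_catalog.fasta"),
        "reads1": os.path.join(outdir, "reads_1.fastq"),
        "reads2": os.path.join(outdir, "reads_2.fastq"),
        "sam": os.path.join(outdir, "alignments.sam"),
        "truth": os.path.join(outdir, "truth.json"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
    }
    write_fasta(scen.genome, paths["reference"])
    write_fasta(mutated, paths["mutated"])
    write_fasta(scen.catalog, paths["catalog"])
    write_fastq(pairs, paths["reads1"], paths["reads2"])
    project_ideal_alignments(
        pairs, scen.genome, scen.catalog, truth, paths["sam"],
        min_anchor=cfg.min_anchor,
    )
    write_truth_json(truth, paths["truth"])
    ann.write_annotations_tsv(scen.features, paths["annotations"])
    return paths


def catalog_names_from_fasta(path: str) -> set[str]:
    return set(read_fasta(path))


def call_from_alignments(
    cfg: PipelineConfig,
    sam_path: str,
    catalog_names: set[str],
    replicon_lengths: dict[str, int],
):
    """classify → model → scan → call.  Returns (model, classified,
    insertion calls, deletion calls)."""
    records = cls.read_alignments(sam_path, catalog_names)
    model = cls.estimate_insert_model(
        records, k_sd=cfg.k_sd, min_model_pairs=cfg.min_model_pairs
    )
    classified = cls.classify_pairs(records, model, catalog_names, cfg.min_mapq)
    clusters = ins.scan_anchor_windows(
        classified,
        replicon_lengths,
        window=cfg.window,
        step=cfg.step,
        alpha=cfg.alpha,
        lam_min=cfg.lam_min,
    )
    insertion_calls = ins.call_insertions(
        clusters,
        max_gap=cfg.effective_max_gap(model),
        min_support=cfg.min_support,
    )
    stretched = dels.collect_stretched_pairs(classified)
    deletion_calls = dels.call_deletions(
        stretched,
        model,
        replicon_lengths,
        min_event_size=cfg.min_event_size,
        min_support=cfg.min_support,
        cluster_gap=cfg.cluster_gap,
        lam_min=cfg.lam_min,
    )
    return model, classified, insertion_calls, deletion_calls


def write_insertions_tsv(calls: list[ins.InsertionCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "replicon\tbp_start\tbp_end\telement\tsupport_left"
            "\tsupport_right\tp_value\n"
        )
        for c in calls:
            fh.write(
                f"{c.replicon}\t{c.bp_start + 1}\t{c.bp_end}\t{c.element}"
                f"\t{c.support_left}\t{c.support_right}\t{c.p_value:.3e}\n"
            )


def write_deletions_tsv(calls: list[dels.DeletionCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tstart\tend\test_size\tsupport\tp_value\n")
        for c in calls:
            fh.write(
                f"{c.replicon}\t{c.start + 1}\t{c.end}\t{c.est_size:.0f}"
                f"\t{c.support}\t{c.p_value:.3e}\n"
            )


def write_report_tsv(rows: list[ann.MutationReportRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tprotein\tinserted_element\treplicon\tcoordinates"
            "\tsupport\tp_value\n"
        )
        for r in rows:
            fh.write(
                f"{r.gene}\t{r.protein}\t{r.inserted_element}\t{r.replicon}"
                f"\t{r.coordinates}\t{r.support}\t{r.p_value:.3e}\n"
            )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full chain; returns a summary dict with the calls,
    report rows and paths of all files written."""
    os.makedirs(cfg.outdir, exist_ok=True)
    log_path = os.path.join(cfg.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("effective config: %s", json.dumps(asdict(cfg), default=str))
        if cfg.scenario is not None:
            paths = simulate_scenario(cfg, cfg.outdir)
            sam_path = paths["sam"]
            catalog_names = catalog_names_from_fasta(paths["catalog"])
            reference = read_fasta(paths["reference"])
            annotations_path = paths["annotations"]
        else:
            for name in ("sam", "reference", "is_catalog"):
                p = getattr(cfg, name)
                if p is None or not os.path.exists(p or ""):
                    raise FileNotFoundError(
                        f"required input --{name.replace('_', '-')}: {p}"
                    )
            sam_path = cfg.sam
            catalog_names = catalog_names_from_fasta(cfg.is_catalog)
            reference = read_fasta(cfg.reference)
            annotations_path = cfg.annotations
            paths = {}
        replicon_lengths = {
            name: len(seq)
            for name, seq in reference.items()
            if name not in catalog_names
        }
        model, classified, insertion_calls, deletion_calls = call_from_alignments(
            cfg, sam_path, catalog_names, replicon_lengths
        )
        logger.info(
            "insert model: median=%.1f sigma=%.2f n=%d threshold=%.1f",
            model.median, model.sigma, model.n, model.stretch_threshold,
        )
        class_counts = {c.value: len(v) for c, v in classified.items()}
        logger.info("pair classes: %s", json.dumps(class_counts))
        features = (
            ann.read_annotations(annotations_path) if annotations_path else []
        )
        rows = ann.annotate_calls(insertion_calls, deletion_calls, features)
        paths["insertions"] = os.path.join(cfg.outdir, "insertions.tsv")
        paths["deletions"] = os.path.join(cfg.outdir, "deletions.tsv")
        paths["report"] = os.path.join(cfg.outdir, "report.tsv")
        write_insertions_tsv(insertion_calls, paths["insertions"])
        write_deletions_tsv(deletion_calls, paths["deletions"])
        write_report_tsv(rows, paths["report"])
        logger.info(
            "%d insertion call(s), %d deletion call(s), %d report row(s)",
            len(insertion_calls), len(deletion_calls), len(rows),
        )
        return {
            "model": model,
            "class_counts": class_counts,
            "insertions": insertion_calls,
            "deletions": deletion_calls,
            "report": rows,
            "paths": paths,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
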