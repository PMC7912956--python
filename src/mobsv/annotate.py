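"""Gene annotation intersection and the mutation report.

Calls are assigned to genes by the midpoint of their breakpoint
interval: the feature overlapping the midpoint wins (ties broken by
larger overlap with the call interval, then lexicographic locus_tag);
calls hitting no feature are reported as intergenic with the flanking
locus tags; deletions spanning several genes list all of them.  The
resulting report has one row per call with gene, product and inserted
element — the shape in which IS-transposition screens of resequenced
strains are conventionally summarised.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils
import pandas as pd


@dataclass
class GeneFeature:
    """A gene with locus tag and product; interval 0-based half-open."""

    locus_tag: str
    product: str
    replicon: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.locus_tag}: empty interval")


@dataclass
class MutationReportRow:
    gene: str
    protein: str
    inserted_element: str
    replicon: str
    coordinates: str  # 1-based inclusive "start-end"
    support: int
    p_value: float


class AnnotationError(ValueError):
    pass


def _read_annotations_tsv(path: str) -> list[GeneFeature]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["replicon", "start", "end", "strand", "locus_tag", "product"],
        dtype={"replicon": str, "locus_tag": str, "product": str},
        skip_blank_lines=True,
    )
    feats = []
    for i, row in df.iterrows():
        if pd.isna(row["locus_tag"]) or not str(row["locus_tag"]).strip():
            raise AnnotationError(f"{path}: line {i + 1}: missing locus_tag")
        feats.append(
            GeneFeature(
                locus_tag=str(row["locus_tag"]),
                product="" if pd.isna(row["product"]) else str(row["product"]),
                replicon=str(row["replicon"]),
                start=int(row["start"]) - 1,  # 1-based inclusive -> 0-based half-open
                end=int(row["end"]),
                strand=str(row["strand"]),
            )
        )
    return feats


def _read_annotations_gff3(path: str) -> list[GeneFeature]:
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    feats = []
    for ftype in ("gene", "CDS"):
        for f in db.features_of_type(ftype):
            tags = f.attributes.get("locus_tag")
            if not tags:
                raise AnnotationError(
                    f"{path}: feature at {f.seqid}:{f.start}-{f.end} lacks locus_tag"
                )
            product = (f.attributes.get("product") or [""])[0]
            feats.append(
                GeneFeature(
                    locus_tag=tags[0],
                    product=product,
                    replicon=f.seqid,
                    start=f.start - 1,
                    end=f.end,
                    strand=f.strand or "+",
                )
            )
    # gene and CDS rows for the same locus_tag collapse to one feature
    seen: dict[str, GeneFeature] = {}
    for f in feats:
        if f.locus_tag in seen:
            g = seen[f.locus_tag]
            if (g.replicon, g.start, g.end) != (f.replicon, f.start, f.end):
                raise AnnotationError(f"duplicate locus_tag {f.locus_tag}")
            if not g.product and f.product:
                g.product = f.product
        else:
            seen[f.locus_tag] = f
    return list(seen.values())


def read_annotations(path: str) -> list[GeneFeature]:
    """Parse gene features from GFF3 or 6-column TSV
    (replicon, start, end, strand, locus_tag, product; 1-based
    inclusive coordinates)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    is_gff = path.endswith((".gff", ".gff3"))
    if not is_gff:
        with open(path) as fh:
            head = fh.readline()
            is_gff = head.startswith("##gff-version")
    feats = _read_annotations_gff3(path) if is_gff else _read_annotations_tsv(path)
    tags = [f.locus_tag for f in feats]
    dupes = {t for t in tags if tags.count(t) > 1}
    if dupes:
        raise AnnotationError(f"duplicate locus_tag(s): {sorted(dupes)}")
    return feats


def write_annotations_tsv(feats: list[GeneFeature], path: str) -> None:
    with open(path, "w") as fh:
        for f in feats:
            fh.write(
                f"{f.replicon}\t{f.start + 1}\t{f.end}\t{f.strand}"
                f"\t{f.locus_tag}\t{f.product}\n"
            )


def write_annotations_gff3(feats: list[GeneFeature], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag};product={f.product}"
            fh.write(
                f"{f.replicon}\tmobsv\tgene\t{f.start + 1}\t{f.end}\t."
                f"\t{f.strand}\t.\t{attrs}\n"
            )


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _assign_point(
    feats: list[GeneFeature], replicon: str, call_start: int, call_end: int
) -> tuple[str, str]:
    """Gene assignment by breakpoint-midpoint overlap."""
    mid = (call_start + call_end) // 2
    hits = [
        f
        for f in feats
        if f.replicon == replicon and f.start <= mid < f.end
    ]
    if hits:
        hits.sort(
            key=lambda f: (-_overlap(f.start, f.end, call_start, call_end), f.locus_tag)
        )
        best = hits[0]
        return best.locus_tag, best.product
    rep_feats = [f for f in feats if f.replicon == replicon]
    before = [f for f in rep_feats if f.end <= mid]
    after = [f for f in rep_feats if f.start > mid]
    up = max(before, key=lambda f: f.end).locus_tag if before else "-"
    down = min(after, key=lambda f: f.start).locus_tag if after else "-"
    return f"intergenic({up}|{down})", ""


def annotate_calls(
    insertions: list,
    deletions: list,
    features: list[GeneFeature],
) -> list[MutationReportRow]:
    """Build the mutation report: one row per call, sorted by gene."""
    call_reps = {c.replicon for c in insertions} | {c.replicon for c in deletions}
    feat_reps = {f.replicon for f in features}
    unmatched = sorted(call_reps - feat_reps)
    if features and unmatched:
        raise ValueError(
            f"calls on replicon(s) absent from the annotation: {unmatched}"
        )
    rows: list[MutationReportRow] = []
    for c in insertions:
        gene, product = _assign_point(features, c.replicon, c.bp_start, c.bp_end)
        rows.append(
            MutationReportRow(
                gene=gene,
                protein=product,
                inserted_element=c.element,
                replicon=c.replicon,
                coordinates=f"{c.bp_start + 1}-{c.bp_end}",
                support=c.support_left + c.support_right,
                p_value=c.p_value,
            )
        )
    for c in deletions:
        span_hits = [
            f
            for f in features
            if f.replicon == c.replicon and _overlap(f.start, f.end, c.start, c.end) > 0
        ]
        if span_hits:
            span_hits.sort(key=lambda f: (f.start, f.locus_tag))
            gene = ";".join(f.locus_tag for f in span_hits)
            product = ";".join(f.product for f in span_hits)
        else:
            gene, product = _assign_point(features, c.replicon, c.start, c.end)
        rows.append(
            MutationReportRow(
                gene=gene,
                protein=product,
                inserted_element=f"deletion({int(round(c.est_size))})",
                replicon=c.replicon,
                coordinates=f"{c.start + 1}-{c.end}",
                support=c.support,
                p_value=c.p_value,
            )
        )
    rows.sort(key=lambda r: r.gene)
    return rows
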