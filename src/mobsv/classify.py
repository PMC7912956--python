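"""Read-pair parsing, robust insert-size modelling and classification.

The insertion and deletion detectors both work from a partition of all
read pairs into evidence classes.  A pair is concordant when both mates
map to the same replicon in head-to-head (forward/reverse) orientation
with an ordinary insert size; "stretched" pairs (insert far beyond the
library's typical size) indicate the sample lacks sequence present in
the reference — a deletion; pairs whose second mate lands on an IS
catalog entry, or fails to map at all, are the "unpaired read" signal
for a new IS insertion.

The insert-size model is robust: median and MAD (scaled by 1.4826 to
estimate a normal sigma) over concordantly oriented pairs, after
trimming the top 1% so that genuine deletion-bridging pairs cannot
inflate the scale estimate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pysam


class PairClass(enum.Enum):
    """Mutually exclusive, exhaustive evidence classes."""

    CONCORDANT = "concordant"
    STRETCHED = "stretched"
    IS_ANCHORED = "is_anchored"
    MATE_UNMAPPED = "mate_unmapped"
    OTHER = "other"


@dataclass
class AlignedMate:
    """One aligned read end."""

    query_id: str
    ref_name: str | None
    pos: int  # 0-based leftmost aligned reference base
    end: int  # one past the rightmost aligned reference base
    strand: str  # "+" or "-"
    mapped: bool
    mapq: int
    is_on_catalog: bool
    qlen: int = 0  # full read length including soft clips

    @classmethod
    def unmapped_placeholder(cls, query_id: str) -> "AlignedMate":
        return cls(query_id, None, 0, 0, "+", False, 0, False)


@dataclass
class ReadPairRecord:
    """Both ends of one fragment.  ``insert_size`` is the outer distance
    (max end − min start), defined only when both mates map to the same
    non-catalog replicon in head-to-head orientation."""

    pair_id: str
    mate1: AlignedMate
    mate2: AlignedMate
    insert_size: int | None = None

    @property
    def proper_orientation(self) -> bool:
        """Leftmost mate forward, rightmost mate reverse, same replicon,
        neither on a catalog entry."""
        m1, m2 = self.mate1, self.mate2
        if not (m1.mapped and m2.mapped):
            return False
        if m1.ref_name != m2.ref_name or m1.is_on_catalog or m2.is_on_catalog:
            return False
        left, right = (m1, m2) if m1.pos <= m2.pos else (m2, m1)
        return left.strand == "+" and right.strand == "-"

    @property
    def inner_interval(self) -> tuple[int, int] | None:
        """Reference interval between the innermost mate ends (may be
        empty for overlapping mates)."""
        if self.insert_size is None:
            return None
        m1, m2 = self.mate1, self.mate2
        left, right = (m1, m2) if m1.pos <= m2.pos else (m2, m1)
        return (left.end, right.pos)


@dataclass
class InsertSizeModel:
    """Robust location/scale of the concordant insert-size distribution."""

    median: float
    sigma: float  # 1.4826 * MAD
    n: int
    stretch_threshold: float
    read_len: int = 0  # typical read length observed in the model pairs


class ModelError(RuntimeError):
    """Raised when too few pairs are available to fit the model."""


def _mate_from_alignment(aln: pysam.AlignedSegment, catalog_names: set[str]) -> AlignedMate:
    if aln.is_unmapped:
        return AlignedMate.unmapped_placeholder(aln.query_name)
    return AlignedMate(
        query_id=aln.query_name,
        ref_name=aln.reference_name,
        pos=aln.reference_start,
        end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        mapped=True,
        mapq=aln.mapping_quality,
        is_on_catalog=aln.reference_name in catalog_names,
        qlen=aln.query_length or aln.infer_read_length() or 0,
    )


def read_alignments(
    sam_path: str, catalog_names: set[str] | None = None
) -> list[ReadPairRecord]:
    """Pair up SAM records by query name into :class:`ReadPairRecord`.

    Secondary and supplementary alignments are ignored; a query name
    seen with a single mate gets an unmapped placeholder partner.
    """
    catalog_names = catalog_names or set()
    mates: dict[str, list[AlignedMate | None]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            name = aln.query_name
            slot = 1 if aln.is_read2 else 0
            if name not in mates:
                mates[name] = [None, None]
                order.append(name)
            if mates[name][slot] is not None:
                continue  # keep primary/first occurrence only
            mates[name][slot] = _mate_from_alignment(aln, catalog_names)

    records = []
    for name in order:
        m1, m2 = mates[name]
        if m1 is None:
            m1 = AlignedMate.unmapped_placeholder(name)
        if m2 is None:
            m2 = AlignedMate.unmapped_placeholder(name)
        rec = ReadPairRecord(name, m1, m2)
        if rec.proper_orientation:
            rec.insert_size = max(m1.end, m2.end) - min(m1.pos, m2.pos)
        records.append(rec)
    return records


def estimate_insert_model(
    records: list[ReadPairRecord],
    k_sd: float = 5.0,
    min_model_pairs: int = 500,
    trim_top: float = 0.01,
) -> InsertSizeModel:
    """Fit the robust insert-size model from concordantly oriented pairs.

    The largest ``trim_top`` fraction of insert sizes is discarded
    before computing median and MAD, so pairs bridging real deletions do
    not inflate the scale; ``stretch_threshold = median + k_sd*sigma``.
    """
    inserts = np.array(
        [r.insert_size for r in records if r.insert_size is not None], dtype=float
    )
    if inserts.size < min_model_pairs:
        raise ModelError(
            f"only {inserts.size} pairs with defined insert size "
            f"(need >= {min_model_pairs}); supply more alignments"
        )
    inserts.sort()
    keep = inserts[: max(1, int(np.ceil(inserts.size * (1 - trim_top))))]
    med = float(np.median(keep))
    sigma = 1.4826 * float(np.median(np.abs(keep - med)))
    qlens = [
        m.qlen
        for r in records
        if r.insert_size is not None
        for m in (r.mate1, r.mate2)
        if m.qlen
    ]
    read_len = int(np.median(qlens)) if qlens else 0
    return InsertSizeModel(
        median=med,
        sigma=sigma,
        n=int(inserts.size),
        stretch_threshold=med + k_sd * sigma,
        read_len=read_len,
    )


def classify_pair(
    record: ReadPairRecord,
    model: InsertSizeModel,
    catalog_names: set[str],
    min_mapq: int = 20,
) -> PairClass:
    """Assign one evidence class, evaluated in fixed priority order:
    IS_ANCHORED, MATE_UNMAPPED, STRETCHED, CONCORDANT, OTHER.  Pairs
    with a mapped mate below ``min_mapq`` are demoted to OTHER."""
    m1, m2 = record.mate1, record.mate2
    for m in (m1, m2):
        if m.mapped and m.mapq < min_mapq:
            return PairClass.OTHER
    on_cat = [m.mapped and (m.is_on_catalog or m.ref_name in catalog_names) for m in (m1, m2)]
    on_rep = [m.mapped and not on_cat[i] for i, m in enumerate((m1, m2))]
    if (on_cat[0] and on_rep[1]) or (on_cat[1] and on_rep[0]):
        return PairClass.IS_ANCHORED
    if (on_rep[0] and not m2.mapped) or (on_rep[1] and not m1.mapped):
        return PairClass.MATE_UNMAPPED
    if record.proper_orientation and record.insert_size is not None:
        if record.insert_size > model.stretch_threshold:
            return PairClass.STRETCHED
        return PairClass.CONCORDANT
    return PairClass.OTHER


def classify_pairs(
    records: list[ReadPairRecord],
    model: InsertSizeModel,
    catalog_names: set[str],
    min_mapq: int = 20,
) -> dict[PairClass, list[ReadPairRecord]]:
    """Partition all records by class (every record appears exactly once)."""
    out: dict[PairClass, list[ReadPairRecord]] = {c: [] for c in PairClass}
    for rec in records:
        out[classify_pair(rec, model, catalog_names, min_mapq)].append(rec)
    return out
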