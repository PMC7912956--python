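"""Project simulated reads back onto the original reference: an ideal
aligner.

Each planted event partitions the mutated genome into segments that lift
either to the original reference or to an IS catalog sequence (catalog
entries are emitted as extra reference sequences, the way one aligns
resequencing reads against reference + mobile-element database).  A mate
falling in a single segment maps at its lifted position; a mate
straddling a junction maps to the side with the larger contiguous anchor
(soft-clipping the rest) when that anchor reaches ``min_anchor``, and is
emitted unmapped otherwise.  Pairs bridging a deletion therefore report
an insert size inflated by the deletion length, and pairs with one mate
inside a new IS copy report that mate on the catalog entry — exactly the
two signals the downstream callers consume.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import pysam

from .genome import ISElement, ReferenceGenome, TruthEvent, revcomp
from .simulate import SimReadPair


@dataclass(frozen=True)
class _Segment:
    """A maximal run of the mutated genome lifting to one source."""

    mut_start: int
    mut_end: int
    source: str  # original replicon or catalog element name
    src_start: int  # source coordinate of mut_start (strand "+") / of mut_end (strand "-")
    strand: str  # "+" host/forward element, "-" reverse-inserted element
    src_len: int


def build_segment_map(
    original: ReferenceGenome,
    catalog: list[ISElement],
    truth: list[TruthEvent],
) -> dict[str, list[_Segment]]:
    """Segment each mutated replicon by the planted events."""
    elements = {e.name: e for e in catalog}
    segmap: dict[str, list[_Segment]] = {}
    for rep, seq in original.replicons.items():
        evs = sorted(
            (e for e in truth if e.replicon == rep), key=lambda e: e.mut_start
        )
        segs: list[_Segment] = []
        cur_mut = 0
        cur_ref = 0
        L = len(seq)
        for ev in evs:
            if ev.mut_start is None:
                raise ValueError("truth events must carry mutated-frame coordinates")
            if ev.mut_start > cur_mut:
                segs.append(
                    _Segment(cur_mut, ev.mut_start, rep, cur_ref, "+", L)
                )
            if ev.kind == "insertion":
                elem = elements[ev.element]
                segs.append(
                    _Segment(
                        ev.mut_start,
                        ev.mut_end,
                        elem.name,
                        0,
                        ev.strand,
                        len(elem.sequence),
                    )
                )
                # reference resumes at the breakpoint, re-reading the TSD
                cur_ref = ev.position
            else:
                cur_ref = ev.end
            cur_mut = ev.mut_end
        mut_len = cur_mut + (L - cur_ref)
        if mut_len > cur_mut:
            segs.append(_Segment(cur_mut, mut_len, rep, cur_ref, "+", L))
        segmap[rep] = segs
    return segmap


@dataclass
class _Placement:
    mapped: bool
    ref_name: str | None = None
    pos: int = 0  # 0-based leftmost on target
    aln_len: int = 0
    clip_head: int = 0  # soft clip before M, in target-forward orientation
    clip_tail: int = 0
    reverse: bool = False  # alignment on target reverse strand


def _place_mate(
    segs: list[_Segment],
    starts: list[int],
    s: int,
    e: int,
    mate_reverse: bool,
    min_anchor: int,
) -> _Placement:
    """Place one mate with mutated-frame footprint [s, e)."""
    i = bisect_right(starts, s) - 1
    pieces: list[tuple[_Segment, int, int]] = []
    while i < len(segs) and segs[i].mut_start < e:
        seg = segs[i]
        ps, pe = max(s, seg.mut_start), min(e, seg.mut_end)
        if pe > ps:
            pieces.append((seg, ps, pe))
        i += 1
    if not pieces:
        return _Placement(False)
    best = max(pieces, key=lambda p: p[2] - p[1])
    if len(pieces) > 1 and best[2] - best[1] < min_anchor:
        return _Placement(False)
    seg, ps, pe = best
    reverse = mate_reverse != (seg.strand == "-")
    if seg.strand == "+":
        pos = seg.src_start + (ps - seg.mut_start)
        clip_head, clip_tail = ps - s, e - pe
    else:
        off_s, off_e = ps - seg.mut_start, pe - seg.mut_start
        seg_len = seg.mut_end - seg.mut_start
        pos = seg.src_start + (seg_len - off_e)
        clip_head, clip_tail = e - pe, ps - s
    return _Placement(True, seg.source, pos, pe - ps, clip_head, clip_tail, reverse)


def project_ideal_alignments(
    pairs: list[SimReadPair],
    original: ReferenceGenome,
    catalog: list[ISElement],
    truth: list[TruthEvent],
    out_sam: str,
    min_anchor: int = 20,
    mapq: int = 60,
) -> None:
    """Write ideal alignments of simulated pairs to a SAM file whose
    header lists the original replicons plus the catalog entries."""
    segmap = build_segment_map(original, catalog, truth)
    starts = {rep: [sg.mut_start for sg in segs] for rep, segs in segmap.items()}
    ref_names = list(original.replicons) + [e.name for e in catalog]
    ref_lens = [len(original[r]) for r in original.replicons] + [
        len(e.sequence) for e in catalog
    ]
    header = pysam.AlignmentHeader.from_references(ref_names, ref_lens)
    tid = {name: i for i, name in enumerate(ref_names)}

    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        for pair in pairs:
            s1, e1 = pair.mate1_interval
            s2, e2 = pair.mate2_interval
            segs = segmap[pair.replicon]
            st = starts[pair.replicon]
            p1 = _place_mate(segs, st, s1, e1, False, min_anchor)
            p2 = _place_mate(segs, st, s2, e2, True, min_anchor)
            for this, other, read_seq, mate_rev, is_read1 in (
                (p1, p2, pair.mate1, False, True),
                (p2, p1, pair.mate2, True, False),
            ):
                a = pysam.AlignedSegment(header)
                a.query_name = pair.pair_id
                flag = 0x1 | (0x40 if is_read1 else 0x80)
                if this.mapped:
                    a.reference_id = tid[this.ref_name]
                    a.reference_start = this.pos
                    a.mapping_quality = mapq
                    if this.reverse:
                        flag |= 0x10
                    cig = []
                    if this.clip_head:
                        cig.append((4, this.clip_head))
                    cig.append((0, this.aln_len))
                    if this.clip_tail:
                        cig.append((4, this.clip_tail))
                    a.cigartuples = cig
                else:
                    flag |= 0x4
                    a.mapping_quality = 0
                if other.mapped:
                    a.next_reference_id = tid[other.ref_name]
                    a.next_reference_start = other.pos
                    if other.reverse:
                        flag |= 0x20
                    if not this.mapped:
                        # unmapped mate placed with its partner
                        a.reference_id = tid[other.ref_name]
                        a.reference_start = other.pos
                else:
                    flag |= 0x8
                    if this.mapped:
                        a.next_reference_id = tid[this.ref_name]
                        a.next_reference_start = this.pos
                proper = (
                    this.mapped
                    and other.mapped
                    and this.ref_name == other.ref_name
                    and this.reverse != other.reverse
                    and this.ref_name in original.replicons
                )
                if proper:
                    flag |= 0x2
                    left = min(this.pos, other.pos)
                    right = max(
                        this.pos + this.aln_len, other.pos + other.aln_len
                    )
                    a.template_length = (right - left) if this.pos <= other.pos else -(
                        right - left
                    )
                a.flag = flag
                # SEQ is stored reverse-complemented when 0x10 is set
                a.query_sequence = (
                    revcomp(read_seq) if (this.mapped and this.reverse) else read_seq
                )
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(read_seq)
                )
                out.write(a)
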