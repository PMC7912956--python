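"""Deletion detection (> 200 bp) from insert-size-stretched read pairs.

A pair bridging a deletion maps with an outer insert size inflated by
the deletion length.  Stretched pairs are clustered by overlap of their
inner intervals (single linkage with a small gap allowance); the cluster
interval is the intersection of the pairs' inner intervals — which
converges on the deleted segment — and the deletion size is estimated
from the median insert-size excess over the library median.

The raw excess is slightly length-biased: a fragment of length f
bridges a junction with probability proportional to (f − read_len), so
bridging fragments run longer than the library median by about
sigma^2 / (median − read_len).  That term is subtracted from the
estimate; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import InsertSizeModel, PairClass, ReadPairRecord
from .insertions import poisson_upper_tail


@dataclass
class DeletionCall:
    replicon: str
    start: int
    end: int
    est_size: float
    support: int
    p_value: float


def collect_stretched_pairs(
    classified: dict[PairClass, list[ReadPairRecord]],
) -> dict[str, list[ReadPairRecord]]:
    """Stretched pairs grouped by replicon, sorted by leftmost position."""
    out: dict[str, list[ReadPairRecord]] = {}
    for rec in classified[PairClass.STRETCHED]:
        rep = rec.mate1.ref_name if rec.mate1.mapped else rec.mate2.ref_name
        out.setdefault(rep, []).append(rec)
    for rep in out:
        out[rep].sort(key=lambda r: min(r.mate1.pos, r.mate2.pos))
    return out


def _length_bias_correction(model: InsertSizeModel) -> float:
    """Expected excess of bridging-fragment length over the library
    median, from length-biased selection with weight (f − read_len)."""
    m = model.median - model.read_len
    if m <= 0 or model.sigma <= 0:
        return 0.0
    return model.sigma**2 / m


def call_deletions(
    stretched: dict[str, list[ReadPairRecord]],
    model: InsertSizeModel,
    replicon_lengths: dict[str, int],
    min_event_size: int = 200,
    min_support: int = 4,
    cluster_gap: int | None = None,
    lam_min: float = 0.05,
) -> list[DeletionCall]:
    """Cluster stretched pairs and call deletions larger than
    ``min_event_size`` (default 200 bases) with at least ``min_support``
    supporting pairs.

    Pairs whose inner intervals overlap, or lie within ``cluster_gap``
    (default: one library sigma), are single-linkage clustered.  The
    reported interval is the intersection of the cluster's inner
    intervals when non-empty, else their bounding interval.
    """
    if cluster_gap is None:
        cluster_gap = int(round(model.sigma)) or 1
    correction = _length_bias_correction(model)
    calls: list[DeletionCall] = []
    for rep, recs in sorted(stretched.items()):
        items = []
        for r in recs:
            inner = r.inner_interval
            if inner is None:
                continue
            items.append((inner[0], inner[1], r))
        items.sort(key=lambda t: t[0])
        total_stretched = len(items)
        clusters: list[list[tuple[int, int, ReadPairRecord]]] = []
        cur: list[tuple[int, int, ReadPairRecord]] = []
        cur_end = None
        for a, b, r in items:
            if cur and a > cur_end + cluster_gap:
                clusters.append(cur)
                cur = []
                cur_end = None
            cur.append((a, b, r))
            cur_end = b if cur_end is None else max(cur_end, b)
        if cur:
            clusters.append(cur)
        for cl in clusters:
            support = len(cl)
            inter_a = max(a for a, _, _ in cl)
            inter_b = min(b for _, b, _ in cl)
            if inter_a < inter_b:
                start, end = inter_a, inter_b
            else:
                start = min(a for a, _, _ in cl)
                end = max(b for _, b, _ in cl)
            inserts = np.array([r.insert_size for _, _, r in cl], dtype=float)
            est = float(np.median(inserts)) - model.median - correction
            if est <= min_event_size or support < min_support:
                continue
            L = replicon_lengths.get(rep, 0)
            span = max(end - start, 1)
            lam = max(lam_min, total_stretched * span / L) if L else lam_min
            calls.append(
                DeletionCall(
                    replicon=rep,
                    start=start,
                    end=end,
                    est_size=est,
                    support=support,
                    p_value=poisson_upper_tail(support, lam),
                )
            )
    calls.sort(key=lambda c: (c.replicon, c.start, c.end))
    return calls
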