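"""IS insertion detection from one-end-anchored read clusters.

A new IS copy in the sample produces read pairs whose anchored mate maps
to the reference flank while the other mate either maps into an IS
catalog sequence or fails to map.  Forward-strand anchored mates pile up
on the left flank of the breakpoint, reverse-strand ones on the right
flank.  The scan slides windows along each replicon and flags windows
whose anchored-mate count is improbably high under a Poisson background
(rate proportional to the replicon-wide anchored-mate density,
Bonferroni-corrected over all windows tested); left and right flank
clusters are then paired into breakpoint calls and the inserted element
is read off the mate-target histogram.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from scipy import stats

from .classify import PairClass, ReadPairRecord


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(K >= k) for K ~ Poisson(lam), via the survival function."""
    if k < 0 or lam < 0:
        raise ValueError("k and lam must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


@dataclass
class AnchorCluster:
    """A window with a significant excess of anchored mates.

    ``side`` is "left" when the anchored mates are forward-strand (the
    breakpoint lies to the window's right) and "right" for
    reverse-strand mates (breakpoint to the left)."""

    replicon: str
    start: int
    end: int
    side: str  # "left" | "right"
    support: int
    mate_targets: dict[str, int] = field(default_factory=dict)
    p_value: float = 1.0


@dataclass
class InsertionCall:
    replicon: str
    bp_start: int
    bp_end: int
    element: str
    support_left: int
    support_right: int
    p_value: float

    @property
    def support(self) -> int:
        return self.support_left + self.support_right


def _anchored_evidence(
    classified: dict[PairClass, list[ReadPairRecord]],
) -> list[tuple[str, int, str, str | None]]:
    """(replicon, innermost coordinate, side, catalog target or None)
    for every anchored mate of an IS_ANCHORED or MATE_UNMAPPED pair."""
    out = []
    for cls in (PairClass.IS_ANCHORED, PairClass.MATE_UNMAPPED):
        for rec in classified[cls]:
            mates = (rec.mate1, rec.mate2)
            anchored = next(
                (m for m in mates if m.mapped and not m.is_on_catalog), None
            )
            if anchored is None:
                continue
            target = next(
                (m.ref_name for m in mates if m.mapped and m.is_on_catalog), None
            )
            if anchored.strand == "+":
                out.append((anchored.ref_name, anchored.end, "left", target))
            else:
                out.append((anchored.ref_name, anchored.pos, "right", target))
    return out


def scan_anchor_windows(
    classified: dict[PairClass, list[ReadPairRecord]],
    replicon_lengths: dict[str, int],
    window: int = 200,
    step: int = 50,
    alpha: float = 0.01,
    lam_min: float = 0.05,
) -> list[AnchorCluster]:
    """Sliding-window scan for anchored-mate excess.

    A window is emitted when its Poisson upper-tail probability falls
    below ``alpha / n_windows`` (Bonferroni over every window tested on
    any replicon and side); overlapping significant windows of the same
    side are merged (support = max, window = union, p = min).
    """
    evidence = _anchored_evidence(classified)
    n_windows = 0
    for L in replicon_lengths.values():
        n_windows += 2 * max(1, (max(L - window, 0)) // step + 1)
    cutoff = alpha / max(n_windows, 1)

    per_key: dict[tuple[str, str], list[tuple[int, str | None]]] = {}
    per_rep_total: dict[str, int] = {}
    for rep, pos, side, target in evidence:
        if rep not in replicon_lengths:
            continue
        per_key.setdefault((rep, side), []).append((pos, target))
        per_rep_total[rep] = per_rep_total.get(rep, 0) + 1

    raw: list[AnchorCluster] = []
    for (rep, side), items in per_key.items():
        L = replicon_lengths[rep]
        lam = max(lam_min, window * per_rep_total[rep] / L)
        items.sort()
        positions = [p for p, _ in items]
        sig: list[tuple[int, int, int]] = []  # (win_start, win_end, count)
        for w0 in range(0, max(L - window, 0) + 1, step):
            w1 = w0 + window
            lo = bisect.bisect_left(positions, w0)
            hi = bisect.bisect_left(positions, w1)
            count = hi - lo
            if count and poisson_upper_tail(count, lam) <= cutoff:
                sig.append((w0, w1, count))
        # merge overlapping significant windows
        merged: list[list[int]] = []
        for w0, w1, count in sig:
            if merged and w0 <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], w1)
                merged[-1][2] = max(merged[-1][2], count)
            else:
                merged.append([w0, w1, count])
        for w0, w1, support in merged:
            lo = bisect.bisect_left(positions, w0)
            hi = bisect.bisect_left(positions, w1)
            hist: dict[str, int] = {}
            for _, target in items[lo:hi]:
                if target is not None:
                    hist[target] = hist.get(target, 0) + 1
            raw.append(
                AnchorCluster(
                    replicon=rep,
                    start=w0,
                    end=w1,
                    side=side,
                    support=support,
                    mate_targets=hist,
                    p_value=poisson_upper_tail(support, lam),
                )
            )
    raw.sort(key=lambda c: (c.replicon, c.start, c.side))
    return raw


def _top_element(hist: dict[str, int]) -> str:
    """Arg-max of the mate-target histogram; 'ambiguous' on ties or an
    empty histogram."""
    if not hist:
        return "ambiguous"
    ranked = sorted(hist.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "ambiguous"
    return ranked[0][0]


def call_insertions(
    clusters: list[AnchorCluster],
    max_gap: int = 390,
    min_support: int = 4,
) -> list[InsertionCall]:
    """Pair left- and right-flank clusters into breakpoint calls.

    Each left cluster is matched to the nearest unconsumed right cluster
    whose window starts within ``max_gap`` downstream; the breakpoint is
    the interval between the innermost window edges (at least 1 base).
    Significant clusters left unpaired are emitted as single-sided calls
    when their support reaches ``2 * min_support``.
    """
    calls: list[InsertionCall] = []
    by_rep: dict[str, tuple[list[AnchorCluster], list[AnchorCluster]]] = {}
    for c in clusters:
        left, right = by_rep.setdefault(c.replicon, ([], []))
        (left if c.side == "left" else right).append(c)

    for rep, (lefts, rights) in sorted(by_rep.items()):
        used = [False] * len(rights)
        for lc in lefts:
            best_j, best_d = None, None
            for j, rc in enumerate(rights):
                if used[j]:
                    continue
                if rc.start < lc.start:
                    continue
                d = rc.start - lc.end
                if d > max_gap:
                    continue
                dist = abs(d)
                if best_d is None or dist < best_d:
                    best_j, best_d = j, dist
            if best_j is not None:
                rc = rights[best_j]
                used[best_j] = True
                bp_start, bp_end = lc.end, rc.start
                if bp_end <= bp_start:
                    mid = (lc.end + rc.start) // 2
                    bp_start, bp_end = mid, mid + 1
                hist: dict[str, int] = dict(lc.mate_targets)
                for k, v in rc.mate_targets.items():
                    hist[k] = hist.get(k, 0) + v
                if lc.support + rc.support >= min_support:
                    calls.append(
                        InsertionCall(
                            replicon=rep,
                            bp_start=bp_start,
                            bp_end=bp_end,
                            element=_top_element(hist),
                            support_left=lc.support,
                            support_right=rc.support,
                            p_value=max(lc.p_value, rc.p_value),
                        )
                    )
            elif lc.support >= 2 * min_support:
                calls.append(
                    InsertionCall(
                        rep, lc.end, lc.end + 1, _top_element(lc.mate_targets),
                        lc.support, 0, lc.p_value,
                    )
                )
        for j, rc in enumerate(rights):
            if not used[j] and rc.support >= 2 * min_support:
                calls.append(
                    InsertionCall(
                        rep, max(rc.start - 1, 0), max(rc.start, 1),
                        _top_element(rc.mate_targets), 0, rc.support, rc.p_value,
                    )
                )
    calls.sort(key=lambda c: (c.replicon, c.bp_start, c.bp_end))
    return calls
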