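"""Synthetic bacterial genomes, IS-element catalogs, and planted events.

A reference genome is an ordered mapping of replicon names to uppercase
DNA strings (bacteria such as *Cupriavidus metallidurans* CH34 carry
several replicons: chromosome, chromid and megaplasmids).  Insertion
sequences (IS) are small mobile elements bounded by terminal inverted
repeats; on transposition they duplicate a short stretch of host sequence
(the target-site duplication, TSD) on both sides of the new copy.  This
module plants such transpositions — and large deletions — into a genome
and keeps truth records in both the original and the mutated coordinate
frame so downstream detection can be scored exactly.

Coordinates are 0-based half-open throughout; file formats that are
1-based (SAM, GFF3, report TSVs) convert at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _ALPHABET[idx].tobytes().decode("ascii")


@dataclass
class ReferenceGenome:
    """Ordered collection of replicon sequences."""

    replicons: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.replicons) == 0:
            raise ValueError("genome must contain at least one replicon")
        for name, seq in self.replicons.items():
            if not name:
                raise ValueError("replicon names must be non-empty")
            if seq.strip("ACGT"):
                raise ValueError(
                    f"replicon {name!r} contains characters outside A/C/G/T"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.replicons.values())

    def __getitem__(self, name: str) -> str:
        return self.replicons[name]


@dataclass
class ISElement:
    """An insertion sequence: name, sequence, terminal inverted repeats
    of ``ir_len`` bases, and the length of the target-site duplication it
    creates on transposition."""

    name: str
    sequence: str
    ir_len: int = 25
    tsd_len: int = 8
    min_length: int = 700
    max_length: int = 3000

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (self.min_length <= n <= self.max_length):
            raise ValueError(
                f"IS element {self.name}: length {n} outside "
                f"[{self.min_length}, {self.max_length}]"
            )
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if 2 * self.ir_len > n:
            raise ValueError("inverted repeats longer than the element")
        head = self.sequence[: self.ir_len]
        tail = self.sequence[n - self.ir_len :]
        if head != revcomp(tail):
            raise ValueError(
                f"IS element {self.name}: termini are not inverted repeats"
            )


@dataclass
class TruthEvent:
    """A planted mutation, recorded on the original reference frame.

    For insertions ``position`` is the breakpoint on the original
    reference (the element plus TSD is inserted there); for deletions
    ``position``/``end`` bound the removed interval.  After
    :func:`plant_events`, ``mut_start``/``mut_end`` give the event's
    footprint on the mutated frame (the inserted element's span, or the
    zero-length junction left by a deletion).
    """

    kind: str  # "insertion" | "deletion"
    replicon: str
    position: int
    end: int | None = None  # deletions only (half-open)
    element: str | None = None  # insertions only
    strand: str = "+"
    size: int = 0
    mut_start: int | None = None
    mut_end: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "deletion":
            if self.end is None or self.end <= self.position:
                raise ValueError("deletion needs a non-empty [start, end)")
        if self.kind == "insertion" and self.strand not in "+-":
            raise ValueError("insertion strand must be '+' or '-'")

    @property
    def ref_interval(self) -> tuple[int, int]:
        """Footprint on the original reference (point for insertions)."""
        if self.kind == "deletion":
            return (self.position, self.end)
        return (self.position, self.position)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "replicon": self.replicon,
            "position": self.position,
            "end": self.end,
            "element": self.element,
            "strand": self.strand,
            "size": self.size,
            "mut_start": self.mut_start,
            "mut_end": self.mut_end,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthEvent":
        return cls(**d)


def generate_genome(
    n_replicons: int,
    lengths: list[int],
    gc: float,
    seed: int,
    names: list[str] | None = None,
) -> ReferenceGenome:
    """Generate ``n_replicons`` i.i.d. random replicons with expected GC
    content ``gc``.  Deterministic for a fixed seed."""
    if n_replicons < 1 or len(lengths) != n_replicons:
        raise ValueError("need one positive length per replicon")
    if any(L <= 0 for L in lengths):
        raise ValueError("replicon lengths must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    if names is None:
        names = [f"replicon{i + 1}" for i in range(n_replicons)]
    if len(set(names)) != n_replicons:
        raise ValueError("replicon names must be unique")
    rng = np.random.default_rng(seed)
    return ReferenceGenome(
        {name: _random_dna(rng, L, gc) for name, L in zip(names, lengths)}
    )


def _identity(a: str, b: str) -> float:
    """Positional identity over the shorter sequence (crude, sufficient
    to enforce that random catalog elements are mutually dissimilar)."""
    n = min(len(a), len(b))
    same = sum(x == y for x, y in zip(a[:n], b[:n]))
    return same / n


def generate_is_catalog(
    names: list[str],
    lengths: list[int],
    ir_len: int = 25,
    tsd_len: int = 8,
    seed: int = 0,
    gc: float = 0.55,
    max_identity: float = 0.60,
) -> list[ISElement]:
    """Generate an IS catalog with terminal inverted repeats.

    Elements are rejection-sampled until every pair of distinct elements
    shares < ``max_identity`` positional identity, so that mate mapping
    can discriminate which element a read came from.
    """
    if len(set(names)) != len(names):
        raise ValueError("catalog names must be unique")
    if len(lengths) != len(names):
        raise ValueError("need one length per name")
    for name, L in zip(names, lengths):
        if 2 * ir_len > L:
            raise ValueError(f"{name}: 2*ir_len={2 * ir_len} exceeds length {L}")
    rng = np.random.default_rng(seed)
    catalog: list[ISElement] = []
    for name, L in zip(names, lengths):
        for _ in range(100):
            body = _random_dna(rng, L, gc)
            seq = body[: L - ir_len] + revcomp(body[:ir_len])
            if all(_identity(seq, other.sequence) < max_identity for other in catalog):
                catalog.append(
                    ISElement(name, seq, ir_len=ir_len, tsd_len=tsd_len)
                )
                break
        else:  # pragma: no cover - random sequences essentially never collide
            raise RuntimeError(f"could not sample a dissimilar sequence for {name}")
    return catalog


def plant_events(
    genome: ReferenceGenome,
    events: list[TruthEvent],
    catalog: list[ISElement],
) -> tuple[ReferenceGenome, list[TruthEvent]]:
    """Apply insertions and deletions to a genome.

    An insertion at reference position ``p`` duplicates the ``tsd_len``
    host bases at ``[p, p + tsd_len)`` so they flank the inserted element
    (target-site duplication); a deletion excises ``[start, end)``.
    Events on one replicon must not overlap.  Returns the mutated genome
    and the truth list annotated with mutated-frame coordinates.
    """
    by_name = {e.name: e for e in catalog}
    per_rep: dict[str, list[TruthEvent]] = {}
    for ev in events:
        if ev.replicon not in genome.replicons:
            raise ValueError(f"unknown replicon {ev.replicon!r}")
        if ev.kind == "insertion" and ev.element not in by_name:
            raise ValueError(f"unknown IS element {ev.element!r}")
        per_rep.setdefault(ev.replicon, []).append(ev)

    mutated: dict[str, str] = {}
    out_events: list[TruthEvent] = []
    for rep, seq in genome.replicons.items():
        evs = sorted(per_rep.get(rep, []), key=lambda e: e.position)
        L = len(seq)
        prev_end = -1
        for ev in evs:
            a, b = ev.ref_interval
            if a < 0 or b > L or (ev.kind == "insertion" and a > L):
                raise ValueError(f"event outside replicon {rep}: {ev}")
            lo = a if ev.kind == "deletion" else a
            if lo < prev_end or (ev.kind == "insertion" and a < prev_end):
                raise ValueError(f"overlapping events on {rep}")
            prev_end = b if ev.kind == "deletion" else a
        pieces: list[str] = []
        cursor = 0  # reference position consumed so far
        offset = 0  # mutated minus reference coordinate at cursor
        for ev in evs:
            if ev.kind == "insertion":
                element = by_name[ev.element]
                tsd = element.tsd_len
                p = ev.position
                if p + tsd > L:
                    raise ValueError(
                        f"TSD at {rep}:{p} extends past the replicon end"
                    )
                ins_seq = (
                    element.sequence if ev.strand == "+" else revcomp(element.sequence)
                )
                # host ..p+tsd) + element + host p.. (duplicating [p, p+tsd))
                pieces.append(seq[cursor : p + tsd])
                pieces.append(ins_seq)
                mut_start = p + tsd + offset
                mut_end = mut_start + len(ins_seq)
                out_events.append(
                    replace(
                        ev,
                        size=len(ins_seq) + tsd,
                        mut_start=mut_start,
                        mut_end=mut_end,
                    )
                )
                cursor = p
                offset += len(ins_seq) + tsd
            else:
                a, b = ev.position, ev.end
                pieces.append(seq[cursor:a])
                junction = a + offset
                out_events.append(
                    replace(ev, size=b - a, mut_start=junction, mut_end=junction)
                )
                cursor = b
                offset -= b - a
        pieces.append(seq[cursor:])
        mutated[rep] = "".join(pieces)
    return ReferenceGenome(mutated), out_events
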