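"""Paired-end read simulation from a (mutated) genome.

Fragments are placed uniformly along each replicon (weighted by replicon
length) with lengths drawn from a normal distribution truncated below at
twice the read length, mimicking an Illumina paired-end library.  Mate 1
reads the fragment's 5' end on the forward strand; mate 2 is the reverse
complement of its 3' end.  Sequencing error is i.i.d. per-base
substitution only — no indel errors — which keeps the ideal alignment
projection (:mod:`mobsv.liftover`) exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ReferenceGenome, revcomp

_BASES = b"ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters: fold coverage, read length, insert-size
    law (mean, sd), per-base substitution rate, and RNG seed."""

    coverage: float = 50.0
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert_mean must exceed 2*read_len")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")


@dataclass
class SimReadPair:
    """One simulated fragment: mate sequences plus true origins on the
    mutated genome (0-based fragment start, fragment length)."""

    pair_id: str
    replicon: str
    frag_start: int
    frag_len: int
    mate1: str  # forward strand, fragment 5' end
    mate2: str  # reverse complement of fragment 3' end

    @property
    def mate1_interval(self) -> tuple[int, int]:
        return (self.frag_start, self.frag_start + len(self.mate1))

    @property
    def mate2_interval(self) -> tuple[int, int]:
        end = self.frag_start + self.frag_len
        return (end - len(self.mate2), end)


def n_pairs_for(cfg: SimConfig, total_length: int) -> int:
    """Pair count giving the requested fold coverage:
    ``round(coverage * total_length / (2 * read_len))``."""
    return int(round(cfg.coverage * total_length / (2 * cfg.read_len)))


def _apply_errors(
    reads: list[bytearray], rng: np.random.Generator, error_rate: float
) -> None:
    """Substitute bases i.i.d. at ``error_rate`` (in place)."""
    if error_rate <= 0 or not reads:
        return
    read_len = len(reads[0])
    total = len(reads) * read_len
    n_err = rng.binomial(total, error_rate)
    flat = rng.integers(0, total, size=n_err)
    shifts = rng.integers(1, 4, size=n_err)
    for pos, shift in zip(flat.tolist(), shifts.tolist()):
        r, i = divmod(pos, read_len)
        old = _BASE_INDEX[reads[r][i]]
        reads[r][i] = _BASES[(old + shift) % 4]


def simulate_read_pairs(
    mutated: ReferenceGenome, cfg: SimConfig
) -> list[SimReadPair]:
    """Simulate paired-end reads from a genome, deterministically for a
    fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    reps = list(mutated.replicons)
    lengths = np.array([len(mutated[r]) for r in reps], dtype=float)
    total = int(lengths.sum())
    n = n_pairs_for(cfg, total)
    rep_idx = rng.choice(len(reps), size=n, p=lengths / lengths.sum())
    frag = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)
    frag = np.maximum(np.rint(frag), 2 * cfg.read_len).astype(int)
    u = rng.random(n)

    pairs: list[SimReadPair] = []
    mate1_raw: list[bytearray] = []
    mate2_raw: list[bytearray] = []
    for k in range(n):
        rep = reps[rep_idx[k]]
        L = len(mutated[rep])
        f = min(frag[k], L)
        start = int(u[k] * (L - f + 1))
        fragment = mutated[rep][start : start + f]
        m1 = fragment[: cfg.read_len]
        m2 = revcomp(fragment[f - cfg.read_len :])
        mate1_raw.append(bytearray(m1, "ascii"))
        mate2_raw.append(bytearray(m2, "ascii"))
        pairs.append(SimReadPair(f"pair{k:07d}", rep, start, f, "", ""))
    _apply_errors(mate1_raw, rng, cfg.error_rate)
    _apply_errors(mate2_raw, rng, cfg.error_rate)
    for p, m1, m2 in zip(pairs, mate1_raw, mate2_raw):
        p.mate1 = m1.decode("ascii")
        p.mate2 = m2.decode("ascii")
    return pairs


def write_fastq(pairs: list[SimReadPair], path1: str, path2: str) -> None:
    """Write the two mate files with ``/1`` and ``/2`` read-name
    suffixes and constant quality."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.mate1)
            q2 = "I" * len(p.mate2)
            f1.write(f"@{p.pair_id}/1\n{p.mate1}\n+\n{q1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.mate2}\n+\n{q2}\n")
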