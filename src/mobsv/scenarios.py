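"""Built-in simulation scenarios.

The ``table4`` scenario re-enacts, at reduced genome scale, the zinc
adaptation experiment of *Cupriavidus metallidurans* CH34: a four-
replicon genome (chromosome, chromid and two megaplasmid stand-ins,
~400 kb total), a three-element IS catalog (IS1088, ISRme5, ISRme15)
and seven planted transpositions disrupting the seven loci found
mutated in the zinc-resistant derivative — five IS1088 copies, one
ISRme15 and one ISRme5, including the IS1088 hit in the glpR repressor
(Rmet_2235) that derepresses the adjacent ABC-type zinc/cadmium
transporter.  Locus coordinates are synthetic stand-ins; the locus
tags, products and element identities are the real ones.

The ``null`` scenario is the matched event-free control for
specificity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import GeneFeature
from .genome import (
    ISElement,
    ReferenceGenome,
    TruthEvent,
    generate_genome,
    generate_is_catalog,
)

#: (locus_tag, product, inserted element) for the seven mutated loci.
TABLE4_LOCI: list[tuple[str, str, str]] = [
    ("Rmet_2146", "ABC superfamily transporter subunit", "IS1088"),
    ("Rmet_2171", "Conserved hypothetical protein", "ISRme15"),
    ("Rmet_2235", "DNA-binding transcriptional repressor", "IS1088"),
    ("Rmet_4452", "Response regulator receiver domain protein (CheY-like)", "IS1088"),
    ("Rmet_4521", "Transcriptional regulator", "ISRme5"),
    (
        "Rmet_4574",
        "Acyl-CoA dehydrogenase protein",
        "IS1088",
    ),
    (
        "Rmet_5200",
        "Putative glyoxalase/bleomycin resistance protein/"
        "dihydroxy-biphenyl dioxygenase",
        "IS1088",
    ),
]

# synthetic fixture coordinates: (replicon, gene start); genes are 900 bp,
# breakpoints at gene midpoints, spacing far beyond twice the insert size
_TABLE4_PLACEMENT: list[tuple[str, int]] = [
    ("CHR1", 40_000),
    ("CHR1", 90_000),
    ("CHR1", 150_000),
    ("CHR2", 20_000),
    ("CHR2", 45_000),
    ("CHR2", 70_000),
    ("CHR2", 92_000),
]

_GENE_LEN = 900

#: replicon stand-ins for chromosome, chromid, pMOL28, pMOL30
TABLE4_REPLICONS: dict[str, int] = {
    "CHR1": 200_000,
    "CHR2": 100_000,
    "pMOL28": 60_000,
    "pMOL30": 40_000,
}

TABLE4_GC = 0.61

#: element lengths within the bacterial IS size range
CATALOG_SPEC: list[tuple[str, int]] = [
    ("IS1088", 1050),
    ("ISRme5", 1200),
    ("ISRme15", 1500),
]

_GENOME_SEED = 20_210_309  # fixed: the reference is a constant, like a real one
_CATALOG_SEED = 1088


@dataclass
class Scenario:
    """A fully specified simulation input: genome, catalog, events to
    plant, and the gene annotation."""

    name: str
    genome: ReferenceGenome
    catalog: list[ISElement]
    events: list[TruthEvent] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)


def default_catalog(tsd_len: int = 8, ir_len: int = 25) -> list[ISElement]:
    names = [n for n, _ in CATALOG_SPEC]
    lengths = [L for _, L in CATALOG_SPEC]
    return generate_is_catalog(
        names, lengths, ir_len=ir_len, tsd_len=tsd_len, seed=_CATALOG_SEED
    )


def _base_genome(genome_seed: int = _GENOME_SEED) -> ReferenceGenome:
    names = list(TABLE4_REPLICONS)
    lengths = list(TABLE4_REPLICONS.values())
    return generate_genome(len(names), lengths, TABLE4_GC, genome_seed, names=names)


def _table4_features() -> list[GeneFeature]:
    feats = [
        GeneFeature(tag, product, rep, start, start + _GENE_LEN)
        for (tag, product, _), (rep, start) in zip(TABLE4_LOCI, _TABLE4_PLACEMENT)
    ]
    # a few unmutated neighbours so intergenic assignment is exercised
    feats.append(
        GeneFeature("Rmet_2229", "ABC-type transporter, permease component",
                    "CHR1", 152_500, 155_000)
    )
    feats.append(
        GeneFeature("Rmet_5800", "Heavy metal efflux pump CzcA homolog",
                    "pMOL30", 10_000, 13_000)
    )
    return feats


def table4_scenario(genome_seed: int = _GENOME_SEED) -> Scenario:
    """Seven IS transpositions at the seven mutated loci."""
    genome = _base_genome(genome_seed)
    catalog = default_catalog()
    events = []
    for (tag, _, element), (rep, start) in zip(TABLE4_LOCI, _TABLE4_PLACEMENT):
        events.append(
            TruthEvent(
                kind="insertion",
                replicon=rep,
                position=start + _GENE_LEN // 2,
                element=element,
                strand="+",
            )
        )
    return Scenario("table4", genome, catalog, events, _table4_features())


def null_scenario(
    genome_seed: int = _GENOME_SEED,
    replicons: dict[str, int] | None = None,
) -> Scenario:
    """Event-free control on the same genome (or a smaller one)."""
    if replicons is None:
        genome = _base_genome(genome_seed)
    else:
        genome = generate_genome(
            len(replicons),
            list(replicons.values()),
            TABLE4_GC,
            genome_seed,
            names=list(replicons),
        )
    return Scenario("null", genome, default_catalog(), [], _table4_features()
                    if replicons is None else [])


def size_rule_scenario(genome_seed: int = _GENOME_SEED) -> Scenario:
    """One 150 bp and one 500 bp deletion: only the latter exceeds the
    200 bp reporting cutoff."""
    genome = _base_genome(genome_seed)
    events = [
        TruthEvent("deletion", "CHR1", 60_000, end=60_150),
        TruthEvent("deletion", "CHR1", 120_000, end=120_500),
    ]
    return Scenario("size_rule", genome, default_catalog(), events,
                    _table4_features())


SCENARIOS = {
    "table4": table4_scenario,
    "null": null_scenario,
    "size_rule": size_rule_scenario,
}


def get_scenario(name: str, genome_seed: int = _GENOME_SEED) -> Scenario:
    try:
        builder = SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
    return builder(genome_seed=genome_seed)
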