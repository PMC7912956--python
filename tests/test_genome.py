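"""Genome generation, IS catalogs, and event planting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobsv.genome import (
    ISElement,
    TruthEvent,
    generate_genome,
    generate_is_catalog,
    plant_events,
    revcomp,
)
from mobsv.scenarios import default_catalog


class TestGenerateGenome:
    def test_length_conservation(self):
        g = generate_genome(1, [10_000], 0.5, seed=1)
        assert g.total_length == 10_000
        (seq,) = g.replicons.values()
        assert len(seq) == 10_000

    def test_determinism(self):
        a = generate_genome(2, [5_000, 3_000], 0.4, seed=1)
        b = generate_genome(2, [5_000, 3_000], 0.4, seed=1)
        assert a.replicons == b.replicons
        c = generate_genome(2, [5_000, 3_000], 0.4, seed=2)
        assert a.replicons != c.replicons

    def test_gc_content(self):
        gc = 0.61
        g = generate_genome(4, [200_000, 100_000, 60_000, 40_000], gc, 7)
        L = g.total_length
        counts = sum(s.count("G") + s.count("C") for s in g.replicons.values())
        tol = 3 * np.sqrt(gc * (1 - gc) / L)
        assert abs(counts / L - gc) < tol

    def test_alphabet(self):
        g = generate_genome(1, [2_000], 0.3, seed=0)
        assert set(g["replicon1"]) <= set("ACGT")

    @pytest.mark.parametrize(
        "args",
        [
            (1, [0], 0.5, 1),
            (1, [-5], 0.5, 1),
            (2, [100], 0.5, 1),
            (1, [100], 0.0, 1),
            (1, [100], 1.0, 1),
        ],
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            generate_genome(*args)


class TestISCatalog:
    def test_default_catalog_shape(self, catalog):
        assert [e.name for e in catalog] == ["IS1088", "ISRme5", "ISRme15"]
        assert [len(e.sequence) for e in catalog] == [1050, 1200, 1500]

    def test_inverted_repeats(self, catalog):
        for e in catalog:
            assert e.sequence[: e.ir_len] == revcomp(e.sequence[-e.ir_len :])

    def test_pairwise_dissimilarity(self, catalog):
        for i, a in enumerate(catalog):
            for b in catalog[i + 1 :]:
                n = min(len(a.sequence), len(b.sequence))
                ident = sum(
                    x == y for x, y in zip(a.sequence[:n], b.sequence[:n])
                ) / n
                assert ident < 0.60

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_is_catalog(["a"], [700], ir_len=400)
        with pytest.raises(ValueError):
            generate_is_catalog(["a", "a"], [800, 900])

    def test_element_invariants_enforced(self):
        with pytest.raises(ValueError):
            ISElement("tiny", "ACGT" * 50)  # below the IS size range
        seq = "A" * 1000
        with pytest.raises(ValueError):  # termini not inverted repeats
            ISElement("bad", seq, ir_len=25)


class TestPlantEvents:
    def test_insertion_arithmetic(self, catalog):
        g = generate_genome(1, [10_000], 0.5, seed=3, names=["chr"])
        ev = TruthEvent("insertion", "chr", 5_000, element="IS1088")
        mutated, truth = plant_events(g, [ev], catalog)
        assert len(mutated["chr"]) == 10_000 + 1050 + 8
        (t,) = truth
        assert t.size == 1058
        elem = catalog[0]
        # target-site duplication flanks the element
        assert mutated["chr"][5_000 : 5_008] == g["chr"][5_000:5_008]
        assert mutated["chr"][t.mut_start : t.mut_end] == elem.sequence
        assert mutated["chr"][t.mut_end : t.mut_end + 8] == g["chr"][5_000:5_008]

    def test_reverse_strand_insertion(self, catalog):
        g = generate_genome(1, [5_000], 0.5, seed=4, names=["chr"])
        ev = TruthEvent("insertion", "chr", 2_000, element="ISRme5", strand="-")
        mutated, truth = plant_events(g, [ev], catalog)
        (t,) = truth
        assert mutated["chr"][t.mut_start : t.mut_end] == revcomp(
            catalog[1].sequence
        )

    def test_deletion_excision(self, catalog):
        g = generate_genome(1, [10_000], 0.5, seed=5, names=["chr"])
        ev = TruthEvent("deletion", "chr", 2_000, end=3_000)
        mutated, _ = plant_events(g, [ev], catalog)
        assert len(mutated["chr"]) == 9_000
        assert mutated["chr"] == g["chr"][:2_000] + g["chr"][3_000:]

    def test_overlapping_events_rejected(self, catalog):
        g = generate_genome(1, [10_000], 0.5, seed=6, names=["chr"])
        evs = [
            TruthEvent("deletion", "chr", 2_000, end=3_000),
            TruthEvent("insertion", "chr", 2_500, element="IS1088"),
        ]
        with pytest.raises(ValueError):
            plant_events(g, evs, catalog)

    def test_unknown_element_rejected(self, catalog):
        g = generate_genome(1, [10_000], 0.5, seed=7, names=["chr"])
        ev = TruthEvent("insertion", "chr", 100, element="IS_nope")
        with pytest.raises(ValueError):
            plant_events(g, [ev], catalog)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_length_bookkeeping(self, data):
        """Mutated length = original + sum(element+TSD) - sum(deletions),
        for random non-overlapping event sets."""
        catalog = default_catalog()
        L = 30_000
        g = generate_genome(1, [L], 0.5, seed=11, names=["chr"])
        n = data.draw(st.integers(0, 6))
        anchors = sorted(
            data.draw(
                st.lists(
                    st.integers(500, L - 1_500),
                    min_size=n,
                    max_size=n,
                    unique=True,
                )
            )
        )
        anchors = [
            a for i, a in enumerate(anchors) if i == 0 or a - anchors[i - 1] > 1_200
        ]
        events, expected_delta = [], 0
        for a in anchors:
            if data.draw(st.booleans()):
                name = data.draw(st.sampled_from([e.name for e in catalog]))
                elem = next(e for e in catalog if e.name == name)
                events.append(TruthEvent("insertion", "chr", a, element=name))
                expected_delta += len(elem.sequence) + elem.tsd_len
            else:
                size = data.draw(st.integers(1, 1_000))
                events.append(TruthEvent("deletion", "chr", a, end=a + size))
                expected_delta -= size
        mutated, truth = plant_events(g, events, catalog)
        assert len(mutated["chr"]) - L == expected_delta
        assert len(truth) == len(events)
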