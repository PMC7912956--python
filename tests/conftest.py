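import pytest

from mobsv import classify as cls
from mobsv.genome import plant_events
from mobsv.liftover import project_ideal_alignments
from mobsv.pipeline import PipelineConfig, run_pipeline
from mobsv.scenarios import default_catalog
from mobsv.simulate import SimConfig, simulate_read_pairs


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def catalog_names(catalog):
    return {e.name for e in catalog}


@pytest.fixture(scope="session")
def table4_run(tmp_path_factory):
    """One full table4 pipeline execution shared across tests."""
    outdir = tmp_path_factory.mktemp("table4")
    cfg = PipelineConfig(scenario="table4", seed=17, outdir=str(outdir))
    result = run_pipeline(cfg)
    return cfg, result


def simulate_to_sam(genome, events, catalog, cfg, sam_path, min_anchor=20):
    """Plant events, simulate reads, project ideal alignments; returns
    (mutated genome, truth, simulated pairs)."""
    mutated, truth = plant_events(genome, events, catalog)
    pairs = simulate_read_pairs(mutated, cfg)
    project_ideal_alignments(
        pairs, genome, catalog, truth, str(sam_path), min_anchor=min_anchor
    )
    return mutated, truth, pairs


def classify_sam(sam_path, catalog_names, k_sd=5.0, min_model_pairs=500,
                 min_mapq=20):
    records = cls.read_alignments(str(sam_path), catalog_names)
    model = cls.estimate_insert_model(
        records, k_sd=k_sd, min_model_pairs=min_model_pairs
    )
    classified = cls.classify_pairs(records, model, catalog_names, min_mapq)
    return records, model, classified
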