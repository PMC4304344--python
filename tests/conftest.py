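import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import senescmir as sm
from senescmir import read_processing as rp
from senescmir import sim
from senescmir import srna_quant as sq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """The full synthetic study shared across tests: 8 sRNA libraries at
    100k reads each (the depth at which the 50 TP2M floor separates planted
    signal from singleton sampling noise), processed end to end."""
    cfg = sm.default_config(seed=11, depth=100_000)
    ref = sm.build_reference(cfg)
    index = rp.GenomeIndex(ref.genome)
    catalog = sq.MirnaCatalog.from_mapping(sim.build_catalog(cfg))
    processed = {}
    for spec in cfg.srna_libraries:
        raw = sim.simulate_srna_library(ref, spec.tissue, spec.stage)
        processed[spec.lib_id] = rp.process_library(
            raw, cfg.adapter3, index, ref.features,
            library_id=spec.lib_id, tissue=spec.tissue, stage=spec.stage,
        )
    matrix = rp.abundance_matrix(p.abundance for p in processed.values())
    hits = {}
    for p in processed.values():
        hits.update(p.hits_by_seq)
    return {
        "config": cfg,
        "reference": ref,
        "index": index,
        "catalog": catalog,
        "processed": processed,
        "matrix": matrix,
        "hits": hits,
    }


@pytest.fixture(scope="session")
def mirna_matrix(study) -> pd.DataFrame:
    return sq.mirna_matrix(study["matrix"], study["catalog"])


@pytest.fixture(scope="session")
def mature_ledger(study) -> pd.DataFrame:
    led = study["reference"].ledger
    return led[led.record == "mature"].set_index("name")
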