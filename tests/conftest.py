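import numpy as np
import pandas as pd
import pytest

from matflux.catalog import default_catalog
from matflux.quant import CountTable


def mole_bookkeeping_enrichment(v_add, t_conc, v_inc, nat_conc, nat_ab_pct, f_t=1.0):
    """Independent oracle for pool excess enrichment.

    Counts heavy and total moles of the mixed dissolved pool explicitly and
    forms atom % by division — no shared code with the implementation.
    """
    tracer_mol = v_add * t_conc
    ambient_mol = v_inc * nat_conc
    heavy_mol = tracer_mol * f_t + ambient_mol * nat_ab_pct / 100.0
    total_mol = tracer_mol + ambient_mol
    return 100.0 * heavy_mol / total_mol - nat_ab_pct


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def toy_annotations():
    return pd.DataFrame(
        {
            "feature_id": ["f1", "f2", "f3", "f4"],
            "gene_symbol": ["nifH", "rbcL", "rbcL", "amoA"],
            "length_bp": [1000, 500, 2000, 1000],
            "taxon_lineage": [
                "Bacteria;Cyanobacteria;C;O;F;Mastigocladus",
                "Bacteria;Cyanobacteria;C;O;F;Mastigocladus",
                "Bacteria;Proteobacteria;C;O;F;Bradyrhizobium",
                "Archaea;Thaumarchaeota;C;O;F;Nitrososphaera",
            ],
        }
    )


@pytest.fixture()
def toy_counts(toy_annotations):
    counts = pd.DataFrame(
        {
            "s_day": [30, 100, 10, 5],
            "s_night": [10, 0, 40, 5],
        },
        index=pd.Index(toy_annotations["feature_id"], name="feature_id"),
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s_day", "s_night"],
            "temperature_C": [58, 58],
            "library": ["cDNA", "cDNA"],
            "time_of_day": ["day", "night"],
            "library_size": [1_000_000, 1_000_000],
        }
    )
    return CountTable(counts=counts, samples=samples)
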