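import numpy as np
import pandas as pd
import pytest

from allomix.isotope_prep import ConsumerPreprocessor
from allomix.sources import SourceBuilder
from allomix.synthetic import GeneratorConfig, TaxonSpec, generate_dataset

# a compact four-taxon design spanning the allochthony range, with both
# baseline taxa present so the preprocessing stage can resolve every group
SMALL_TAXA = (
    TaxonSpec("cladocera", "pelagic", 2.1, -0.55, 0.10),
    TaxonSpec("asellus", "littoral", 2.1, -1.67, -0.10),
    TaxonSpec("chironomid_profundal", "profundal", 2.2, -2.58, -0.05),
    TaxonSpec("perch_large", "fish", 3.8, -0.18, 0.00),
)


def small_config(**overrides) -> GeneratorConfig:
    kw = dict(n_lakes=8, taxa=SMALL_TAXA, samples_per_taxon_lake=2, seed=7)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def model_data_from(ds: dict) -> pd.DataFrame:
    """Preprocess a generated dataset and join source pairs + true covariate."""
    lakes, cons = ds["lakes"], ds["consumers"]
    cons = cons.merge(lakes[["lake_id", "d2h_water", "covariate"]], on="lake_id")
    prepared = ConsumerPreprocessor().fit(cons).transform(cons)
    src = lakes[["lake_id", "d2h_water", "d2h_inlet_dom"]].copy()
    src["substitute_lake_id"] = ""
    pairs = SourceBuilder().fit(src).transform(src)
    return prepared.merge(pairs, on="lake_id")


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def small_model_data(small_dataset):
    return model_data_from(small_dataset)


@pytest.fixture(scope="session")
def single_cell_data():
    """One taxon in one lake with known sources: the reduced-model setting."""
    rng = np.random.default_rng(42)
    T, A = -70.0, -170.0
    y = 0.3 * T + 0.7 * A + rng.normal(0, 20, 15)
    return pd.DataFrame(
        {
            "lake_id": "L1",
            "taxon": "tax",
            "d2h_corrected": y,
            "d2h_corrected_sd": 13.0,
            "terrestrial_mean": T,
            "terrestrial_sd": 11.2,
            "aquatic_mean": A,
            "aquatic_sd": 23.6,
        }
    )
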