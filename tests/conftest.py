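import numpy as np
import pandas as pd
import pytest

from evomethylome import synthdata
from evomethylome.dataset import CohortDataset
from evomethylome.io_formats import validate_sample_sheet


def make_sheet(groups, conversion=0.998):
    """groups: list of (species, cell_type, n)."""
    rows = []
    for sp, ct, n in groups:
        for i in range(n):
            rows.append({"sample_id": f"{sp}_{ct}_{i}", "species": sp,
                         "cell_type": ct, "sex": "F" if i % 2 else "M",
                         "age_class": ("young", "middle", "old")[i % 3],
                         "conversion_rate": conversion})
    return validate_sample_sheet(pd.DataFrame(rows))


def make_dataset(coverage, meth, sheet, positions=None, context="CG",
                 chrom="chr1"):
    """In-memory CohortDataset from count matrices (sites × samples)."""
    coverage = np.asarray(coverage)
    meth = np.asarray(meth)
    if positions is None:
        positions = np.arange(coverage.shape[0]) * 10
    sites = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "strand": "+", "context": context})
    return CohortDataset(sites, coverage.astype(np.int64),
                         meth.astype(np.int64), sheet)


@pytest.fixture(scope="session")
def small_config():
    """Reduced desk scenario shared by slower tests: one 20 kb chromosome."""
    return synthdata.SimulationConfig(
        chrom_sizes={"chr1": 20_000},
        n_cg_sites=1_200, n_ch_sites=3_000,
        n_individuals={("human", "NeuN"): 12, ("human", "OLIG2"): 12,
                       ("chimpanzee", "NeuN"): 11, ("chimpanzee", "OLIG2"): 11,
                       ("macaque", "NeuN"): 12, ("macaque", "OLIG2"): 11},
        roster=[synthdata.PlantedDmr("conserved_celltype", "CG", 400, 0.30, 1),
                synthdata.PlantedDmr("human_specific_hypo", "CG", 400, 0.28, -1),
                synthdata.PlantedDmr("chimp_specific_hyper", "CG", 400, 0.28, 1),
                synthdata.PlantedDmr("celltype_restricted_species_change",
                                     "CG", 400, 0.30, -1, cell_type="NeuN"),
                synthdata.PlantedDmr("human_specific_hyper", "CH", 300, 0.25, 1,
                                     cell_type="NeuN")],
        seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return synthdata.simulate_dataset(small_config)
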