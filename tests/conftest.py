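import numpy as np
import pytest
from hypothesis import settings

from piebaldnet.genotypes import CASE, CONTROL, GenotypeTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_table(calls, labels=None, chroms=None, positions=None):
    """Build a GenotypeTable from a plain list-of-lists of genotype codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_a, n_s = calls.shape
    animal_ids = [f"a{i}" for i in range(n_a)]
    snp_ids = [f"s{j}" for j in range(n_s)]
    if chroms is None:
        chroms = ["chr1"] * n_s
    if positions is None:
        positions = list(range(1, n_s + 1))
    lab = {}
    if labels is not None:
        for a, status in zip(animal_ids, labels):
            lab[a] = status
    return GenotypeTable(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chromosomes=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions),
        calls=calls,
        labels=lab,
    )


@pytest.fixture
def case_control_table():
    """4 cases + 8 controls over 3 SNPs with a strong case-enriched SNP."""
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(12, 3))
    calls[:4, 0] = 2  # cases loaded with the B allele at SNP 0
    calls[4:, 0] = 0
    return make_table(calls, labels=[CASE] * 4 + [CONTROL] * 8)


# Normalized expression rows for a selection of genes: the five varieties in
# the order NOR, PBB, PBW, RSB, RSW.  Used as worked-example inputs for the
# DE contrast arithmetic.
EXPRESSION_ROWS = {
    "ATRN": {"NOR": 6.15, "PBB": 8.43, "PBW": 8.42, "RSB": 7.59, "RSW": 8.99},
    "IGFBP7": {"NOR": 11.37, "PBB": 10.35, "PBW": 9.7, "RSB": 9.87, "RSW": 10.7},
    "CD9": {"NOR": 9.63, "PBB": 9.32, "PBW": 9.01, "RSB": 8.33, "RSW": 9.58},
}
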