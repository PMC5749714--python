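import numpy as np
import pandas as pd
import pytest

from cavecom.community_data import IncidenceMatrix, TaxonomyTable


@pytest.fixture
def small_matrix() -> IncidenceMatrix:
    values = np.array([
        [1, 1, 0, 0],
        [0, 1, 1, 0],
        [1, 0, 0, 1],
    ])
    return IncidenceMatrix(values, ("a", "b", "c"), ("s1", "s2", "s3", "s4"))


@pytest.fixture
def springtail_taxonomy() -> TaxonomyTable:
    """The two fully classified springtail species used as the worked
    example of the taxonomic step distance (suborder unnamed for both)."""
    frame = pd.DataFrame(
        {
            "order": ["Poduromorpha", "Entomobryomorpha"],
            "superfamily": ["Neanuroidea", "Entomobryoidea"],
            "family": ["Neanuridae", "Lepidocyrtidae"],
            "subfamily": ["Pseudachorutinae", "Lepidocyrtinae"],
            "tribe": ["Pseudachorutini", "Lepidocyrtini"],
            "genus": ["Anurida", "Lepidocyrtus"],
            "subgenus": ["Anurida", "Lanocyrtus"],
        },
        index=["Anurida subarctica", "Lepidocyrtus selvaticus"],
    )
    return TaxonomyTable(frame)


@pytest.fixture(scope="session")
def regional_census_bundle():
    from cavecom.synthetic import regional_census_dataset

    return regional_census_dataset(seed=1)


def brute_force_c_score(values: np.ndarray) -> float:
    """Exhaustive C-score: count 2x2 checkerboard submatrices per species
    pair by enumerating all site pairs, then average over species pairs."""
    n_species, n_sites = values.shape
    total = 0
    n_pairs = 0
    for i in range(n_species):
        for j in range(i + 1, n_species):
            cu = 0
            for k in range(n_sites):
                for l in range(k + 1, n_sites):
                    sub = (values[i, k], values[i, l], values[j, k], values[j, l])
                    if sub in ((1, 0, 0, 1), (0, 1, 1, 0)):
                        cu += 1
            total += cu
            n_pairs += 1
    return total / n_pairs


def brute_force_nodf(values: np.ndarray) -> float:
    """Direct NODF per definition, looping over row and column pairs."""
    def axis_pairs(mat):
        contributions = []
        for i in range(mat.shape[0]):
            for j in range(i + 1, mat.shape[0]):
                fi, fj = mat[i].sum(), mat[j].sum()
                if fi == fj:
                    contributions.append(0.0)
                else:
                    poorer, richer = (mat[j], mat[i]) if fi > fj else (mat[i], mat[j])
                    if poorer.sum() == 0:
                        contributions.append(0.0)
                    else:
                        overlap = int(np.dot(poorer, richer))
                        contributions.append(100.0 * overlap / poorer.sum())
        return contributions

    parts = axis_pairs(values) + axis_pairs(values.T)
    return sum(parts) / len(parts)
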