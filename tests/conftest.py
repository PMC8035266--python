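import numpy as np
import pandas as pd
import pytest

from pneumotyper import abundance, diversity, synthetic
from pneumotyper.core_io import CountTable


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort shared across read-only tests."""
    return synthetic.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def processed_cohort(cohort):
    """Filtered, rarefied, relative+absolute matrices of the default cohort."""
    table, info, truth = cohort
    filtered, kept, _ = abundance.filter_dataset(table, info)
    rarefied = abundance.rarefy(filtered, seed=11)
    rel = abundance.to_relative(rarefied)
    absolute = abundance.to_absolute(rel, kept)
    return {
        "table": rarefied,
        "info": kept,
        "truth": truth,
        "relative": rel,
        "absolute": absolute,
    }


@pytest.fixture(scope="session")
def bray_curtis_dm(processed_cohort):
    return diversity.beta_matrix(processed_cohort["relative"], "bray_curtis")


@pytest.fixture
def toy_table():
    """3 samples x 4 OTUs with full taxonomy."""
    counts = pd.DataFrame(
        [[10, 30, 60, 0], [5, 5, 5, 5], [0, 0, 100, 100]],
        index=["s1", "s2", "s3"],
        columns=["o1", "o2", "o3", "o4"],
    )
    tax = {
        o: {"kingdom": "Bacteria", "phylum": "Firmicutes", "genus": f"g{o}"}
        for o in counts.columns
    }
    return CountTable(counts, tax)


def random_dissimilarity(n: int, rng: np.random.Generator) -> diversity.DissimilarityMatrix:
    """Random symmetric dissimilarity matrix in [0, 1]."""
    pts = rng.random((n, 4))
    D = np.abs(pts[:, None, :] - pts[None, :, :]).mean(axis=2)
    D = D / max(D.max(), 1e-9)
    np.fill_diagonal(D, 0.0)
    return diversity.DissimilarityMatrix([f"s{i}" for i in range(n)], D, "bray_curtis")
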