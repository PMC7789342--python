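import numpy as np
import pandas as pd
import pytest

from ssrkit import simdata


@pytest.fixture(scope="session")
def small_genome():
    """Five 1.5 kb scaffolds with three planted SSRs and exact truth."""
    spec = simdata.SyntheticGenomeSpec(
        n_scaffolds=5,
        scaffold_length=1500,
        gc_fraction=0.45,
        planted_ssrs=[("AG", 10, 0, 300), ("AAT", 7, 1, 700), ("A", 9, 2, 150)],
        seed=11,
    )
    scaffolds, truth = simdata.simulate_genome(spec)
    return dict(scaffolds), truth


@pytest.fixture(scope="session")
def population_panel():
    """27-accession, three-group codominant panel with moderate structure."""
    spec = simdata.PopSimSpec(
        group_sizes=(8, 6, 13),
        n_loci=30,
        alleles_per_locus=3,
        target_fst=0.25,
        missing_rate=0.05,
        seed=7,
        group_names=("MGL", "SI", "QTP"),
    )
    matrix, groups, freqs = simdata.simulate_population(spec)
    return matrix, groups, freqs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genotype_matrix(rng, n=12, loci=6, alleles=3):
    cells = []
    for _ in range(n):
        row = []
        for _ in range(loci):
            pair = sorted(rng.integers(1, alleles + 1, size=2))
            row.append(f"{pair[0]}/{pair[1]}")
        cells.append(row)
    return pd.DataFrame(
        cells,
        index=[f"acc{i}" for i in range(n)],
        columns=[f"L{j}" for j in range(loci)],
    )
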