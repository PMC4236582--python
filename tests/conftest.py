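import warnings

import numpy as np
import pytest

from scarless import (
    DesignConfig,
    EditSpec,
    FixtureSpec,
    default_library,
    default_table,
    generate_fixture,
)


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def config():
    return DesignConfig()


@pytest.fixture()
def genome():
    return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture(autouse=True)
def _quiet_cds_warnings():
    # designs legitimately truncate CDS features in intermediate genomes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def synonymous_edit(genome, table, feature, variant, rng=None, rbs_boost=False):
    """An essential-gene EditSpec changing one degenerate mid-gene codon."""
    rng = rng or np.random.default_rng(0)
    cds = genome.extract(feature.region)
    n = len(cds) // 3
    order = list(range(max(2, n // 4), min(n - 1, 3 * n // 4)))
    rng.shuffle(order)
    for r in order:
        cod = cds[3 * (r - 1) : 3 * r]
        syn = [c for c in table.synonyms(cod) if c != cod]
        if syn:
            return EditSpec(
                kind="essential_gene",
                feature_id=feature.feature_id,
                variant=variant,
                mutations=[{"residue_index": r, "new_codon": syn[0]}],
                rbs_boost=rbs_boost,
            )
    raise AssertionError("no degenerate codon found in fixture gene")
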