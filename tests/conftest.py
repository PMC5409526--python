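import numpy as np
import pytest

from exoncnv import (
    CoverageMatrix,
    Implant,
    SimSpec,
    TargetRegion,
    TargetSet,
    make_panel,
    simulate_pool,
)


@pytest.fixture(scope="session")
def panel():
    """Default synthetic two-gene panel (49 targets, 2 chromosomes)."""
    targets, _annotation = make_panel(seed=1)
    return targets


@pytest.fixture(scope="session")
def clean_pool(panel):
    """48 CNV-negative samples at ~1000 reads/target."""
    matrix, truth = simulate_pool(SimSpec(n_samples=48, seed=1), panel)
    assert not truth
    return matrix


@pytest.fixture(scope="session")
def implant_pool(panel):
    """48-sample pool with known single- and multi-exon CNVs implanted."""
    spec = SimSpec(
        n_samples=48,
        seed=3,
        implants=(
            Implant(4, "GENEA", 7, 9, "deletion"),
            Implant(10, "GENEA", 13, 13, "duplication"),
            Implant(20, "GENEB", 12, 12, "deletion"),
            Implant(30, "GENEB", 20, 24, "duplication"),
        ),
    )
    matrix, truth = simulate_pool(spec, panel)
    return matrix, truth


@pytest.fixture()
def tiny_targets():
    return TargetSet(
        [
            TargetRegion("chr1", 100, 200, "G1"),
            TargetRegion("chr1", 300, 420, "G1"),
            TargetRegion("chr1", 5000, 5100, "G2"),
            TargetRegion("chr2", 50, 180, "G3"),
        ]
    )


@pytest.fixture()
def random_matrix(tiny_targets):
    rng = np.random.default_rng(11)
    counts = rng.integers(0, 2000, size=(len(tiny_targets), 3))
    return CoverageMatrix(tiny_targets, ["A", "B", "C"], counts)
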