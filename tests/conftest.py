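import numpy as np
import pytest

from polypopgen.genotypes import Genotype, GenotypeMatrix, Locus


@pytest.fixture
def trio_locus() -> Locus:
    return Locus("LwA", 3, (140, 200))


@pytest.fixture
def small_matrix(trio_locus) -> GenotypeMatrix:
    """Two populations x three individuals, two trinucleotide loci."""
    l2 = Locus("LwB", 3, (200, 260))
    cells = [
        [Genotype((150, 153, 153, 156), dosage_known=True), Genotype((210, 210, 213, 216), dosage_known=True)],
        [Genotype((150, 156)), Genotype((210, 213, 219))],
        [Genotype((153, 153, 156, 159), dosage_known=True), Genotype(())],
        [Genotype((150, 150, 150, 150), dosage_known=True), Genotype((216, 219))],
        [Genotype((159, 162)), Genotype((213, 213, 216, 222), dosage_known=True)],
        [Genotype((150, 153, 159, 162), dosage_known=True), Genotype((210, 222))],
    ]
    inds = [f"ind{i}" for i in range(6)]
    pops = {f"ind{i}": ("P1" if i < 3 else "P2") for i in range(6)}
    return GenotypeMatrix(inds, [trio_locus, l2], cells, pops)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
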