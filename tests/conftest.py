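import numpy as np
import pytest
from hypothesis import settings

from quantm.reference import TRNAGene, collapse_identical
from quantm.simulate import make_fixture_reference

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_gene(name="tRNA-Ala-AGC-1-1", seq=None, aa="Ala", ac="AGC",
              fam=1, copy=1, compartment="cytosolic"):
    if seq is None:
        rng = np.random.default_rng(abs(hash(name)) % (2**31))
        seq = "".join(rng.choice(list("ACGT"), size=76))
        seq = seq[:33] + ac + seq[36:]
    return TRNAGene(
        gene_name=name, amino_acid=aa, anticodon=ac, family_index=fam,
        copy_index=copy, sequence=seq, compartment=compartment,
    )


@pytest.fixture(scope="session")
def small_ref():
    """Six-family, two-member synthetic reference used across modules."""
    return make_fixture_reference(6, 2, seed=42)


@pytest.fixture(scope="session")
def tiny_ref():
    """Three divergent single-member entries (two anticodon classes)."""
    genes = [
        make_gene("tRNA-Ala-AGC-1-1", aa="Ala", ac="AGC", fam=1, copy=1),
        make_gene("tRNA-Ala-TGC-2-1", aa="Ala", ac="TGC", fam=2, copy=1),
        make_gene("tRNA-Gly-GCC-1-1", aa="Gly", ac="GCC", fam=1, copy=1),
    ]
    return collapse_identical(genes)
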