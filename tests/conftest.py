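import numpy as np
import pytest

from tcrforge import synthetic_data as sd
from tcrforge.io_repertoire import SpecificityRecord, TcrChain, TemplateComplex


@pytest.fixture(scope="session")
def toy_complex():
    """A toy complex with one ionic, one hydrogen-bond and one VDW contact."""
    return sd.generate_toy_complex(
        sd.ToyComplexSpec(
            contacts=((3, 2, 2.9, "IONIC"), (5, 5, 3.2, "HBOND"), (7, 8, 4.2, "VDW")),
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def toy_template(toy_complex):
    """The toy complex wrapped as an annotated template (alpha chain)."""
    core = toy_complex.cdr3_sequence
    template = TemplateComplex(
        pdb_id="toy1",
        structure=toy_complex.structure,
        chain_map={"tcr_alpha": "C", "peptide": "P"},
        cdr3_alpha_range=(1, len(core)),
        core_records={
            TcrChain.ALPHA: SpecificityRecord(
                cdr3=core, chain=TcrChain.ALPHA, v_gene="TRAV1-1*01",
                j_gene="TRAJ1*01", epitope=toy_complex.peptide_sequence,
                mhc_allele="HLA-A*02:01", record_id="toy1:alpha",
            )
        },
    )
    template.validate()
    return template


def make_record(cdr3, chain=TcrChain.ALPHA, v="TRAV1-1*01", j="TRAJ1*01",
                epitope="LLFGYPVYV", rid="r"):
    return SpecificityRecord(
        cdr3=cdr3, chain=chain, v_gene=v, j_gene=j, epitope=epitope,
        mhc_allele="HLA-A*02:01", record_id=rid,
    )


@pytest.fixture
def record_factory():
    return make_record
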