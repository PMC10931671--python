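import numpy as np
import pandas as pd
import pytest

from resilioprot.io_quant import ProteinQuantTable
from resilioprot.synthetic_data import SyntheticSpec, generate_dataset


def make_table(values, groups, peptides=None, unique=None, ids=None, genes=None):
    """Build a small ProteinQuantTable from a nested list / array.

    ``values`` is proteins x samples (NaN for missing); ``groups`` maps
    sample ids to phenotype labels (sample order = dict order).
    """
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    samples = list(groups)
    assert len(samples) == n_samp
    ids = ids or [f"P{i+1:03d}" for i in range(n_prot)]
    proteins = pd.DataFrame(
        {
            "gene": genes or [f"g{i+1}" for i in range(n_prot)],
            "peptides": peptides if peptides is not None else [5] * n_prot,
            "unique_peptides": unique if unique is not None else [3] * n_prot,
        },
        index=pd.Index(ids, name="protein_id"),
    )
    intens = pd.DataFrame(values, index=proteins.index, columns=samples)
    return ProteinQuantTable(proteins=proteins, intensities=intens,
                             sample_group=dict(groups))


@pytest.fixture
def two_group_labels():
    """8 resilient + 8 susceptible sample annotation."""
    return {**{f"R{i}": "resilient" for i in range(1, 9)},
            **{f"S{i}": "susceptible" for i in range(1, 9)}}


@pytest.fixture
def small_synthetic():
    """A compact generated dataset with every planted role present."""
    spec = SyntheticSpec(n_proteins=120, n_de=10, n_classsep=3, n_pairsep=1,
                         low_evidence_rate=0.05, seed=7)
    table, truth = generate_dataset(spec)
    return spec, table, truth


@pytest.fixture
def quant_tsv(tmp_path):
    """A 3-protein x 4-sample TSV fixture with one blank and one zero cell."""
    lines = [
        "Protein IDs\tGene names\tPeptides\tUnique peptides\tR1\tR2\tS1\tS2",
        "P001\tGeneA\t5\t3\t11000000\t\t9000000\t8500000",
        "P002\tGeneB\t1\t1\t2000000\t2100000\t0\t1900000",
        "P003\tGeneC\t4\t2\t5000000\t5200000\t4800000\t5100000",
    ]
    path = tmp_path / "quant.tsv"
    path.write_text("\n".join(lines) + "\n")
    ann = tmp_path / "annotation.csv"
    ann.write_text("sample,group\nR1,resilient\nR2,resilient\n"
                   "S1,susceptible\nS2,susceptible\n")
    return path, ann
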