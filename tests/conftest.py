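import numpy as np
import pandas as pd
import pytest

from scnome.types import sites_frame


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome genome covering every context class."""
    return {
        "chr1": "TACGAGCGTACCGTTGCATGCCGGCACG",
        "chr2": "ACGTGGCCATATGCGC",
    }


@pytest.fixture(scope="session")
def random_genome():
    """1 Mb i.i.d. uniform-composition genome, fixed seed."""
    rng = np.random.default_rng(12345)
    return {"chrR": "".join(rng.choice(list("ACGT"), 1_000_000))}


def random_sites(n, seed=0, chroms=("chr1",), max_pos=1000):
    """Random valid cytosine-report rows (positions need not be genomic Cs)."""
    rng = np.random.default_rng(seed)
    tris = ["ACG", "TCG", "GCG", "CCG", "GCA", "GCC", "GCT", "ACA"]
    df = pd.DataFrame(
        {
            "chrom": rng.choice(chroms, n),
            "pos": rng.integers(1, max_pos + 1, n),
            "strand": rng.choice(["+", "-"], n),
            "n_meth": rng.integers(0, 10, n),
            "n_unmeth": rng.integers(0, 10, n),
            "context": "CpG",
            "trinucleotide": rng.choice(tris, n),
        }
    )
    return df.drop_duplicates(subset=["chrom", "pos", "strand"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def qc_fixture():
    """Frozen 20-cell QC statistics table with known ES-preset outcomes.

    Cells 1-14 pass everything; the rest each violate exactly one
    threshold of the serum-ES preset.
    """
    rng = np.random.default_rng(77)
    rows = []
    for i in range(20):
        rows.append(
            {
                "cell_id": f"cell_{i + 1:02d}",
                "mapped_reads": int(rng.uniform(4e5, 2e6)),
                "mito_frac": float(rng.uniform(0.02, 0.12)),
                "n_genes": int(rng.uniform(3000, 9000)),
                "mapping_efficiency": float(rng.uniform(0.2, 0.5)),
                "cpg_sites": int(rng.uniform(6e5, 3e6)),
                "gpc_sites": int(rng.uniform(6e6, 2e7)),
            }
        )
    qc = pd.DataFrame(rows).set_index("cell_id")
    qc.loc["cell_15", "mapped_reads"] = 200_000     # below 300k ES floor
    qc.loc["cell_16", "mito_frac"] = 0.16           # above 15% ceiling
    qc.loc["cell_17", "n_genes"] = 1500
    qc.loc["cell_18", "mapping_efficiency"] = 0.08
    qc.loc["cell_19", "cpg_sites"] = 400_000
    qc.loc["cell_20", "gpc_sites"] = 4_000_000
    return qc


@pytest.fixture()
def empty_sites():
    return sites_frame()
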