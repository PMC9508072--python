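import numpy as np
import pandas as pd
import pytest

from pairmeta.io import SummaryStats
from pairmeta.simulate import LDStructure, build_ld_structure


@pytest.fixture
def toy_sumstats_file(tmp_path):
    """Three clean rows in the default dialect."""
    path = tmp_path / "toy.tsv"
    pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"],
            "CHR": ["1", "1", "2"],
            "BP": [100, 200, 300],
            "A1": ["A", "C", "G"],
            "A2": ["G", "T", "A"],
            "Z": [1.0, -2.0, 0.5],
            "N": [1000, 1000, 1000],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def small_ld() -> LDStructure:
    return build_ld_structure(n_blocks=10, block_size=20, rho=(0.0, 0.9), seed=7)


def sumstats_from_positions(chrom, pos, z=None):
    """Minimal in-memory SummaryStats for mapping tests."""
    m = len(pos)
    z = np.zeros(m) if z is None else np.asarray(z, float)
    from scipy import stats as st

    return SummaryStats(
        table=pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(m)],
                "chrom": list(chrom),
                "pos": list(pos),
                "a1": "A",
                "a2": "G",
                "z": z,
                "p": 2 * st.norm.sf(np.abs(z)),
                "n": 1000.0,
                "maf": 0.3,
            }
        )
    )
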