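import numpy as np
import pandas as pd
import pytest

from callusmap import simdata
from callusmap.core import BinMarkerMatrix, GeneticMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_chrom_map():
    return GeneticMap.uniform([100.0, 80.0])


@pytest.fixture(scope="session")
def small_truth():
    """Small error-free F2 with one strong QTL, shared across tests."""
    gmap = GeneticMap.uniform([100.0, 80.0])
    cfg = simdata.SimConfig(
        genetic_map=gmap,
        qtls=(simdata.QtlSpec("chr1", 50.0, 1.5),),
        n_embryos=300,
        n_select_per_class=40,
        snp_density=2.0,
        missing_rate=0.0,
        genotype_error_rate=0.0,
        het_undercall_rate=0.0,
        seed=99,
    )
    return simdata.simulate_f2(cfg)


def make_bins(calls: np.ndarray, pos_cm: np.ndarray, chrom: str = "chr1",
              bp_per_cm: float = 1e6) -> BinMarkerMatrix:
    """Hand-build a BinMarkerMatrix from a (markers x individuals) array."""
    calls = np.asarray(calls, dtype=np.int8)
    pos_cm = np.asarray(pos_cm, dtype=float)
    bp = (pos_cm * bp_per_cm).astype(np.int64)
    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start_bp": bp - 1000,
            "end_bp": bp + 1000,
            "rep_pos_bp": bp,
            "rep_pos_cm": pos_cm,
        }
    )
    inds = [f"ind{j:03d}" for j in range(calls.shape[1])]
    return BinMarkerMatrix(bins, inds, calls)
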