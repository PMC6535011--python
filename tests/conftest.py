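import numpy as np
import pytest

from adaptscape.popgen import GenotypeMatrix
from adaptscape.rasters import Raster, RasterStack
from adaptscape.synthio import LandscapeConfig, generate_climate_rasters


@pytest.fixture()
def toy_genepop(tmp_path):
    """Two populations x two individuals x two loci, 2-digit codes."""
    text = (
        "toy dataset\n"
        "locusA\n"
        "locusB\n"
        "Pop\n"
        "ind1 , 0101 0102\n"
        "ind2 , 0102 0202\n"
        "Pop\n"
        "ind3 , 0202 0101\n"
        "ind4 , 0101 0000\n"
    )
    path = tmp_path / "toy.gen"
    path.write_text(text)
    return path


@pytest.fixture()
def small_gm():
    """5 loci with known allele frequencies over 4 individuals."""
    values = np.array(
        [
            [0, 2, 1, 0, 0],
            [1, 2, 1, 0, -1],
            [0, 2, 0, 1, 0],
            [0, 2, 2, 1, 0],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(
        values,
        sample_ids=[f"i{k}" for k in range(4)],
        locus_ids=[f"L{k}" for k in range(5)],
        populations=["a", "a", "b", "b"],
    )


@pytest.fixture()
def gradient_stack():
    """Deterministic 16x16 east-west gradient pair (no noise)."""
    config = LandscapeConfig(
        grid_rows=16, grid_cols=16, noise_sd=0.0, autocorrelation_range=2.0, seed=0
    )
    return generate_climate_rasters(config, n_layers=2)


@pytest.fixture()
def checker_raster():
    """Small raster with one nodata hole for masking tests."""
    values = np.arange(36, dtype=float).reshape(6, 6)
    values[2, 3] = -9999.0
    return Raster(values, nodata=-9999.0)


def binary_raster(n_ones: int, total: int = 10_000, side: int = 100) -> Raster:
    """A 0/1 raster with exactly n_ones suitable cells out of total."""
    assert side * side == total
    flat = np.zeros(total)
    flat[:n_ones] = 1.0
    return Raster(flat.reshape(side, side), nodata=-9999.0)


@pytest.fixture()
def make_binary_raster():
    return binary_raster
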