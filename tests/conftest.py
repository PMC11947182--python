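import numpy as np
import pandas as pd
import pytest

from msiregion import (
    AnnotationLibrary,
    LibraryEntry,
    MSISample,
    PixelSpectrum,
    FeatureMatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def tiny_sample():
    """A 2x2-pixel processed-mode sample with per-pixel m/z axes."""
    pixels = [
        PixelSpectrum(1, 1, 1, [300.0, 500.0], [10.0, 20.0]),
        PixelSpectrum(2, 1, 2, [310.0, 520.0, 700.0], [5.0, 0.0, 3.0]),
        PixelSpectrum(1, 2, 3, [400.0], [7.0]),
        PixelSpectrum(2, 2, 4, [450.0, 460.0], [1.0, 2.0]),
    ]
    return MSISample("tiny", "negative", pixels)


@pytest.fixture
def toy_library():
    entries = [
        LibraryEntry("PC 32:0", "PC", 32, 0, 734.569, "positive"),
        LibraryEntry("PE 36:2", "PE", 36, 2, 734.586, "positive"),
        LibraryEntry("PI 36:4", "PI", 36, 4, 857.518, "positive"),
        LibraryEntry("PS 40:6", "PS", 40, 6, 834.529, "positive"),
        LibraryEntry("SM 44:1", "SM", 44, 1, 841.600, "positive"),
        LibraryEntry("PI 36:4", "PI", 36, 4, 857.518, "negative"),
        LibraryEntry("FA 22:6", "FA", 22, 6, 327.233, "negative"),
        LibraryEntry("PE 18:0/22:6", "PE", 40, 6, 790.539, "negative"),
    ]
    return AnnotationLibrary(entries)


def make_matrix(values, sample_id="s1", feature_mz=None, group="", sex="", mode="negative"):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    if feature_mz is None:
        feature_mz = np.linspace(400, 800, f)
    pixel_table = pd.DataFrame(
        {
            "x": np.arange(1, n + 1),
            "y": np.ones(n, dtype=int),
            "acquisition_index": np.arange(1, n + 1),
        }
    )
    return FeatureMatrix(
        sample_id=sample_id,
        values=values,
        feature_mz=np.asarray(feature_mz, dtype=float),
        pixel_table=pixel_table,
        ionization_mode=mode,
        group=group,
        sex=sex,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
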