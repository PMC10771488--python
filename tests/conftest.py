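import numpy as np
import pytest

from fossilfluor import ElementarySpectrum, EndmemberMatrix, SpectralAxis


@pytest.fixture
def axis5():
    """Tiny 5-channel axis, 1 nm spacing, centers 500-504 nm."""
    return SpectralAxis(centers=np.arange(500.0, 505.0), bandwidth_nm=1.0)


@pytest.fixture
def axis2():
    return SpectralAxis(centers=np.array([500.0, 501.0]), bandwidth_nm=1.0)


def endmember_matrix(axis, columns, names=None):
    """Build an EndmemberMatrix from raw column vectors (max-normalized)."""
    names = names or [f"e{i}" for i in range(len(columns))]
    return EndmemberMatrix(
        [
            ElementarySpectrum(n, np.asarray(c, dtype=float), axis, normalize=True)
            for n, c in zip(names, columns)
        ]
    )


def random_endmembers(rng, m, l, axis_cls=SpectralAxis):
    """Random full-rank nonnegative endmember matrix on an m-channel axis."""
    l = min(l, m)  # more endmembers than channels is never identifiable
    axis = axis_cls(centers=np.arange(500.0, 500.0 + m), bandwidth_nm=1.0)
    while True:
        cols = rng.random((l, m)) + 0.05
        try:
            return endmember_matrix(axis, cols), axis
        except Exception:
            continue
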