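import numpy as np
import pytest

from glspca import GLSPCAParams, fit_glspca, knn_affinity, laplacian, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 50-gene x 30-sample blobs dataset used across solver tests."""
    return make_dataset(n_samples=30, m_genes=50, n_clusters=3,
                        n_informative=10, seed=7)


@pytest.fixture(scope="session")
def small_laplacian(small_dataset):
    return laplacian(knn_affinity(small_dataset.X, k_neighbors=5))


@pytest.fixture(scope="session")
def default_fit(small_dataset, small_laplacian):
    """One converged fit at the default beta=0.5, gamma=1 setting."""
    return fit_glspca(small_dataset.X, small_laplacian,
                      GLSPCAParams(k_dims=2, beta=0.5, gamma=1.0))


def write_matrix_file(path, body, header="\tsA\tsB", sep="\t"):
    """Write a tiny labeled matrix file from a list of row strings."""
    lines = [header] + body
    path.write_text("\n".join(line.replace("\t", sep) for line in lines) + "\n")
    return path
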