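"""Seeded synthetic expression matrices with planted structure.

Two generative modes emulate the situations the solver is built for:

``blobs``
    Samples fall into well-defined clusters.  A small planted set of
    informative genes carries cluster-specific mean offsets of magnitude
    ``signal`` (random sign per gene and cluster); every other gene is
    pure Gaussian noise.  This is the classic mean-shift setting in which
    PCA-type methods are analyzable, and gives ground truth both for
    sample clustering (the cluster ids) and for gene ranking (the
    planted informative set).

``curve``
    Samples lie on interleaved 1-D arcs in a 2-D latent space (a
    multi-arc "moons" geometry), lifted into the informative genes by a
    random orthonormal loading and corrupted by noise.  Globally,
    Euclidean distances mix the arcs, so plain PCA + K-means struggles,
    while a kNN graph follows each arc — the setting in which the
    Laplacian term earns its keep.

Identical parameters and seed give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .exprio import ExpressionMatrix

__all__ = ["GeneratorParams", "SyntheticDataset", "make_dataset"]

Manifold = Literal["blobs", "curve"]


@dataclass(frozen=True)
class GeneratorParams:
    """Generator configuration.

    Defaults describe a small but non-trivial recovery problem: 60
    samples in 3 balanced clusters, 200 genes of which 20 are
    informative, mean-shift signal 4 against unit noise — comfortably
    detectable but far from degenerate, mimicking the genes >> samples
    shape of tumor expression panels at desk scale.
    """

    n_samples: int = 60
    m_genes: int = 200
    n_clusters: int = 3
    n_informative: int = 20
    signal: float = 4.0
    noise_sd: float = 1.0
    manifold: Manifold = "blobs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.m_genes < 2:
            raise ValueError("need at least 2 samples and 2 genes")
        if not 1 <= self.n_informative <= self.m_genes:
            raise ValueError(
                f"n_informative must be in [1, {self.m_genes}], got {self.n_informative}"
            )
        if not 1 <= self.n_clusters <= self.n_samples:
            raise ValueError(
                f"n_clusters must be in [1, {self.n_samples}], got {self.n_clusters}"
            )
        if self.signal < 0 or self.noise_sd < 0:
            raise ValueError("signal and noise_sd must be >= 0")
        if self.manifold not in ("blobs", "curve"):
            raise ValueError(f"unknown manifold {self.manifold!r}")
        if self.manifold == "curve" and self.n_informative < 2:
            raise ValueError("curve mode needs >= 2 informative genes")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated matrix plus its ground truth."""

    X: ExpressionMatrix
    truth_labels: np.ndarray
    informative_idx: np.ndarray
    params: GeneratorParams

    @property
    def informative_gene_ids(self) -> tuple[str, ...]:
        return tuple(self.X.gene_ids[i] for i in self.informative_idx)


def _arc_latent(theta: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Interleaved half-circle arcs in 2-D, one arc per cluster.

    Arc 0 is the upper unit half-circle; each subsequent arc alternates
    orientation and shifts right so consecutive arcs interlock (the
    two-arc case is the standard "two moons" geometry).
    """
    z = np.empty((theta.shape[0], 2))
    for lbl in np.unique(labels):
        sel = labels == lbl
        shift = float(lbl)
        if lbl % 2 == 0:
            z[sel, 0] = np.cos(theta[sel]) + shift
            z[sel, 1] = np.sin(theta[sel])
        else:
            z[sel, 0] = 1.0 - np.cos(theta[sel]) + (shift - 1.0)
            z[sel, 1] = 0.5 - np.sin(theta[sel])
    return z


def make_dataset(params: GeneratorParams | None = None, **overrides) -> SyntheticDataset:
    """Generate a seeded dataset; keyword overrides patch the defaults."""
    if params is None:
        params = GeneratorParams(**overrides)
    elif overrides:
        params = GeneratorParams(**{**asdict(params), **overrides})
    rng = np.random.default_rng(params.seed)
    m, n, c = params.m_genes, params.n_samples, params.n_clusters

    labels = np.arange(n) % c  # balanced, deterministic assignment
    informative = np.sort(rng.choice(m, size=params.n_informative, replace=False))

    X = rng.normal(0.0, params.noise_sd, size=(m, n))
    if params.manifold == "blobs":
        # cluster-specific +/- signal offsets on informative genes only
        offsets = params.signal * rng.choice(
            [-1.0, 1.0], size=(params.n_informative, c)
        )
        X[np.ix_(informative, np.arange(n))] += offsets[:, labels]
    else:
        theta = rng.uniform(0.0, np.pi, size=n)
        latent = _arc_latent(theta, labels)  # n x 2
        loading = np.linalg.qr(rng.normal(size=(params.n_informative, 2)))[0]
        X[informative, :] += params.signal * (loading @ latent.T)

    gene_ids = tuple(f"g{i:04d}" for i in range(m))
    sample_ids = tuple(f"s{j:03d}" for j in range(n))
    return SyntheticDataset(
        X=ExpressionMatrix(X, gene_ids, sample_ids),
        truth_labels=labels,
        informative_idx=informative,
        params=params,
    )
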