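"""Population structure from the final genotype matrix.

Genotypes are coded as alternate-allele dosage (0/1/2, missing masked).
PCA follows the standard genotype-PCA recipe: per-site mean centring with
mean imputation of missing values, scaling by sqrt(p(1-p)) where p is the
alternate allele frequency, then eigendecomposition of the sample-by-sample
covariance. Distances are identity-by-state dissimilarities (mean dosage
difference over co-called sites, halved to [0, 1]) and the dendrogram is
average-linkage (UPGMA) agglomeration of that matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .vcfio import FinalVcf


@dataclass
class GenotypeMatrix:
    samples: list[str]
    codes: np.ndarray  # samples x sites int8 dosage; -1 missing

    @property
    def missing(self) -> np.ndarray:
        return self.codes < 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape


def genotype_numeric(final: FinalVcf) -> GenotypeMatrix:
    """0/1/2 dosage coding of the final VCF with missing preserved."""
    return GenotypeMatrix(samples=list(final.samples), codes=final.codes.copy())


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # non-increasing
    coordinates: np.ndarray  # samples x components


def pca(matrix: GenotypeMatrix) -> PcaResult:
    """Genotype PCA; raises on a degenerate (all-monomorphic) matrix."""
    codes = matrix.codes.astype(float)
    codes[matrix.missing] = np.nan
    with np.errstate(invalid="ignore"):
        means = np.nanmean(codes, axis=0)
        var = np.nanvar(codes, axis=0)
    usable = ~np.isnan(means) & (var > 0)
    if not usable.any():
        raise ValueError("all sites monomorphic or missing: PCA undefined")
    p = means / 2.0
    scale = np.sqrt(p * (1.0 - p))
    x = codes[:, usable]
    filled = np.where(np.isnan(x), means[usable], x)
    z = (filled - means[usable]) / scale[usable]
    cov = z @ z.T / z.shape[1]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvals[eigvals < 1e-9 * max(eigvals[0], 1e-30)] = 0.0  # numerical null space
    # project onto components: zero-variance directions carry no spread
    coords = eigvecs[:, order] * np.sqrt(eigvals)
    # sign convention: largest-magnitude loading positive, for determinism
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return PcaResult(eigenvalues=eigvals, coordinates=coords)


def ibs_dissimilarity(matrix: GenotypeMatrix) -> np.ndarray:
    """d(i, j) = mean over co-called sites of |dosage_i - dosage_j| / 2."""
    n = len(matrix.samples)
    if n < 2:
        raise ValueError("need at least two samples")
    codes = matrix.codes.astype(np.int16)
    called = codes >= 0
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                out[i, j] = out[j, i] = np.nan
                continue
            d = np.abs(codes[i, both] - codes[j, both]).mean() / 2.0
            out[i, j] = out[j, i] = d
    return out


def upgma_linkage(dissimilarity: np.ndarray) -> np.ndarray:
    if dissimilarity.ndim != 2 or dissimilarity.shape[0] != dissimilarity.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(dissimilarity, dissimilarity.T, equal_nan=True):
        raise ValueError("dissimilarity must be symmetric")
    if np.isnan(dissimilarity).any():
        raise ValueError("dissimilarity has missing entries; cannot cluster")
    n = dissimilarity.shape[0]
    condensed = dissimilarity[np.triu_indices(n, k=1)]
    return hierarchy.linkage(condensed, method="average")


def upgma_newick(dissimilarity: np.ndarray, labels: list[str]) -> str:
    """Average-linkage dendrogram as a Newick string with branch lengths.

    Node heights are the UPGMA merge heights; a leaf's branch length is
    half the first merge height it participates in (ultrametric tree)."""
    link = upgma_linkage(dissimilarity)
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        height = node.dist / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = render(node.left, height)
        right = render(node.right, height)
        return f"({left},{right}):{parent_height - height:.6g}"

    root_height = tree.dist / 2.0
    left = render(tree.left, root_height)
    right = render(tree.right, root_height)
    return f"({left},{right});"


def last_joined_leaf_set(dissimilarity: np.ndarray, labels: list[str]) -> set[str]:
    """Labels on the smaller side of the root split (the outgroup side
    when one sample attaches last)."""
    link = upgma_linkage(dissimilarity)
    tree = hierarchy.to_tree(link)
    left = set(tree.left.pre_order(lambda n: labels[n.id]))
    right = set(tree.right.pre_order(lambda n: labels[n.id]))
    return left if len(left) <= len(right) else right
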