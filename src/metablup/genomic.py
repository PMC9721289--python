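"""Genomic relationship matrices and the ssGTBLUP Woodbury factorization.

The metafounder theory requires the genomic relationship matrix to be
built with all allele frequencies fixed at 0.5: genotypes are coded
-1/0/+1 (``Z101``) and G05 = Z101 Z101' / k with k = m/2.  Residual
polygenic blending Gc = (1-w) G05 + w A22 guarantees invertibility, and
the Woodbury identity expresses the inverse through the m x m inner
system::

    Gc = w A22 + (1-w)/k Z Z'
    Gc^-1 = (1/w) A22^-1 - T' T,
    T = w^{-1/2} L^{-1} Z' A22^-1,   L L' = (k w / (1-w)) I + Z' A22^-1 Z

so that only A22^-1 (sparse at production scale) and the m x n matrix T
are needed -- the regime that motivates ssGTBLUP is n >> m.  The inverse
identity Gc * ((1/w) A22^-1 - T'T) = I is the binding contract and is what
the tests enforce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .pedigree import RelationshipMatrix

__all__ = [
    "GenotypePanel",
    "BlendedGenomicMatrix",
    "build_G05",
    "blend",
    "woodbury_factorize",
    "apply_Gc_inverse",
]

DEFAULT_RPG_PROPORTION = 0.30  # residual polygenic proportion w


class GenotypePanel:
    """Dosage matrix (animals x markers, 0/1/2) with -1/0/+1 coding derived.

    Input is post-imputation by contract: missing dosages are an error.
    """

    def __init__(self, dosages, animal_ids, marker_ids):
        D = np.asarray(dosages)
        if D.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        if np.isnan(D.astype(float)).any():
            raise ValueError("missing dosages not allowed (input is post-imputation)")
        if not np.isin(D, [0, 1, 2]).all():
            bad = np.argwhere(~np.isin(D, [0, 1, 2]))[0]
            raise ValueError(f"invalid dosage at row {bad[0]}, marker {bad[1]}")
        self.dosages = D.astype(np.int8)
        self.animal_ids = np.asarray(animal_ids)
        self.marker_ids = np.asarray(marker_ids)
        if len(self.animal_ids) != D.shape[0] or len(self.marker_ids) != D.shape[1]:
            raise ValueError("id lengths do not match dosage matrix shape")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def k(self) -> float:
        """Scaling factor k = m/2 of the 0.5-allele-frequency G."""
        return self.m / 2.0

    @property
    def Z101(self) -> np.ndarray:
        """Centered coding: -1 / 0 / +1 for the two homozygotes / heterozygote."""
        return self.dosages.astype(np.float64) - 1.0

    def subset_animals(self, ids) -> "GenotypePanel":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [index[a] for a in ids]
        return GenotypePanel(self.dosages[rows], np.asarray(list(ids)), self.marker_ids)

    def subset_markers(self, marker_ids) -> "GenotypePanel":
        index = {m: j for j, m in enumerate(self.marker_ids)}
        cols = [index[m] for m in marker_ids]
        return GenotypePanel(self.dosages[:, cols], self.animal_ids, np.asarray(list(marker_ids)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.animal_ids, columns=self.marker_ids)


@dataclass
class BlendedGenomicMatrix:
    """Gc = (1-w) G05 + w base, with optional Woodbury factor pair."""

    w: float
    G05: np.ndarray
    base: RelationshipMatrix
    Gc: np.ndarray
    panel: GenotypePanel | None = None
    T: np.ndarray | None = None      # m x n
    L: np.ndarray | None = None      # lower Cholesky of the inner matrix
    base_inv: object | None = None


def build_G05(panel: GenotypePanel) -> np.ndarray:
    """G05 = Z101 Z101' / k with all allele frequencies assumed 0.5."""
    if panel.m == 0:
        raise ValueError("panel has no markers")
    Z = panel.Z101
    return (Z @ Z.T) / panel.k


def blend(
    G05: np.ndarray,
    base: RelationshipMatrix,
    w: float = DEFAULT_RPG_PROPORTION,
    panel: GenotypePanel | None = None,
) -> BlendedGenomicMatrix:
    """Residual polygenic blending Gc = (1-w) G05 + w base.

    ``base`` is A22 (UPG models) or A22^Gamma (metafounder models).  The
    default w = 0.30.
    """
    if not (0 < w <= 1):
        raise ValueError("w must be in (0, 1]")
    B = base.dense()
    if B.shape != np.asarray(G05).shape:
        raise ValueError("G05 and base are not conformable")
    Gc = (1.0 - w) * np.asarray(G05) + w * B
    return BlendedGenomicMatrix(w=w, G05=np.asarray(G05), base=base, Gc=Gc, panel=panel)


def woodbury_factorize(blended: BlendedGenomicMatrix, base_inverse) -> BlendedGenomicMatrix:
    """Factorize Gc^-1 = (1/w) base^-1 - T'T via the Woodbury identity.

    ``base_inverse`` is the dense or sparse inverse of the blending base.
    Returns the input with the (L, T) pair attached.  Requires w < 1
    (at w = 1 the genomic term vanishes and T = 0).
    """
    if blended.panel is None:
        raise ValueError("blended matrix must carry its genotype panel")
    w = blended.w
    panel = blended.panel
    Z = panel.Z101
    n, m = Z.shape
    Binv = base_inverse.values if isinstance(base_inverse, RelationshipMatrix) else base_inverse
    if sp.issparse(Binv):
        W = Binv @ Z
    else:
        W = np.asarray(Binv) @ Z
    if w >= 1.0:
        blended.T = np.zeros((m, n))
        blended.L = np.eye(m)
        blended.base_inv = Binv
        return blended
    inner = (panel.k * w / (1.0 - w)) * np.eye(m) + Z.T @ W
    try:
        L = np.linalg.cholesky(inner)
    except np.linalg.LinAlgError as e:
        raise ValueError("Woodbury inner matrix not positive definite") from e
    T = sla.solve_triangular(L, W.T, lower=True) / np.sqrt(w)
    blended.T = T
    blended.L = L
    blended.base_inv = Binv
    return blended


def apply_Gc_inverse(blended: BlendedGenomicMatrix, v: np.ndarray) -> np.ndarray:
    """Matrix-free product Gc^-1 v = (1/w) base^-1 v - T'(T v)."""
    if blended.T is None or blended.base_inv is None:
        raise ValueError("call woodbury_factorize first")
    v = np.asarray(v, dtype=float)
    if v.shape[0] != blended.T.shape[1]:
        raise ValueError(
            f"dimension mismatch: vector {v.shape[0]}, matrix {blended.T.shape[1]}"
        )
    Binv = blended.base_inv
    out = (Binv @ v) / blended.w
    out -= blended.T.T @ (blended.T @ v)
    return np.asarray(out)
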