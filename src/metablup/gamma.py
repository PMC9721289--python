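"""Metafounder relationship matrix Gamma: estimation, extrapolation, bending.

The self- and cross-relationships of metafounders form a covariance
matrix Gamma that can be estimated as 8 Cov(P), where P holds GLS
estimates of base-population allele frequencies (markers x groups).
Groups without genotype linkage cannot enter the GLS, so Gamma for the
full group set is obtained by fitting a covariance function
Gamma_pre = Phi K Phi' + E over group descriptors (standardized year and
breed class) and extrapolating Gamma_all = Phi_all K Phi_all'.  The
extrapolated matrix has rank at most q (the number of Phi columns) and is
bent -- off-diagonals shrunk, diagonals inflated by the same small
fraction -- before any inverse is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .genomic import GenotypePanel
from .pedigree import GroupContributionMatrix, GroupTable, RelationshipMatrix

__all__ = [
    "AlleleFreqPanel",
    "GammaMatrix",
    "CovFunctionModel",
    "estimate_base_af_gls",
    "gamma_from_af",
    "merge_af_panels",
    "assemble_gamma_pre",
    "build_phi",
    "fit_cov_function",
    "extrapolate_gamma",
    "bend_gamma",
    "gamma_block_stats",
    "matrix_compare",
    "variance_scaling_factor",
]

YEAR_MIN_DEFAULT = 1950
YEAR_MAX_DEFAULT = 2021
BEND_DELTA_DEFAULT = 0.025


@dataclass
class AlleleFreqPanel:
    """Estimated base-population allele frequencies, markers x groups.

    GLS estimates are deliberately not clipped to [0, 1]: clipping would
    bias the covariance used for Gamma.  ``n_out_of_range`` counts the
    offending entries for logging.
    """

    P: np.ndarray
    marker_ids: np.ndarray
    group_ids: list
    source: str = "gls"

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.marker_ids = np.asarray(self.marker_ids)
        if self.P.shape != (len(self.marker_ids), len(self.group_ids)):
            raise ValueError("P shape does not match marker/group ids")
        if not np.isfinite(self.P).all():
            raise ValueError("non-finite allele-frequency estimates")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker ids not unique")

    @property
    def m(self) -> int:
        return self.P.shape[0]

    @property
    def r(self) -> int:
        return self.P.shape[1]

    @property
    def n_out_of_range(self) -> int:
        return int(((self.P < 0) | (self.P > 1)).sum())


@dataclass
class GammaMatrix:
    """Symmetric r x r metafounder covariance matrix with provenance."""

    values: np.ndarray
    group_ids: list
    provenance: str = "estimated"  # estimated | assembled | extrapolated | bent
    rank_model: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        G = self.values
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("Gamma must be square")
        if G.shape[0] != len(self.group_ids):
            raise ValueError("group_ids length does not match Gamma size")
        if not np.allclose(G, G.T, atol=1e-12 * max(1.0, np.abs(G).max())):
            raise ValueError("Gamma must be symmetric")
        self.values = 0.5 * (G + G.T)

    @property
    def r(self) -> int:
        return self.values.shape[0]

    def numerical_rank(self, rtol: float = 1e-10) -> int:
        s = np.linalg.svd(self.values, compute_uv=False)
        if s[0] == 0:
            return 0
        return int((s > rtol * s[0]).sum())


@dataclass
class CovFunctionModel:
    """Fitted covariance function Gamma ~ Phi K Phi'.

    ``column_spec`` records which Phi columns are year terms and which are
    breed-class indicators so extrapolation can rebuild Phi consistently.
    """

    Phi: np.ndarray
    K: np.ndarray
    residual_fro: float
    column_spec: dict = field(default_factory=dict)
    year_min: int = YEAR_MIN_DEFAULT
    year_max: int = YEAR_MAX_DEFAULT

    @property
    def q(self) -> int:
        return self.Phi.shape[1]


# ---------------------------------------------------------------------------
# estimation

def estimate_base_af_gls(
    panel: GenotypePanel,
    A22_inv,
    Q2: GroupContributionMatrix,
) -> AlleleFreqPanel:
    """GLS base allele frequencies per marker and group.

    For marker j with dosage vector m_j over the genotyped animals,
    p_hat_j = 0.5 (Q2' A22^-1 Q2)^-1 Q2' A22^-1 m_j.  ``A22_inv`` and
    ``Q2`` (genotyped rows of Q) come from the truncated pedigree, which
    spreads the genomic information evenly over the groups.
    """
    Ainv = A22_inv.values if isinstance(A22_inv, RelationshipMatrix) else A22_inv
    Q = Q2.Q
    order = Q2.animal_ids
    gp = panel.subset_animals(order) if not np.array_equal(order, panel.animal_ids) else panel
    M = gp.dosages.astype(np.float64)  # n x m
    W = Ainv @ Q                       # n x r
    S = Q.T @ W                        # r x r
    eig = np.linalg.eigvalsh(S)
    if not np.isfinite(S).all() or eig[0] <= 1e-10 * max(eig[-1], 1.0):
        raise _gls_singular_error(Q, Q2.group_ids)
    c, low = sla.cho_factor(S)
    rhs = W.T @ M                      # r x m
    P = 0.5 * sla.cho_solve((c, low), rhs)  # r x m
    return AlleleFreqPanel(P.T, gp.marker_ids, list(Q2.group_ids), source="gls")


def _gls_singular_error(Q, group_ids):
    support = Q.sum(axis=0)
    weak = [g for g, s in zip(group_ids, support) if s < 1e-8]
    return ValueError(
        "GLS system singular: groups without genotype linkage: "
        + (", ".join(map(str, weak)) if weak else "(collinear group contributions)")
    )


def gamma_from_af(panel: AlleleFreqPanel, provenance: str = "estimated") -> GammaMatrix:
    """Gamma = 8 x covariance of base AF across markers (divisor m)."""
    if panel.m < 2:
        raise ValueError("need at least 2 markers to estimate a covariance")
    P = panel.P
    C = np.cov(P.T, bias=True)
    C = np.atleast_2d(C)
    return GammaMatrix(8.0 * C, list(panel.group_ids), provenance=provenance)


def merge_af_panels(a: AlleleFreqPanel, b: AlleleFreqPanel):
    """Join two AF panels on their common markers; columns = union of groups.

    Returns (joint_panel, dropped_counts) where dropped_counts is the
    number of markers discarded from each input.
    """
    common = [m for m in a.marker_ids if m in set(b.marker_ids)]
    if not common:
        raise ValueError("no overlapping markers between panels")
    overlap_groups = set(a.group_ids) & set(b.group_ids)
    if overlap_groups:
        raise ValueError(f"panels share groups {sorted(overlap_groups)}")
    ia = {m: i for i, m in enumerate(a.marker_ids)}
    ib = {m: i for i, m in enumerate(b.marker_ids)}
    ra = [ia[m] for m in common]
    rb = [ib[m] for m in common]
    P = np.hstack([a.P[ra], b.P[rb]])
    dropped = (a.m - len(common), b.m - len(common))
    joint = AlleleFreqPanel(
        P, np.asarray(common), list(a.group_ids) + list(b.group_ids), source="merged"
    )
    return joint, dropped


def assemble_gamma_pre(
    joint: AlleleFreqPanel, per_panel: list[AlleleFreqPanel]
) -> GammaMatrix:
    """Gamma_pre: 8 Cov of the joint panel with per-source diagonals.

    Off-diagonals come from the marker-intersection joint panel; each
    diagonal is overwritten with the variance computed from the source
    panel on its full marker set (merging drops markers, which deflates
    the per-group variance).
    """
    gamma = gamma_from_af(joint, provenance="assembled")
    G = gamma.values.copy()
    pos = {g: i for i, g in enumerate(joint.group_ids)}
    covered = set()
    for panel in per_panel:
        sub = gamma_from_af(panel)
        for g, d in zip(panel.group_ids, np.diag(sub.values)):
            if g in pos:
                G[pos[g], pos[g]] = d
                covered.add(g)
    missing = set(joint.group_ids) - covered
    if missing:
        raise ValueError(f"groups present in joint panel but in no source panel: {sorted(missing)}")
    return GammaMatrix(G, list(joint.group_ids), provenance="assembled")


# ---------------------------------------------------------------------------
# covariance function

def standardize_year(year, year_min=YEAR_MIN_DEFAULT, year_max=YEAR_MAX_DEFAULT):
    """Map a year to [-1, 1]: t = 2 (year - year_min)/(year_max - year_min) - 1."""
    return 2.0 * (np.asarray(year, dtype=float) - year_min) / (year_max - year_min) - 1.0


def build_phi(
    groups: GroupTable,
    year_min: int = YEAR_MIN_DEFAULT,
    year_max: int = YEAR_MAX_DEFAULT,
    breed_classes: list | None = None,
    year_degree: int = 1,
) -> tuple[np.ndarray, dict]:
    """Model matrix Phi for the covariance function.

    Columns: ``year_degree`` standardized-year polynomial terms followed by
    one 0/1 indicator per breed class.  A group's breed class defaults to
    its breed code; an explicit ``breed_classes`` list fixes the column
    order.  ``year_degree = 0`` drops the year terms (for group sets whose
    representative years are all equal).  Returns (Phi, column_spec).
    """
    df = groups.df
    if "breed_class" in df.columns:
        cls = df["breed_class"].to_numpy()
    else:
        cls = df["breed"].to_numpy()
    if breed_classes is None:
        breed_classes = sorted(set(cls))
    unknown = set(cls) - set(breed_classes)
    if unknown:
        raise ValueError(f"breed classes not in spec: {sorted(unknown)}")
    years = df["representative_year"].to_numpy()
    if (years < year_min).any() or (years > year_max).any():
        bad = df.loc[(years < year_min) | (years > year_max), "group_id"].tolist()
        raise ValueError(f"representative year outside [{year_min}, {year_max}] for groups {bad}")
    cols = []
    if year_degree >= 1:
        if year_max <= year_min:
            raise ValueError("year_max must exceed year_min when year terms are used")
        t = standardize_year(years, year_min, year_max)
        cols = [t ** d for d in range(1, year_degree + 1)]
    for b in breed_classes:
        cols.append((cls == b).astype(float))
    Phi = np.column_stack(cols)
    spec = {
        "year_degree": year_degree,
        "breed_classes": list(breed_classes),
        "year_min": year_min,
        "year_max": year_max,
    }
    return Phi, spec


def fit_cov_function(
    gamma_pre: GammaMatrix, phi: np.ndarray, column_spec: dict | None = None
) -> CovFunctionModel:
    """Two-sided least-squares fit K = (Phi'Phi)^-1 Phi' Gamma Phi (Phi'Phi)^-1.

    Equivalent to the OLS solution of the vectorized regression of Gamma
    entries on column-pair products of Phi.  Residual E = Gamma - Phi K Phi'
    is reported through its Frobenius norm; E = 0 when row rank of Phi
    equals dim(Gamma).
    """
    Phi = np.asarray(phi, dtype=float)
    G = gamma_pre.values
    if Phi.shape[0] != G.shape[0]:
        raise ValueError("Phi rows must match Gamma dimension")
    PtP = Phi.T @ Phi
    rank = np.linalg.matrix_rank(PtP)
    if rank < Phi.shape[1]:
        # name collinear columns via QR pivoting
        _, _, piv = sla.qr(Phi, pivoting=True)
        bad = sorted(piv[rank:].tolist())
        raise ValueError(f"Phi is rank-deficient; collinear columns: {bad}")
    Pinv = np.linalg.inv(PtP)
    K = Pinv @ Phi.T @ G @ Phi @ Pinv
    K = 0.5 * (K + K.T)
    E = G - Phi @ K @ Phi.T
    spec = dict(column_spec or {})
    return CovFunctionModel(
        Phi=Phi,
        K=K,
        residual_fro=float(np.linalg.norm(E, "fro")),
        column_spec=spec,
        year_min=spec.get("year_min", YEAR_MIN_DEFAULT),
        year_max=spec.get("year_max", YEAR_MAX_DEFAULT),
    )


def extrapolate_gamma(
    model: CovFunctionModel, phi_all: np.ndarray, group_ids: list,
    column_spec: dict | None = None,
) -> GammaMatrix:
    """Gamma for an arbitrary group set: Gamma_all = Phi_all K Phi_all'."""
    Phi = np.asarray(phi_all, dtype=float)
    if Phi.shape[1] != model.q:
        raise ValueError(
            f"Phi_all has {Phi.shape[1]} columns, model expects {model.q}"
        )
    if column_spec is not None and model.column_spec:
        for key in ("year_degree", "breed_classes", "year_min", "year_max"):
            if key in model.column_spec and column_spec.get(key) != model.column_spec[key]:
                raise ValueError(f"column spec mismatch on {key!r}")
    G = Phi @ model.K @ Phi.T
    rank = int(np.linalg.matrix_rank(model.K))
    return GammaMatrix(G, list(group_ids), provenance="extrapolated", rank_model=rank)


def bend_gamma(gamma: GammaMatrix, delta: float = BEND_DELTA_DEFAULT) -> GammaMatrix:
    """Bend a (possibly singular) Gamma to positive definiteness.

    Off-diagonals are multiplied by (1 - delta) and diagonals by
    (1 + delta); equivalently bent = (1-delta) Gamma + 2 delta diag(Gamma),
    which is positive definite whenever Gamma is PSD with positive
    diagonal.
    """
    G = gamma.values
    d = np.diag(G)
    if (d <= 0).any():
        raise ValueError("bending requires strictly positive diagonal")
    B = (1.0 - delta) * G + 2.0 * delta * np.diag(d)
    return GammaMatrix(B, list(gamma.group_ids), provenance="bent",
                       rank_model=gamma.rank_model)


# ---------------------------------------------------------------------------
# diagnostics

def gamma_block_stats(gamma: GammaMatrix, group_classes: dict) -> pd.DataFrame:
    """Block deviations: 100 x mean(block k,l) / mean(all off-diagonals).

    ``group_classes`` maps group id -> class label.  Within-class blocks
    exclude the diagonal; a singleton class has no within-class
    off-diagonal and is reported as NaN.
    """
    G = gamma.values
    ids = list(gamma.group_ids)
    cls = np.asarray([group_classes[g] for g in ids])
    labels = sorted(set(cls))
    off_mask = ~np.eye(len(ids), dtype=bool)
    denom = G[off_mask].mean()
    out = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        ia = np.flatnonzero(cls == a)
        for b in labels:
            ib = np.flatnonzero(cls == b)
            block = G[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    out.loc[a, b] = np.nan
                    continue
                mask = ~np.eye(len(ia), dtype=bool)
                val = block[mask].mean()
            else:
                val = block.mean()
            out.loc[a, b] = 100.0 * val / denom
    return out


def matrix_compare(a: RelationshipMatrix, b: RelationshipMatrix) -> dict:
    """Summary comparison of two relationship matrices on the same ids.

    Mean/min/max of diagonal and off-diagonal elements of each, plus the
    correlation between paired diagonals and paired off-diagonals.
    """
    if a.n != b.n or not np.array_equal(np.asarray(a.ids), np.asarray(b.ids)):
        raise ValueError("matrices are indexed by different id sets")
    A, B = a.dense(), b.dense()
    eye = np.eye(A.shape[0], dtype=bool)
    iu = np.triu_indices_from(A, k=1)
    out = {}
    for name, M in (("a", A), ("b", B)):
        d, o = np.diag(M), M[iu]
        out[name] = {
            "diag_mean": d.mean(), "diag_min": d.min(), "diag_max": d.max(),
            "offdiag_mean": o.mean(), "offdiag_min": o.min(), "offdiag_max": o.max(),
        }
    out["diag_correlation"] = float(np.corrcoef(np.diag(A), np.diag(B))[0, 1])
    out["offdiag_correlation"] = float(np.corrcoef(A[iu], B[iu])[0, 1])
    return out


def variance_scaling_factor(gamma: GammaMatrix) -> float:
    """Additive-variance scaling 1 + tr(Gamma)/(2n) - 1'Gamma 1/n^2.

    Diagnostic only: it presumes the population is a homogeneous mixture of
    all base populations, so the default pipeline reports it without
    rescaling the variances.
    """
    G = gamma.values
    n = G.shape[0]
    return float(1.0 + np.trace(G) / (2 * n) - G.sum() / n**2)
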