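"""Mixed-model equations for the four evaluation models, with a PCG solver.

Model types
-----------
``pupg``   pedigree BLUP, unknown-parent groups in the QP-augmented A^-1
``pmf``    pedigree BLUP, metafounders via the augmented (A^Gamma)^-1
``ssupg``  single-step GTBLUP with UPG: QP-augmented A^-1 plus B blocks on
           the (genotyped, UPG) coordinates
``ssmf``   single-step GTBLUP with metafounders: augmented (A^Gamma)^-1
           plus the genomic correction Gc^-1 - (A22^Gamma)^-1

The genomic corrections are applied matrix-free through the Woodbury
factor pair, so the coefficient matrix exists only as an operator; the
system is solved by preconditioned conjugate gradients with the Euclidean
relative-residual convergence criterion ||rhs - C x|| / ||rhs|| < tol.

Multi-trait support follows the usual Kronecker layout (trait-minor
ordering within each level); records with missing traits are handled by
residual-covariance subsetting per missingness pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gamma import GammaMatrix
from .genomic import (
    BlendedGenomicMatrix,
    GenotypePanel,
    apply_Gc_inverse,
    blend,
    build_G05,
    woodbury_factorize,
)
from .pedigree import (
    GroupContributionMatrix,
    GroupTable,
    Pedigree,
    RelationshipMatrix,
    build_A,
    build_A_gamma,
    build_A_gamma_inverse,
    build_A_inverse,
    build_A_upg_inverse,
    compute_Q,
    compute_inbreeding,
)

__all__ = [
    "ModelSpec",
    "MMESystem",
    "SolverOptions",
    "PCGResult",
    "build_H_inverse_mf",
    "build_H_inverse_upg",
    "assemble_mme",
    "solve_pcg",
    "extract_gebv",
    "extract_group_solutions",
    "build_evaluation",
    "MODEL_TYPES",
]

MODEL_TYPES = ("pupg", "pmf", "ssupg", "ssmf")


@dataclass
class ModelSpec:
    """Trait list, fixed-effect layout, variance components, model type.

    ``fixed_factors`` are categorical phenotype columns; ``covariates``
    numeric ones.  ``calving_age_col`` triggers the calving-age-by-breed
    covariates: centered alpha = (age - mean age)/365 and its square and
    cube, each multiplied by the animal's pedigree breed proportions so
    the general breed level stays in the breeding values.
    """

    traits: list
    fixed_factors: list = field(default_factory=list)
    covariates: list = field(default_factory=list)
    model_type: str = "pmf"
    G0: np.ndarray = None
    R0: np.ndarray = None
    w: float = 0.30
    calving_age_col: str | None = None

    def __post_init__(self):
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")
        t = len(self.traits)
        self.G0 = np.eye(t) if self.G0 is None else np.asarray(self.G0, float)
        self.R0 = np.eye(t) if self.R0 is None else np.asarray(self.R0, float)
        for name, M in (("G0", self.G0), ("R0", self.R0)):
            if M.shape != (t, t):
                raise ValueError(f"{name} must be {t} x {t}")
            if not np.allclose(M, M.T) or np.linalg.eigvalsh(M)[0] <= 0:
                raise ValueError(f"{name} must be symmetric positive definite")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def h2(self) -> np.ndarray:
        g, r = np.diag(self.G0), np.diag(self.R0)
        return g / (g + r)


@dataclass
class SolverOptions:
    tolerance: float = 1e-6
    max_iterations: int = 5000
    preconditioner: str = "jacobi"  # jacobi | none

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


# ---------------------------------------------------------------------------
# relationship operators

class RelationshipOperator:
    """Precision operator over random-effect levels (animals [+ groups]).

    ``ids`` labels the levels; group levels carry negated group ids.
    Subclasses implement ``matvec`` on (n_levels x t) blocks and ``diag``.
    """

    ids: np.ndarray

    def matvec(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def diag(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def n(self) -> int:
        return len(self.ids)


class SparsePrecisionOperator(RelationshipOperator):
    """Wraps an assembled sparse inverse (A^-1, QP-augmented, or A^Gamma)."""

    def __init__(self, rel: RelationshipMatrix):
        self.M = sp.csr_matrix(rel.values)
        self.ids = np.asarray(rel.ids)

    def matvec(self, X):
        return self.M @ X

    def diag(self):
        return self.M.diagonal()


class _WoodburyCorrection:
    """(1-w)/w base^-1 - T'T applied to genotyped-row blocks."""

    def __init__(self, blended: BlendedGenomicMatrix):
        if blended.T is None:
            raise ValueError("blended matrix has no Woodbury factorization")
        self.w = blended.w
        self.T = blended.T
        Binv = blended.base_inv
        self.Binv = Binv.toarray() if sp.issparse(Binv) else np.asarray(Binv)

    def matvec(self, X):
        out = ((1.0 - self.w) / self.w) * (self.Binv @ X)
        out -= self.T.T @ (self.T @ X)
        return out

    def diag(self):
        return ((1.0 - self.w) / self.w) * np.diag(self.Binv) - (self.T**2).sum(axis=0)


class MetafounderSSOperator(RelationshipOperator):
    """(H^Gamma)^-1: augmented (A^Gamma)^-1 plus Gc^-1 - (A22^Gamma)^-1."""

    def __init__(self, A_gamma_inv: RelationshipMatrix, blended: BlendedGenomicMatrix):
        if blended.base.kind != "A22_gamma":
            raise ValueError("blended matrix must be built on A22^Gamma")
        self.M = sp.csr_matrix(A_gamma_inv.values)
        self.ids = np.asarray(A_gamma_inv.ids)
        self.corr = _WoodburyCorrection(blended)
        index = {a: i for i, a in enumerate(self.ids)}
        self.geno_rows = np.array([index[a] for a in blended.base.ids])

    def matvec(self, X):
        out = self.M @ X
        Xg = np.asarray(X)[self.geno_rows]
        out[self.geno_rows] += self.corr.matvec(Xg)
        return out

    def diag(self):
        d = self.M.diagonal().copy()
        d[self.geno_rows] += self.corr.diag()
        return d


class UPGSSOperator(RelationshipOperator):
    """H^-1 with UPG: QP-augmented A^-1 plus B blocks.

    B11 = (1-w)/w A22^-1 - T'T acts on genotyped rows, B12 = -B11 Q2,
    B22 = Q2' B11 Q2 couple the genotyped animals with the UPG equations.
    """

    def __init__(self, A_upg_inv: RelationshipMatrix, blended: BlendedGenomicMatrix,
                 Q2: GroupContributionMatrix):
        if blended.base.kind not in ("A22",):
            raise ValueError("blended matrix must be built on A22")
        self.M = sp.csr_matrix(A_upg_inv.values)
        self.ids = np.asarray(A_upg_inv.ids)
        self.corr = _WoodburyCorrection(blended)
        self.Q2 = np.asarray(Q2.Q)
        index = {a: i for i, a in enumerate(self.ids)}
        self.geno_rows = np.array([index[a] for a in blended.base.ids])
        self.group_rows = np.array([index[-g] for g in Q2.group_ids])

    def matvec(self, X):
        X = np.asarray(X)
        out = self.M @ X
        Xg = X[self.geno_rows]
        Xu = X[self.group_rows]
        inner = self.corr.matvec(Xg - self.Q2 @ Xu)
        out[self.geno_rows] += inner
        out[self.group_rows] += -self.Q2.T @ inner
        return out

    def diag(self):
        d = self.M.diagonal().copy()
        d[self.geno_rows] += self.corr.diag()
        BQ = self.corr.matvec(self.Q2)          # B11 Q2
        d[self.group_rows] += (self.Q2 * BQ).sum(axis=0)
        return d


def build_H_inverse_mf(A_gamma_inv: RelationshipMatrix,
                       A22_gamma: RelationshipMatrix,
                       blended: BlendedGenomicMatrix) -> MetafounderSSOperator:
    """Operator for (H^Gamma)^-1; ``blended`` must be blended on A22^Gamma."""
    if blended.base is not A22_gamma and blended.base.kind != "A22_gamma":
        raise ValueError("blended base must be A22^Gamma")
    return MetafounderSSOperator(A_gamma_inv, blended)


def build_H_inverse_upg(A_upg_inv: RelationshipMatrix,
                        A22_inv,
                        Q2: GroupContributionMatrix,
                        blended: BlendedGenomicMatrix) -> UPGSSOperator:
    """Operator for the UPG single-step H^-1 (QP-augmented plus B blocks)."""
    return UPGSSOperator(A_upg_inv, blended, Q2)


# ---------------------------------------------------------------------------
# MME assembly

@dataclass
class MMESystem:
    """Assembled mixed-model equations in operator form.

    Unknown ordering: [fixed levels; random levels], trait-minor within a
    level.  ``data_blocks`` hold per-missingness-pattern (W'W sparse,
    embedded R^-1) pairs; the genetic block is operator x G0^-1.
    """

    n_fixed: int
    operator: RelationshipOperator
    G0_inv: np.ndarray
    data_blocks: list          # (sparse S over all levels, t x t Rinv)
    rhs: np.ndarray            # flat, length (n_fixed + n_random) * t
    fixed_labels: list
    n_traits: int

    @property
    def n_levels(self) -> int:
        return self.n_fixed + self.operator.n

    @property
    def n_unknowns(self) -> int:
        return self.n_levels * self.n_traits

    def matvec(self, x: np.ndarray) -> np.ndarray:
        t = self.n_traits
        X = x.reshape(self.n_levels, t)
        out = np.zeros_like(X)
        for S, Rinv in self.data_blocks:
            out += (S @ X) @ Rinv
        Xr = X[self.n_fixed:]
        out[self.n_fixed:] += self.operator.matvec(Xr) @ self.G0_inv
        return out.ravel()

    def diagonal(self) -> np.ndarray:
        t = self.n_traits
        d = np.zeros((self.n_levels, t))
        for S, Rinv in self.data_blocks:
            d += np.outer(S.diagonal(), np.diag(Rinv))
        d[self.n_fixed:] += np.outer(self.operator.diag(), np.diag(self.G0_inv))
        return d.ravel()


def _fixed_design(data: pd.DataFrame, spec: ModelSpec,
                  breed_props: pd.DataFrame | None):
    """Sparse fixed-effect design and column labels.

    The first categorical factor keeps all levels (acts as intercept);
    later factors drop their first level to limit rank deficiency.
    Covariates are used as-is; the calving-age-by-breed block adds
    alpha^d x breed-proportion columns for d = 1..3.
    """
    cols = []
    labels = []
    n = len(data)
    for j, fac in enumerate(spec.fixed_factors):
        levels = sorted(data[fac].astype(str).unique())
        use = levels if j == 0 else levels[1:]
        for lev in use:
            v = (data[fac].astype(str) == lev).to_numpy(dtype=float)
            cols.append(sp.csc_matrix(v.reshape(-1, 1)))
            labels.append(f"{fac}={lev}")
    for cov in spec.covariates:
        cols.append(sp.csc_matrix(data[cov].to_numpy(dtype=float).reshape(-1, 1)))
        labels.append(cov)
    if spec.calving_age_col is not None:
        age = data[spec.calving_age_col].to_numpy(dtype=float)
        alpha = (age - age.mean()) / 365.0
        if breed_props is None:
            raise ValueError("calving-age-by-breed covariates need breed proportions")
        props = breed_props.reindex(data["animal"]).to_numpy()
        for d in (1, 2, 3):
            for bj, breed in enumerate(breed_props.columns):
                v = (alpha ** d) * props[:, bj]
                cols.append(sp.csc_matrix(v.reshape(-1, 1)))
                labels.append(f"alpha^{d}:{breed}")
    if not cols:
        cols.append(sp.csc_matrix(np.ones((n, 1))))
        labels.append("intercept")
    X = sp.hstack(cols, format="csr")
    return X, labels


def _pattern_inverse(R0: np.ndarray, observed: np.ndarray) -> np.ndarray:
    t = R0.shape[0]
    Rinv = np.zeros((t, t))
    idx = np.flatnonzero(observed)
    sub = np.linalg.inv(R0[np.ix_(idx, idx)])
    Rinv[np.ix_(idx, idx)] = sub
    return Rinv


def assemble_mme(spec: ModelSpec, data: pd.DataFrame,
                 operator: RelationshipOperator,
                 breed_props: pd.DataFrame | None = None) -> MMESystem:
    """Assemble Henderson's MME for the given model and data.

    ``data`` holds one row per record: an ``animal`` column, the trait
    columns (NaN = missing), and the fixed-effect columns.  The random
    levels (animals and UPG/MF equations) come from ``operator.ids``.
    """
    for tr in spec.traits:
        if tr not in data.columns:
            raise ValueError(f"trait column {tr!r} missing from data")
    index = {a: i for i, a in enumerate(operator.ids)}
    try:
        arow = np.array([index[a] for a in data["animal"]])
    except KeyError as e:
        raise ValueError(f"phenotype for unknown animal {e.args[0]}") from None

    X, labels = _fixed_design(data, spec, breed_props)
    n_fixed = X.shape[1]
    n_rand = operator.n
    n_rec = len(data)
    Z = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), arow)), shape=(n_rec, n_rand)
    )
    W = sp.hstack([X, Z], format="csr")

    Y = data[list(spec.traits)].to_numpy(dtype=float)
    observed = ~np.isnan(Y)
    if not observed.any(axis=1).all():
        raise ValueError("records with no observed trait are not allowed")
    Y0 = np.where(observed, Y, 0.0)

    patterns = {}
    for i in range(n_rec):
        patterns.setdefault(tuple(observed[i]), []).append(i)

    blocks = []
    t = spec.n_traits
    rhs = np.zeros((n_fixed + n_rand, t))
    for pat, rows in patterns.items():
        Rinv = _pattern_inverse(spec.R0, np.asarray(pat))
        Wp = W[rows]
        S = (Wp.T @ Wp).tocsr()
        blocks.append((S, Rinv))
        rhs += Wp.T @ (Y0[rows] @ Rinv)

    G0_inv = np.linalg.inv(spec.G0)
    return MMESystem(
        n_fixed=n_fixed,
        operator=operator,
        G0_inv=G0_inv,
        data_blocks=blocks,
        rhs=rhs.ravel(),
        fixed_labels=labels,
        n_traits=t,
    )


# ---------------------------------------------------------------------------
# solver

@dataclass
class PCGResult:
    x: np.ndarray
    iterations: int
    converged: bool
    criterion: float
    trace: np.ndarray

    def solution_matrix(self, system: MMESystem) -> np.ndarray:
        return self.x.reshape(system.n_levels, system.n_traits)


def solve_pcg(system: MMESystem, options: SolverOptions | None = None) -> PCGResult:
    """Preconditioned conjugate gradients from a zero start vector.

    Convergence criterion: Euclidean norm of (rhs - C x) relative to the
    norm of rhs, below ``options.tolerance`` (default 1e-6).  Jacobi
    (diagonal) preconditioning; deterministic.
    """
    options = options or SolverOptions()
    b = system.rhs
    nb = np.linalg.norm(b)
    if nb == 0:
        return PCGResult(np.zeros_like(b), 0, True, 0.0, np.zeros(0))
    if options.preconditioner == "jacobi":
        d = system.diagonal()
        d = np.where(d > 1e-300, d, 1.0)
        Minv = 1.0 / d
    else:
        Minv = np.ones_like(b)
    x = np.zeros_like(b)
    r = b.copy()
    z = Minv * r
    p = z.copy()
    rz = r @ z
    trace = []
    crit = np.linalg.norm(r) / nb
    for it in range(1, options.max_iterations + 1):
        Ap = system.matvec(p)
        pAp = p @ Ap
        if pAp <= 0:
            break  # left the positive subspace; return best so far
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        crit = np.linalg.norm(r) / nb
        trace.append(crit)
        if crit < options.tolerance:
            # confirm with the true residual
            crit = np.linalg.norm(b - system.matvec(x)) / nb
            trace[-1] = crit
            if crit < options.tolerance:
                return PCGResult(x, it, True, crit, np.asarray(trace))
            r = b - system.matvec(x)
        z = Minv * r
        rz_new = r @ z
        beta = rz_new / rz
        rz = rz_new
        p = z + beta * p
    return PCGResult(x, len(trace), False, crit, np.asarray(trace))


def extract_gebv(result: PCGResult, system: MMESystem, spec: ModelSpec) -> pd.DataFrame:
    """Per-animal, per-trait genetic solutions.

    QP-augmented systems already yield group-inclusive breeding values for
    the animal equations; metafounder systems report animal solutions
    as-is.  Group/metafounder equations (negative ids) are dropped.
    """
    U = result.solution_matrix(system)[system.n_fixed:]
    ids = system.operator.ids
    keep = ids > 0
    out = pd.DataFrame(U[keep], index=ids[keep], columns=list(spec.traits))
    out.index.name = "animal"
    return out


def extract_group_solutions(result: PCGResult, system: MMESystem,
                            spec: ModelSpec) -> pd.DataFrame:
    """Solutions of the UPG/metafounder equations (indexed by group id).

    These are the estimated genetic levels of the unknown-parent base
    populations: the expected breeding value of an unrecorded parent
    coded to group g.
    """
    U = result.solution_matrix(system)[system.n_fixed:]
    ids = system.operator.ids
    keep = ids < 0
    out = pd.DataFrame(U[keep], index=-ids[keep], columns=list(spec.traits))
    out.index.name = "group"
    return out


# ---------------------------------------------------------------------------
# high-level model construction

@dataclass
class Evaluation:
    spec: ModelSpec
    system: MMESystem
    result: PCGResult
    gebv: pd.DataFrame
    group_solutions: pd.DataFrame
    fixed_solutions: pd.Series
    operator: RelationshipOperator


def _build_operator(spec: ModelSpec, pedigree: Pedigree, groups: GroupTable,
                    panel: GenotypePanel | None, gamma: GammaMatrix | None):
    mt = spec.model_type
    if mt in ("pmf", "ssmf"):
        if gamma is None:
            raise ValueError(f"model {mt} requires a (bent) Gamma matrix")
        if gamma.provenance != "bent":
            raise ValueError("Gamma must be bent before use in an inverse")
        Ag_inv = build_A_gamma_inverse(pedigree, gamma)
        if mt == "pmf":
            return SparsePrecisionOperator(Ag_inv)
        geno = panel.animal_ids
        A22g = build_A_gamma(pedigree, gamma, subset=geno)
        A22g_inv = np.linalg.inv(A22g.dense())
        G05 = build_G05(panel)
        bl = blend(G05, A22g, w=spec.w, panel=panel)
        woodbury_factorize(bl, A22g_inv)
        return build_H_inverse_mf(Ag_inv, A22g, bl)
    # UPG family
    F = compute_inbreeding(pedigree)
    Q = compute_Q(pedigree, groups)
    A_upg_inv = build_A_upg_inverse(pedigree, F, Q)
    if mt == "pupg":
        return SparsePrecisionOperator(A_upg_inv)
    geno = panel.animal_ids
    A22 = build_A(pedigree, subset=geno)
    A22_inv = np.linalg.inv(A22.dense())
    Q2 = GroupContributionMatrix(Q.rows(geno), np.asarray(geno), Q.group_ids)
    G05 = build_G05(panel)
    bl = blend(G05, A22, w=spec.w, panel=panel)
    woodbury_factorize(bl, A22_inv)
    return build_H_inverse_upg(A_upg_inv, A22_inv, Q2, bl)


def build_evaluation(spec: ModelSpec, pedigree: Pedigree, groups: GroupTable,
                     phenotypes: pd.DataFrame,
                     panel: GenotypePanel | None = None,
                     gamma: GammaMatrix | None = None,
                     breed_props: pd.DataFrame | None = None,
                     options: SolverOptions | None = None) -> Evaluation:
    """Assemble and solve one of the four evaluation models end to end."""
    if spec.model_type.startswith("ss") and panel is None:
        raise ValueError("single-step models require genotypes")
    operator = _build_operator(spec, pedigree, groups, panel, gamma)
    system = assemble_mme(spec, phenotypes, operator, breed_props=breed_props)
    result = solve_pcg(system, options)
    gebv = extract_gebv(result, system, spec)
    group_solutions = extract_group_solutions(result, system, spec)
    t = spec.n_traits
    fixed = result.solution_matrix(system)[:system.n_fixed]
    fixed_labels = []
    for lab in system.fixed_labels:
        for tr in spec.traits:
            fixed_labels.append(f"{lab}|{tr}")
    fixed_solutions = pd.Series(fixed.ravel(), index=fixed_labels)
    return Evaluation(spec=spec, system=system, result=result, gebv=gebv,
                      group_solutions=group_solutions,
                      fixed_solutions=fixed_solutions, operator=operator)
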