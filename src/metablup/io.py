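"""Plain-text readers/writers and the staged pipeline driver.

All formats are tab-separated text for inspectability at desk scale:
pedigree, group, genotype, allele-frequency, Gamma, phenotype, and
[G]EBV tables.  Floats are written with 10 significant digits so
write(read(f)) round-trips bit-identically modulo formatting.
"""

from __future__ import annotations

import sys

import numpy as np
import pandas as pd

from .gamma import AlleleFreqPanel, GammaMatrix
from .genomic import GenotypePanel
from .pedigree import GroupTable, Pedigree

__all__ = [
    "read_pedigree", "write_pedigree",
    "read_groups", "write_groups",
    "read_genotypes", "write_genotypes",
    "read_af_panel", "write_af_panel",
    "read_gamma", "write_gamma",
    "read_phenotypes", "write_phenotypes",
    "read_gebv", "write_gebv",
    "read_config", "run_pipeline",
]

_FLOAT_FMT = "%.10g"


def _fmt(x) -> str:
    return _FLOAT_FMT % x


# -- pedigree ---------------------------------------------------------------

def read_pedigree(path, groups: GroupTable | None = None) -> Pedigree:
    df = pd.read_csv(path, sep="\t")
    required = ["animal", "sire", "dam", "birth_year", "breed", "country", "sex", "genotyped"]
    for i, col in enumerate(required):
        if col not in df.columns:
            raise ValueError(f"{path}: missing pedigree column {col!r}")
    for col in ("animal", "sire", "dam", "birth_year"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"{path}:{line}: malformed integer in column {col!r}")
        df[col] = df[col].astype(np.int64)
    df["genotyped"] = df["genotyped"].astype(int).astype(bool)
    return Pedigree(df, groups=groups)


def write_pedigree(pedigree: Pedigree, path) -> None:
    df = pedigree.df.copy()
    df["genotyped"] = df["genotyped"].astype(int)
    cols = ["animal", "sire", "dam", "birth_year", "breed", "country", "sex", "genotyped"]
    df[cols].to_csv(path, sep="\t", index=False)


# -- groups -----------------------------------------------------------------

def read_groups(path) -> GroupTable:
    df = pd.read_csv(path, sep="\t")
    return GroupTable(df)


def write_groups(groups: GroupTable, path) -> None:
    cols = ["group_id", "breed", "country", "year_start", "year_end"]
    extra = [c for c in ("breed_class", "name") if c in groups.df.columns]
    groups.df[cols + extra].to_csv(path, sep="\t", index=False)


# -- genotypes --------------------------------------------------------------

def read_genotypes(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "animal":
        raise ValueError(f"{path}: first genotype column must be 'animal'")
    markers = list(df.columns[1:])
    D = df[markers].to_numpy()
    bad = ~np.isin(D, [0, 1, 2])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}:{int(i) + 2}: invalid dosage {D[i, j]!r} for marker {markers[j]}"
        )
    return GenotypePanel(D, df["animal"].to_numpy(), np.asarray(markers))


def write_genotypes(panel: GenotypePanel, path) -> None:
    df = panel.to_frame()
    df.index.name = "animal"
    df.to_csv(path, sep="\t")


# -- allele-frequency panel -------------------------------------------------

def read_af_panel(path) -> AlleleFreqPanel:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "marker":
        raise ValueError(f"{path}: first AF column must be 'marker'")
    groups = [int(c) if str(c).isdigit() else c for c in df.columns[1:]]
    return AlleleFreqPanel(df.iloc[:, 1:].to_numpy(float),
                           df["marker"].to_numpy(), groups, source=str(path))


def write_af_panel(panel: AlleleFreqPanel, path) -> None:
    df = pd.DataFrame(panel.P, columns=[str(g) for g in panel.group_ids])
    df.insert(0, "marker", panel.marker_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# -- gamma ------------------------------------------------------------------

def read_gamma(path, provenance: str = "estimated") -> GammaMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    G = df.to_numpy(float)
    ids = [int(c) if str(c).isdigit() else c for c in df.columns]
    asym = np.abs(G - G.T)
    if asym.size and asym.max() > 1e-8 * max(1.0, np.abs(G).max()):
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"{path}: Gamma not symmetric at cell ({ids[i]}, {ids[j]})"
        )
    return GammaMatrix(0.5 * (G + G.T), ids, provenance=provenance)


def write_gamma(gamma: GammaMatrix, path) -> None:
    df = pd.DataFrame(gamma.values,
                      index=[str(g) for g in gamma.group_ids],
                      columns=[str(g) for g in gamma.group_ids])
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# -- phenotypes / GEBV ------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gebv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.pivot(index="animal", columns="trait", values="gebv")


def write_gebv(gebv: pd.DataFrame, path) -> None:
    tidy = gebv.reset_index().melt(id_vars="animal", var_name="trait",
                                   value_name="gebv")
    tidy.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# -- config & pipeline ------------------------------------------------------

def read_config(path) -> dict:
    """Plain key = value config; values parsed as int/float when possible."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            k, v = (s.strip() for s in line.split("=", 1))
            for cast in (int, float):
                try:
                    v = cast(v)
                    break
                except ValueError:
                    continue
            out[k] = v
    return out


def run_pipeline(config: dict, out_dir, log=print) -> dict:
    """Execute simulate -> prune -> freq -> gamma -> solve -> validate.

    ``config`` keys (all optional, with generator defaults): seed, model
    (pupg/pmf/ssupg/ssmf), w, tolerance, bend_delta, cutoff_years, plus any
    :class:`~metablup.simulate.SimulationConfig` field.  Artifacts are
    written to ``out_dir``; the main result tables are returned.
    """
    import os

    from .gamma import (bend_gamma, build_phi, estimate_base_af_gls,
                        extrapolate_gamma, fit_cov_function, gamma_from_af)
    from .mme import ModelSpec, SolverOptions, build_evaluation
    from .pedigree import build_A, compute_Q, truncate_pedigree
    from .simulate import SimulationConfig, simulate_all
    from .validation import forward_validation

    os.makedirs(out_dir, exist_ok=True)
    sim_keys = set(SimulationConfig.__dataclass_fields__)
    sim_cfg = SimulationConfig(**{k: v for k, v in config.items() if k in sim_keys})
    log(f"[simulate] seed={sim_cfg.seed}")
    data = simulate_all(sim_cfg)
    write_pedigree(data.pedigree, os.path.join(out_dir, "pedigree.tsv"))
    write_groups(data.groups, os.path.join(out_dir, "groups.tsv"))
    write_genotypes(data.panel, os.path.join(out_dir, "genotypes.tsv"))
    write_phenotypes(data.phenotypes, os.path.join(out_dir, "phenotypes.tsv"))
    log(f"[simulate] {data.pedigree.n} animals, {data.panel.n} genotyped, "
        f"{len(data.phenotypes)} records")

    log("[prune] truncating pedigree to one ancestor generation of genotyped animals")
    trunc = truncate_pedigree(data.pedigree, data.groups, depth=1)
    write_pedigree(trunc, os.path.join(out_dir, "pedigree_truncated.tsv"))

    log("[freq] GLS base allele frequencies")
    geno_ids = data.panel.animal_ids
    A22 = build_A(trunc, subset=geno_ids)
    A22_inv = np.linalg.inv(A22.dense())
    Q2 = compute_Q(trunc, data.groups, rows=geno_ids)
    af = estimate_base_af_gls(data.panel, A22_inv, Q2)
    write_af_panel(af, os.path.join(out_dir, "base_af.tsv"))
    log(f"[freq] {af.n_out_of_range} estimates outside [0, 1] (kept unclipped)")

    log("[gamma] 8*Cov, covariance-function fit, extrapolation, bending")
    g_pre = gamma_from_af(af)
    ymin = int(data.groups.df["representative_year"].min())
    ymax = int(data.groups.df["representative_year"].max())
    phi, spec_cols = build_phi(data.groups, year_min=ymin, year_max=ymax,
                               year_degree=1 if ymax > ymin else 0)
    model = fit_cov_function(g_pre, phi, spec_cols)
    g_all = extrapolate_gamma(model, phi, data.groups.group_ids, spec_cols)
    g_bent = bend_gamma(g_all, float(config.get("bend_delta", 0.025)))
    write_gamma(g_pre, os.path.join(out_dir, "gamma_pre.tsv"))
    write_gamma(g_all, os.path.join(out_dir, "gamma_extrapolated.tsv"))
    write_gamma(g_bent, os.path.join(out_dir, "gamma_bent.tsv"))
    log(f"[gamma] rank(K)={model.q}, residual |E|_F={model.residual_fro:.4g}")

    model_type = str(config.get("model", "ssmf"))
    spec = ModelSpec(
        traits=[f"trait{j+1}" for j in range(sim_cfg.n_traits)],
        fixed_factors=["herd", "year", "season"],
        model_type=model_type,
        G0=sim_cfg.G0(), R0=sim_cfg.R0(),
        w=float(config.get("w", 0.30)),
    )
    options = SolverOptions(tolerance=float(config.get("tolerance", 1e-6)))
    gamma_arg = g_bent if model_type in ("pmf", "ssmf") else None
    log(f"[solve] model={model_type}")
    ev = build_evaluation(spec, data.pedigree, data.groups, data.phenotypes,
                          panel=data.panel, gamma=gamma_arg, options=options)
    write_gebv(ev.gebv, os.path.join(out_dir, "gebv.tsv"))
    log(f"[solve] PCG iterations={ev.result.iterations} "
        f"criterion={ev.result.criterion:.3e} converged={ev.result.converged}")

    cutoff = int(config.get("cutoff_years", 4))
    log(f"[validate] forward prediction, cutoff_years={cutoff}")
    results = forward_validation(spec, data.pedigree, data.groups,
                                 data.phenotypes, panel=data.panel,
                                 gamma=gamma_arg, cutoff_years=cutoff,
                                 role=str(config.get("role", "cow")),
                                 options=options, full_eval=ev)
    vdf = pd.DataFrame([vars(r) for r in results])
    vdf.to_csv(os.path.join(out_dir, "validation.tsv"), sep="\t", index=False,
               float_format=_FLOAT_FMT)
    for r in results:
        log(f"[validate] {r.trait}: b1={r.b1:.3f} R2={r.r2:.3f} "
            f"adj.rel={r.adjusted_reliability:.3f} n={r.n}")
    return {"evaluation": ev, "gamma": g_bent, "validation": results,
            "af": af, "data": data}
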