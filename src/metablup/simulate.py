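"""Synthetic multi-breed pedigree, genotype, and phenotype generator.

Emulates, at desk scale, the population structure the evaluation models
are built for: several base populations (metafounders) defined as
breed x country x period cells, drifted apart from a common ancestral
population; an overlapping-generation pedigree with heavy sire use,
occasional crossbreeding and migration, and missing parents; gene-dropped
marker genotypes; and phenotypes with a stated heritability, herd/season
fixed effects, and parity-as-trait structure.

The generator knows its own truth: base allele frequencies per
metafounder (hence Gamma_true = 8 Cov(P_true)), true breeding values, and
the marker/polygenic split, so estimation and validation code can be
tested for parameter recovery.

All draws flow from a single integer seed; identical configs give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic import GenotypePanel
from .pedigree import GroupTable, Pedigree, sort_and_validate

__all__ = ["SimulationConfig", "TruthBundle", "SimulatedData",
           "simulate_base_populations", "simulate_pedigree", "gene_drop",
           "simulate_phenotypes", "simulate_all"]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    Defaults are a desk-scale image of a multi-country dairy evaluation:
    four base populations (two breeds in two countries), drift F ~ 0.08
    between them (between-population cattle F_ST is commonly 0.05-0.15),
    2,000 markers with ancestral frequencies uniform on [0.05, 0.95], and
    roughly 500 genotyped animals in the youngest generations.
    """

    seed: int = 1
    breeds: tuple = ("RDC", "FIC")
    countries: tuple = ("FIN", "SWE")
    n_metafounders: int = 4
    founders_per_mf: int = 100
    generations: int = 6
    offspring_per_generation: int = 180
    sires_per_cell: int = 15
    crossing_rate: float = 0.05     # matings across breed
    migration_rate: float = 0.05    # matings across country within breed
    missing_parent_rate: float = 0.08
    m_markers: int = 2000
    ancestral_af_low: float = 0.05
    ancestral_af_high: float = 0.95
    f_drift: float = 0.08
    n_traits: int = 1               # parities, modeled as traits
    h2: float = 0.40                # 305-d yield scale heritability
    genetic_corr: float = 0.85      # between parity traits
    rpg_share: float = 0.30        # polygenic (non-marker) share of sigma_u^2
    sigma_u2: float = 1.0
    n_herds: int = 25
    herd_sd: float = 0.5
    season_sd: float = 0.2
    genotyped_generations: int = 3
    genotyped_fraction: float = 0.95
    founder_year: int = 1990
    years_per_generation: int = 3

    def __post_init__(self):
        for name in ("crossing_rate", "migration_rate", "missing_parent_rate",
                     "genotyped_fraction", "f_drift", "rpg_share"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    def G0(self) -> np.ndarray:
        t = self.n_traits
        C = np.full((t, t), self.genetic_corr)
        np.fill_diagonal(C, 1.0)
        return self.sigma_u2 * C

    def R0(self) -> np.ndarray:
        se2 = self.sigma_u2 * (1.0 - self.h2) / self.h2
        return se2 * np.eye(self.n_traits)


@dataclass
class TruthBundle:
    """What the generator knows that estimation must recover."""

    P_true: np.ndarray                  # markers x metafounders
    gamma_true: np.ndarray              # 8 Cov(P_true)
    marker_ids: np.ndarray | None = None
    group_ids: list | None = None
    true_bv: pd.DataFrame | None = None       # animals x traits
    marker_effects: np.ndarray | None = None  # markers x traits
    R0_used: np.ndarray | None = None         # residual covariance realized


@dataclass
class SimulatedData:
    pedigree: Pedigree
    groups: GroupTable
    panel: GenotypePanel          # genotyped animals only
    phenotypes: pd.DataFrame
    truth: TruthBundle
    config: SimulationConfig
    allele_pairs: tuple = None    # internal: full (pat, mat) allele arrays


# ---------------------------------------------------------------------------

def _group_scheme(config: SimulationConfig) -> pd.DataFrame:
    """Metafounder cells: breed x country, extra periods if r > cells."""
    cells = [(b, c) for b in config.breeds for c in config.countries]
    r = config.n_metafounders
    rows = []
    span = 10
    last_year = config.founder_year + config.generations * config.years_per_generation
    for g in range(r):
        b, c = cells[g % len(cells)]
        period = g // len(cells)
        end = config.founder_year - span * period
        rows.append(dict(group_id=g + 1, breed=b, country=c,
                         year_start=end - span + 1, year_end=min(end, last_year),
                         name=f"{b}-{c}-{end % 100:02d}", breed_class=b))
    # let the newest period of each cell absorb later years
    df = pd.DataFrame(rows)
    for (b, c), sub in df.groupby(["breed", "country"]):
        df.loc[sub["year_end"].idxmax(), "year_end"] = last_year
    return df


def simulate_base_populations(config: SimulationConfig) -> TruthBundle:
    """Ancestral allele frequencies and per-metafounder drifted base AF.

    One ancestral frequency p per marker, uniform on the configured range;
    each metafounder's base AF is a Beta draw with mean p and variance
    p(1-p) * f_drift, the classical drift parameterization (f_drift = 0
    collapses all populations onto the ancestral AF).
    """
    rng = config.rng(11)
    m, r = config.m_markers, config.n_metafounders
    p = rng.uniform(config.ancestral_af_low, config.ancestral_af_high, size=m)
    if config.f_drift == 0:
        P = np.repeat(p[:, None], r, axis=1)
    else:
        nu = 1.0 / config.f_drift - 1.0
        a = np.clip(p * nu, 1e-3, None)
        b = np.clip((1.0 - p) * nu, 1e-3, None)
        P = rng.beta(a[:, None], b[:, None], size=(m, r))
    gamma_true = 8.0 * np.cov(P.T, bias=True)
    marker_ids = np.array([f"snp{j + 1}" for j in range(m)])
    return TruthBundle(P_true=P, gamma_true=np.atleast_2d(gamma_true),
                       marker_ids=marker_ids,
                       group_ids=list(range(1, r + 1)))


def simulate_pedigree(config: SimulationConfig):
    """Overlapping-generation pedigree plus its group table.

    Founders are assigned to metafounder cells; each later generation
    mates a small team of sires per breed x country cell to dams drawn
    from the two preceding generations, with configured crossbreeding,
    migration, and missing-parent rates.  Animals in the youngest
    generations are flagged genotyped (all retained sires, plus a fraction
    of females).
    """
    rng = config.rng(22)
    gdf = _group_scheme(config)
    groups = GroupTable(gdf)
    rows = []
    aid = 0

    def add(sire, dam, year, breed, country, sex, gen):
        nonlocal aid
        aid += 1
        rows.append(dict(animal=aid, sire=sire, dam=dam, birth_year=year,
                         breed=breed, country=country, sex=sex,
                         genotyped=False, generation=gen))
        return aid

    by_cell: dict[tuple, dict[int, list]] = {}
    for _, g in gdf.iterrows():
        cell = (g["breed"], g["country"])
        members = by_cell.setdefault(cell, {})
        lst = members.setdefault(0, [])
        for _ in range(config.founders_per_mf):
            sex = "M" if rng.random() < 0.5 else "F"
            a = add(-int(g["group_id"]), -int(g["group_id"]),
                    int(g["year_end"]) if g["year_end"] <= config.founder_year
                    else config.founder_year,
                    g["breed"], g["country"], sex, 0)
            lst.append((a, sex))

    cells = list(by_cell)
    for gen in range(1, config.generations + 1):
        year = config.founder_year + gen * config.years_per_generation
        # candidate parents: previous two generations
        def pool(cell, sex):
            out = []
            for g in (gen - 1, gen - 2):
                out += [a for a, s in by_cell.get(cell, {}).get(g, []) if s == sex]
            return out

        sire_team = {}
        for cell in cells:
            males = pool(cell, "M")
            if males:
                sire_team[cell] = rng.choice(
                    males, size=min(config.sires_per_cell, len(males)), replace=False
                )
        n_off = config.offspring_per_generation
        for _ in range(n_off):
            cell = cells[rng.integers(len(cells))]
            breed, country = cell
            dam_cell = cell
            u = rng.random()
            if u < config.crossing_rate:
                others = [c for c in cells if c[0] != breed]
                if others:
                    dam_cell = others[rng.integers(len(others))]
            elif u < config.crossing_rate + config.migration_rate:
                others = [c for c in cells if c[0] == breed and c[1] != country]
                if others:
                    dam_cell = others[rng.integers(len(others))]
            dams = pool(dam_cell, "F")
            sires = sire_team.get(cell, [])
            sire = int(rng.choice(sires)) if len(sires) else 0
            dam = int(rng.choice(dams)) if dams else 0
            if sire and rng.random() < config.missing_parent_rate:
                sire = -int(groups.assign(breed, country, year - 5))
            if dam and rng.random() < config.missing_parent_rate:
                dam = -int(groups.assign(dam_cell[0], dam_cell[1], year - 5))
            if sire == 0:
                sire = -int(groups.assign(breed, country, year - 5))
            if dam == 0:
                dam = -int(groups.assign(dam_cell[0], dam_cell[1], year - 5))
            sex = "M" if rng.random() < 0.5 else "F"
            a = add(sire, dam, year, breed, country, sex, gen)
            by_cell.setdefault(cell, {}).setdefault(gen, []).append((a, sex))

    df = pd.DataFrame(rows)
    young = df["generation"] > config.generations - config.genotyped_generations
    is_male = df["sex"] == "M"
    keep = young & (is_male | (rng.random(len(df)) < config.genotyped_fraction))
    df.loc[keep, "genotyped"] = True
    ped = sort_and_validate(Pedigree(df, groups=groups))
    return ped, groups


def gene_drop(pedigree: Pedigree, truth: TruthBundle, config: SimulationConfig,
              animals: str = "genotyped"):
    """Drop alleles through the pedigree from metafounder base frequencies.

    Founders (and unknown-parent sides) draw alleles Bernoulli(p_g) from
    their group's base AF; each descendant inherits one uniformly chosen
    allele per parent per marker.  Returns a dosage
    :class:`~metablup.genomic.GenotypePanel` for the genotyped subset (or
    all animals), plus the raw allele pair for internal reuse.
    """
    rng = config.rng(33)
    m = truth.P_true.shape[0]
    n = pedigree.n
    pat = np.zeros((n, m), dtype=np.int8)
    mat = np.zeros((n, m), dtype=np.int8)
    P = truth.P_true
    for i in range(n):
        for side, store in ((0, pat), (1, mat)):
            pos = (pedigree.sire_pos, pedigree.dam_pos)[side][i]
            grp = (pedigree.sire_grp, pedigree.dam_grp)[side][i]
            if pos >= 0:
                pick = rng.integers(0, 2, size=m)
                store[i] = np.where(pick == 0, pat[pos], mat[pos])
            else:
                g = grp if grp >= 0 else 0
                store[i] = rng.random(m) < P[:, g]
    dosage = pat + mat
    if animals == "all":
        ids = pedigree.ids
        sel = np.arange(n)
    else:
        sel = np.flatnonzero(pedigree.df["genotyped"].astype(bool).to_numpy())
        ids = pedigree.ids[sel]
    panel = GenotypePanel(dosage[sel], ids, truth.marker_ids)
    return panel, (pat, mat)


def _psd_factor(S: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (S + S.T))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _true_breeding_values(pedigree, dosage_all, truth, config, rng):
    """Breeding values on the metafounder (Gamma-base) scale.

    Marker part: u_m = Z101 a with i.i.d. effect variance
    (1 - rpg) sigma_u^2 / k, so that Cov(u_m) matches the G05-based
    genomic covariance analytically (no empirical rescaling).  Polygenic
    part: metafounder group means drawn with covariance rpg sigma_u^2
    Gamma_true, founders deviating with variance (1 - gamma_gg/2), then
    the standard Mendelian recursion -- i.e. rpg sigma_u^2 A^Gamma.
    Together the truth has the covariance structure the metafounder
    models assume.
    """
    m = dosage_all.shape[1]
    t = config.n_traits
    G0 = config.G0()
    Lt = np.linalg.cholesky(G0 / config.sigma_u2)
    k = m / 2.0
    sig_a = np.sqrt((1.0 - config.rpg_share) * config.sigma_u2 / k)
    a = (rng.standard_normal((m, t)) @ Lt.T) * sig_a
    Z = dosage_all.astype(np.float64) - 1.0
    u_m = Z @ a
    # polygenic share: rpg * sigma_u^2 * A^Gamma structure
    s2p = config.rpg_share * config.sigma_u2
    gamma = truth.gamma_true
    gdiag = np.diag(gamma)
    Fg = _psd_factor(gamma)                       # group-mean factor
    group_means = (Fg @ rng.standard_normal((gamma.shape[0], t)) @ Lt.T) * np.sqrt(s2p)

    def virtual_parent(grp):
        g = grp if grp >= 0 else 0
        dev = np.sqrt(max(1.0 - gdiag[g] / 2.0, 0.0) * s2p)
        return group_means[g] + dev * (rng.standard_normal(t) @ Lt.T), 1.0 + gdiag[g] / 2.0

    n = pedigree.n
    up = np.zeros((n, t))
    for i in range(n):
        vals, selfrels = [], []
        for pos, grp in ((pedigree.sire_pos[i], pedigree.sire_grp[i]),
                         (pedigree.dam_pos[i], pedigree.dam_grp[i])):
            if pos >= 0:
                vals.append(up[pos])
                selfrels.append(1.0)
            else:
                v, s = virtual_parent(grp)
                vals.append(v)
                selfrels.append(s)
        mend = max(1.0 - 0.25 * sum(selfrels), 0.05)
        up[i] = 0.5 * (vals[0] + vals[1]) + np.sqrt(mend * s2p) * (
            rng.standard_normal(t) @ Lt.T
        )
    return u_m + up, a


def simulate_phenotypes(pedigree: Pedigree, truth: TruthBundle,
                        config: SimulationConfig,
                        allele_pairs=None) -> pd.DataFrame:
    """Phenotype records for cows: parity traits with herd/season effects.

    y = herd + year-season + calving-age polynomial + u + e, one record
    per cow and parity trait.  The residual variance is set from the
    configured heritability against the *realized* population variance of
    the true breeding values (the Gamma-base scale inflates genetic
    variance above sigma_u^2), so Var(u)/Var(y) matches h2; the residual
    covariance actually used is stored as ``truth.R0_used`` for
    model-consistent evaluation.  Requires the gene-drop allele arrays (to
    build true breeding values); they are generated if absent.
    """
    rng = config.rng(44)
    if allele_pairs is None:
        _, allele_pairs = gene_drop(pedigree, truth, config, animals="all")
    dosage_all = (allele_pairs[0] + allele_pairs[1])
    u, a_scaled = _true_breeding_values(pedigree, dosage_all, truth, config, rng)
    truth.true_bv = pd.DataFrame(
        u, index=pedigree.ids, columns=[f"trait{j+1}" for j in range(config.n_traits)]
    )
    truth.marker_effects = a_scaled
    df = pedigree.df
    cows = np.flatnonzero((df["sex"] == "F").to_numpy())
    herd_eff = rng.normal(0, config.herd_sd, size=config.n_herds)
    # residual scaled so the configured h2 holds on the realized scale
    realized = float(np.mean(u.var(axis=0)))
    R0 = config.R0() * (realized / config.sigma_u2 if realized > 0 else 1.0)
    truth.R0_used = R0
    Lr = np.linalg.cholesky(R0)
    recs = []
    years = df["birth_year"].to_numpy()
    last_year = years.max() + 2
    season_eff = {s: rng.normal(0, config.season_sd) for s in (1, 2)}
    for i in cows:
        if pedigree.sire_pos[i] < 0 and pedigree.dam_pos[i] < 0 and years[i] <= config.founder_year:
            continue  # founder dams carry no records
        herd = int(rng.integers(config.n_herds))
        calv_year = years[i] + 2
        if calv_year > last_year:
            continue
        season = int(rng.integers(1, 3))
        age_days = float(rng.normal(730, 40))
        e = rng.standard_normal(config.n_traits) @ Lr.T
        y = herd_eff[herd] + season_eff[season] + u[i] + e
        rec = dict(animal=int(df["animal"].iloc[i]), herd=herd, year=int(calv_year),
                   season=season, calving_age=age_days)
        for j in range(config.n_traits):
            rec[f"trait{j+1}"] = y[j]
        recs.append(rec)
    return pd.DataFrame(recs)


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Run the full generator: base AF, pedigree, genotypes, phenotypes."""
    truth = simulate_base_populations(config)
    ped, groups = simulate_pedigree(config)
    panel, pairs = gene_drop(ped, truth, config, animals="genotyped")
    # reuse full allele arrays for truth BVs
    phen = simulate_phenotypes(ped, truth, config, allele_pairs=pairs)
    return SimulatedData(pedigree=ped, groups=groups, panel=panel,
                         phenotypes=phen, truth=truth, config=config,
                         allele_pairs=pairs)
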