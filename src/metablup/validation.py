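"""Forward-prediction validation: YD/DYD, weighted bias regression, trends.

The validation design: fit the model on data reduced by the last
``cutoff_years`` of records, then regress later realized performance --
yield deviations (YD) for cows, daughter yield deviations (DYD) for bulls,
both computed from the *full* data -- on the reduced-data [G]EBV.  A
regression slope b1 near 1 indicates absence of over/under-prediction
(for bulls the reported slope is doubled, since DYD is on the
transmitting-ability scale).  Weighted regression uses
EDC/(EDC + lambda_b) for bulls and ERC/(ERC + lambda_c) for cows, with
lambda_b = (4 - h^2)/h^2 and lambda_c = (1 - h^2)/h^2; the adjusted
validation reliability is R^2 divided by the mean weight.

ERC is simplified to the per-trait record count of the cow and EDC to the
sum of daughter ERC.  With single-record daughters this makes
EDC/(EDC + lambda_b) exactly the reliability of the DYD (the quarter
signal share of a daughter is already inside lambda_b), so the adjusted
reliability stays on the [0, 1] scale.  Any monotone positive
contribution measure yields a valid weighted regression; the
simplification is isolated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mme import Evaluation, ModelSpec, _fixed_design

__all__ = [
    "ValidationResult",
    "compute_yd",
    "compute_dyd",
    "effective_contributions",
    "reliability_weights",
    "validation_regression",
    "combined_index",
    "genetic_trend",
    "forward_validation",
]

PARITY_WEIGHTS = (0.30, 0.25, 0.45)


@dataclass
class ValidationResult:
    """Weighted bias regression summary for one trait."""

    trait: str
    role: str                  # bull | cow
    b0: float
    b1: float                  # doubled for bulls (transmitting-ability scale)
    r2: float
    adjusted_reliability: float
    n: int
    lambda_used: float
    mean_weight: float


def compute_yd(phenotypes: pd.DataFrame, evaluation: Evaluation,
               breed_props: pd.DataFrame | None = None) -> pd.DataFrame:
    """Yield deviations: per-cow mean of (y - fitted fixed effects).

    Fixed-effect fits come from the supplied (full-data) evaluation; the
    phenotype table must be the one the evaluation was assembled from so
    factor levels line up.  Returns a tidy frame (animal, trait, yd,
    n_records).
    """
    spec = evaluation.spec
    X, labels = _fixed_design(phenotypes, spec, breed_props)
    if labels != evaluation.system.fixed_labels:
        raise ValueError("phenotype table does not match the evaluation's design")
    t = spec.n_traits
    F = evaluation.result.solution_matrix(evaluation.system)[: evaluation.system.n_fixed]
    fits = X @ F
    out = []
    Y = phenotypes[list(spec.traits)].to_numpy(dtype=float)
    dev = Y - fits
    frame = pd.DataFrame(dev, columns=list(spec.traits))
    frame["animal"] = phenotypes["animal"].to_numpy()
    for trait in spec.traits:
        g = frame.groupby("animal")[trait].agg(["mean", "count"])
        g = g[g["count"] > 0].dropna()
        for a, row in g.iterrows():
            out.append(dict(animal=a, trait=trait, yd=row["mean"],
                            n_records=int(row["count"])))
    return pd.DataFrame(out)


def effective_contributions(yd: pd.DataFrame) -> pd.DataFrame:
    """ERC per cow and trait: the number of records for the trait."""
    erc = yd[["animal", "trait", "n_records"]].copy()
    erc = erc.rename(columns={"n_records": "erc"})
    erc["erc"] = erc["erc"].astype(float)
    return erc


def compute_dyd(yd: pd.DataFrame, pedigree, dam_ebv: pd.DataFrame,
                group_ebv: pd.DataFrame | None = None) -> pd.DataFrame:
    """Daughter yield deviations for bulls.

    DYD is on the transmitting-ability scale: the ERC-weighted mean over
    phenotyped daughters of (YD_daughter - EBV_dam / 2), i.e. an estimate
    of half the bull's breeding value -- which is why the validation
    regression doubles the reported bull slope.  A dam recorded as an
    unknown-parent code contributes the model's estimated group/metafounder
    level (``group_ebv``, indexed by group id) -- leaving it at zero would
    push the base-population mean into the DYD and bias the validation
    slope upward.  Bulls without phenotyped daughters are absent from the
    output.  Returns (bull, trait, dyd, n_daughters, edc).
    """
    df = pedigree.df.set_index("animal")
    sire = df["sire"]
    dam = df["dam"]
    out = []
    for trait, sub in yd.groupby("trait"):
        sub = sub.set_index("animal")
        bulls: dict = {}
        for cow, row in sub.iterrows():
            s = sire.get(cow, 0)
            if s is None or s <= 0:
                continue
            d = dam.get(cow, 0)
            dam_val = 0.0
            if d is not None and d > 0 and trait in dam_ebv.columns and d in dam_ebv.index:
                dam_val = float(dam_ebv.loc[d, trait])
            elif d is not None and d < 0 and group_ebv is not None and -d in group_ebv.index:
                dam_val = float(group_ebv.loc[-d, trait])
            w = float(row["n_records"])
            contrib = row["yd"] - 0.5 * dam_val
            acc = bulls.setdefault(s, [0.0, 0.0, 0])
            acc[0] += w * contrib
            acc[1] += w
            acc[2] += 1
        for b, (num, den, cnt) in bulls.items():
            out.append(dict(animal=b, trait=trait, dyd=num / den,
                            n_daughters=cnt, edc=den))
    return pd.DataFrame(out)


def reliability_weights(contributions, h2: float, role: str) -> np.ndarray:
    """Validation weights: c/(c + lambda) with the role-specific lambda.

    Bulls: lambda_b = (4 - h^2)/h^2 (DYD scale); cows:
    lambda_c = (1 - h^2)/h^2 (single-record YD scale).
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must be in (0, 1)")
    lam = (4.0 - h2) / h2 if role == "bull" else (1.0 - h2) / h2
    c = np.asarray(contributions, dtype=float)
    if (c < 0).any():
        raise ValueError("contributions must be non-negative")
    return c / (c + lam)


def validation_regression(observed, predicted, weights, role: str,
                          trait: str = "", h2: float | None = None) -> ValidationResult:
    """Weighted regression of DYD/YD on reduced-data [G]EBV.

    The reported bull slope is doubled (DYD is a transmitting-ability
    measure, [G]EBV a breeding-value one).  Adjusted reliability is the
    weighted R^2 divided by the mean weight.
    """
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 animals for the validation regression")
    W = w / w.sum()
    xb = (W * x).sum()
    yb = (W * y).sum()
    sxx = (W * (x - xb) ** 2).sum()
    sxy = (W * (x - xb) * (y - yb)).sum()
    syy = (W * (y - yb) ** 2).sum()
    slope = sxy / sxx
    b0 = yb - slope * xb
    r2 = 0.0 if syy == 0 else (sxy**2) / (sxx * syy)
    mean_w = w.mean()
    lam = np.nan
    if h2 is not None:
        lam = (4.0 - h2) / h2 if role == "bull" else (1.0 - h2) / h2
    b1 = 2.0 * slope if role == "bull" else slope
    return ValidationResult(trait=trait, role=role, b0=float(b0), b1=float(b1),
                            r2=float(r2),
                            adjusted_reliability=float(r2 / mean_w),
                            n=len(y), lambda_used=float(lam),
                            mean_weight=float(mean_w))


def combined_index(parity_ebv) -> float | np.ndarray:
    """Combined parity index: 0.30 p1 + 0.25 p2 + 0.45 p3."""
    p = np.asarray(parity_ebv, dtype=float)
    w = np.asarray(PARITY_WEIGHTS)
    if p.ndim == 1:
        if p.shape[0] != 3:
            raise ValueError("expected three parity values")
        return float(p @ w)
    if p.shape[1] != 3:
        raise ValueError("expected three parity columns")
    return p @ w


def genetic_trend(gebv: pd.Series, birth_years: pd.Series,
                  reference: pd.Index | np.ndarray) -> pd.DataFrame:
    """Yearly mean (combined-index) [G]EBV, centered on a reference group."""
    ref = pd.Index(reference)
    common = ref.intersection(gebv.index)
    if len(common) == 0:
        raise ValueError("empty reference group")
    center = gebv.loc[common].mean()
    df = pd.DataFrame({"gebv": gebv, "year": birth_years.reindex(gebv.index)})
    out = df.groupby("year")["gebv"].mean() - center
    return out.reset_index().rename(columns={"gebv": "mean_index"})


# ---------------------------------------------------------------------------
# end-to-end forward prediction

def forward_validation(spec: ModelSpec, pedigree, groups, phenotypes,
                       panel=None, gamma=None, breed_props=None,
                       cutoff_years: int = 4, role: str = "bull",
                       min_daughters: int = 5, options=None,
                       full_eval: Evaluation | None = None) -> list[ValidationResult]:
    """Run the modified forward prediction for one model.

    Fits the model on the full data and on data reduced by the last
    ``cutoff_years`` of records; computes YD (and DYD) from the full fit;
    and regresses them on the reduced-data [G]EBV of the validation
    animals (those with data only in the full set).
    """
    from .mme import build_evaluation

    year_max = int(phenotypes["year"].max())
    cutoff = year_max - cutoff_years
    reduced = phenotypes[phenotypes["year"] <= cutoff].reset_index(drop=True)
    if reduced.empty:
        raise ValueError("cutoff removes all records")
    if full_eval is None:
        full_eval = build_evaluation(spec, pedigree, groups, phenotypes,
                                     panel=panel, gamma=gamma,
                                     breed_props=breed_props, options=options)
    red_eval = build_evaluation(spec, pedigree, groups, reduced,
                                panel=panel, gamma=gamma,
                                breed_props=breed_props, options=options)
    yd = compute_yd(phenotypes, full_eval, breed_props)
    h2s = spec.h2()
    in_reduced = set(reduced["animal"])
    results = []
    if role == "cow":
        val_animals = set(phenotypes["animal"]) - in_reduced
        for j, trait in enumerate(spec.traits):
            sub = yd[(yd["trait"] == trait) & yd["animal"].isin(val_animals)]
            sub = sub[sub["animal"].isin(red_eval.gebv.index)]
            w = reliability_weights(sub["n_records"], h2s[j], "cow")
            pred = red_eval.gebv.loc[sub["animal"], trait]
            results.append(validation_regression(
                sub["yd"], pred, w, "cow", trait=trait, h2=h2s[j]))
        return results
    # bulls: daughters with data only in the full set
    val_cows = set(phenotypes["animal"]) - in_reduced
    yd_val = yd[yd["animal"].isin(val_cows)]
    dyd = compute_dyd(yd_val, pedigree, full_eval.gebv,
                      group_ebv=full_eval.group_solutions)
    for j, trait in enumerate(spec.traits):
        sub = dyd[(dyd["trait"] == trait) & (dyd["n_daughters"] >= min_daughters)]
        sub = sub[sub["animal"].isin(red_eval.gebv.index)]
        w = reliability_weights(sub["edc"], h2s[j], "bull")
        pred = red_eval.gebv.loc[sub["animal"], trait]
        results.append(validation_regression(
            sub["dyd"], pred, w, "bull", trait=trait, h2=h2s[j]))
    return results
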