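"""Published reference inputs for the Nordic Red Dairy Cattle application.

These constants reproduce the published application of the method to the
Denmark-Finland-Sweden Red Dairy Cattle evaluation: the fitted 9 x 9
covariance-function coefficient matrix, the 29-group base scheme used to
estimate the preliminary Gamma, and a deterministic reconstruction of the
148-group (breed x country x period) scheme of the full pedigree.  They
are inputs for worked examples and for reproducing the published rank
property of the extrapolated Gamma; nothing here is estimated by this
package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gamma import YEAR_MAX_DEFAULT, YEAR_MIN_DEFAULT
from .pedigree import GroupTable

__all__ = [
    "K_HAT_RDC",
    "BREED_CLASSES_RDC",
    "base_group_table",
    "reference_group_table",
]

# Breed classes of the published covariance function: RDC by country of
# origin, then Finncattle, other breeds, and Holstein.  Eight classes plus
# the standardized-year column give the 9-column model matrix.
BREED_CLASSES_RDC = ["FIN", "SWE", "DNK", "NOR", "RDC", "FIC", "OTHER", "HOL"]

# Published 9 x 9 covariance-function coefficient matrix (upper triangle as
# printed; column 1 is the standardized-year term, columns 2-9 the breed
# classes).  The matrix is positive definite (eigmin ~ 0.007), which is why
# the extrapolated Gamma has rank exactly 9.
_K_UPPER = [
    [0.0108, 0.0093, 0.0083, -0.0042, -0.0004, 0.0003, -0.0058, -0.0054, 0.0046],
    [0.6563, 0.6203, 0.5551, 0.5961, 0.5850, 0.5511, 0.5434, 0.5158],
    [0.6349, 0.5621, 0.6094, 0.5795, 0.5434, 0.5415, 0.5164],
    [0.6098, 0.5544, 0.5644, 0.5467, 0.5778, 0.5358],
    [0.6535, 0.5678, 0.5441, 0.5375, 0.5159],
    [0.5899, 0.5442, 0.5458, 0.5325],
    [0.6666, 0.5530, 0.5121],
    [0.6946, 0.5205],
    [0.6053],
]


def _sym_from_upper(rows):
    q = len(rows)
    K = np.zeros((q, q))
    for i, r in enumerate(rows):
        K[i, i:] = r
    return K + np.triu(K, 1).T


K_HAT_RDC = _sym_from_upper(_K_UPPER)

# 29-group base scheme used to estimate the preliminary Gamma: breed x
# country x five- or ten-year period; open-ended first periods start at the
# pedigree's first year point (1950).  (breed, country, year_start,
# year_end, abbreviation); breed_class follows the covariance-function
# classes above.
_BASE_GROUPS = [
    ("RDC", "FIN", 1950, 1970, "FIN70"),
    ("RDC", "FIN", 1971, 1980, "FIN80"),
    ("RDC", "FIN", 1981, 1990, "FIN90"),
    ("RDC", "FIN", 1991, 2000, "FIN00"),
    ("RDC", "FIN", 2001, 2010, "FIN10"),
    ("RDC", "FIN", 2011, 2020, "FIN20"),
    ("RDC", "SWE", 1950, 1970, "SWE70"),
    ("RDC", "SWE", 1971, 1980, "SWE80"),
    ("RDC", "SWE", 1981, 1990, "SWE90"),
    ("RDC", "SWE", 1991, 2000, "SWE00"),
    ("RDC", "SWE", 2001, 2010, "SWE10"),
    ("RDC", "SWE", 2011, 2020, "SWE20"),
    ("RDC", "DNK", 1950, 1980, "DNK80"),
    ("RDC", "DNK", 1981, 1990, "DNK90"),
    ("RDC", "DNK", 1991, 2000, "DNK00"),
    ("RDC", "DNK", 2001, 2010, "DNK10"),
    ("RDC", "DNK", 2011, 2020, "DNK20"),
    ("RDC", "NOR", 1950, 2000, "NOR00"),
    ("RDC", "NOR", 2001, 2020, "NOR20"),
    ("RDC", "ANY", 1950, 2000, "RDC00"),
    ("RDC", "ANY", 2001, 2020, "RDC20"),
    ("FIC", "FIN", 1950, 1990, "FIC90"),
    ("FIC", "FIN", 1991, 2000, "FIC00"),
    ("FIC", "FIN", 2001, 2020, "FIC20"),
    ("OTHER", "ANY", 1950, 2020, "OTH20"),
    ("HOL", "ANY", 1950, 1970, "HOL70"),
    ("HOL", "ANY", 1971, 1990, "HOL90"),
    ("HOL", "ANY", 1991, 2010, "HOL10"),
    ("HOL", "ANY", 2010, 2020, "HOL20"),
]


def _breed_class(breed: str, country: str) -> str:
    if breed == "RDC":
        return country if country in ("FIN", "SWE", "DNK", "NOR") else "RDC"
    return breed


def base_group_table() -> GroupTable:
    """The 29-group base scheme as a :class:`GroupTable`."""
    df = pd.DataFrame(
        _BASE_GROUPS, columns=["breed", "country", "year_start", "year_end", "name"]
    )
    df.insert(0, "group_id", np.arange(1, len(df) + 1))
    df["breed_class"] = [
        _breed_class(b, c) for b, c in zip(df["breed"], df["country"])
    ]
    return GroupTable(df)


# Group counts of the full 148-group scheme by breed class: 61 RDC split
# over five country classes, 45 HOL, 16 FIC, 26 OTHER.
_FULL_COUNTS = {
    "FIN": 13, "SWE": 13, "DNK": 13, "NOR": 11, "RDC": 11,
    "FIC": 16, "OTHER": 26, "HOL": 45,
}


def reference_group_table(
    counts: dict | None = None,
    year_min: int = YEAR_MIN_DEFAULT,
    year_max: int = YEAR_MAX_DEFAULT,
) -> GroupTable:
    """Deterministic reconstruction of the 148-group scheme.

    Per breed class, representative years are spread evenly over
    [year_min, year_max] (the exact period boundaries of the production
    pedigree are not published; only class membership and the year spread
    enter the covariance-function model matrix).
    """
    counts = dict(_FULL_COUNTS if counts is None else counts)
    rows = []
    gid = 1
    for cls, cnt in counts.items():
        years = np.linspace(year_min, year_max, cnt).round().astype(int)
        breed = cls if cls in ("FIC", "OTHER", "HOL") else "RDC"
        country = cls if cls in ("FIN", "SWE", "DNK", "NOR") else "ANY"
        prev = year_min - 1
        for j, y in enumerate(years):
            rows.append(
                dict(group_id=gid, breed=breed, country=country,
                     year_start=min(prev + 1, int(y)), year_end=int(y),
                     name=f"{cls}{y % 100:02d}", breed_class=cls)
            )
            prev = int(y)
            gid += 1
    return GroupTable(pd.DataFrame(rows))
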