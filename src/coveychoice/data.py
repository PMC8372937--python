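"""Choice-set data model and preparation for discrete-choice analysis.

A choice set pairs one used telemetry location with three available
locations sampled around it; each of the four alternatives carries nine
field and landscape covariates:

====  =========================================================  ==========
code  meaning                                                    range
====  =========================================================  ==========
FB    percent forbs in a 0.50-m^2 quadrat frame                  [0, 100]
GS    percent grass in the frame                                 [0, 100]
BR    percent bare ground in the frame                           [0, 100]
VO    mean visual obstruction of a 2-m pole, 4 cardinal reads    [0, 100]
SC    woody stems > 1 m tall within 5 m (count)                  >= 0
NG    proportion native grass within 50 m                        [0, 1]
PG    proportion burned/grazed in last 12 months within 50 m     [0, 1]
TD    distance to nearest tree (m)                               >= 0
WE    woody edge density within 50 m (m/ha)                      >= 0
====  =========================================================  ==========

The NG x PG interaction (``NG_PG``) is derived from the raw product, never
stored on an alternative.  FB + GS + BR may exceed 100: the frame classes
are independent cover estimates.

This module also provides available-location sampling (uniform distance in
[50, 400] m, uniform azimuth), pooled covariate standardization, and the
variance-inflation-factor multicollinearity screen (threshold 2.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .landscape import Point

__all__ = [
    "COVARIATES",
    "ALL_TERMS",
    "Alternative",
    "ChoiceSet",
    "StandardizationParams",
    "season_from_date",
    "sample_available_locations",
    "assemble_choice_sets",
    "sets_to_frame",
    "read_choice_csv",
    "write_choice_csv",
    "standardize_covariates",
    "design_matrix",
    "vif_screen",
]

#: the nine stored covariates, in canonical order
COVARIATES = ("FB", "GS", "BR", "VO", "SC", "NG", "PG", "TD", "WE")
#: stored covariates plus the derived NG x PG interaction
ALL_TERMS = COVARIATES + ("NG_PG",)

_BOUNDS = {
    "FB": (0.0, 100.0), "GS": (0.0, 100.0), "BR": (0.0, 100.0),
    "VO": (0.0, 100.0), "SC": (0.0, math.inf), "NG": (0.0, 1.0),
    "PG": (0.0, 1.0), "TD": (0.0, math.inf), "WE": (0.0, math.inf),
}

CSV_COLUMNS = ["set_id", "covey_id", "date", "season", "used", *COVARIATES]


@dataclass(frozen=True)
class Alternative:
    """One used or available location with its covariate vector."""

    FB: float
    GS: float
    BR: float
    VO: float
    SC: float
    NG: float
    PG: float
    TD: float
    WE: float
    used: bool = False

    def value(self, term: str) -> float:
        """Covariate value for a term, deriving NG_PG and quadratic forms."""
        if term.endswith("^2"):
            return self.value(term[:-2]) ** 2
        if term == "NG_PG":
            return self.NG * self.PG
        return getattr(self, term)

    def validate(self) -> None:
        for name, (lo, hi) in _BOUNDS.items():
            v = getattr(self, name)
            if not np.isfinite(v) or not (lo <= v <= hi):
                raise ValueError(f"covariate {name}={v} outside [{lo}, {hi}]")
        if abs(self.SC - round(self.SC)) > 1e-9:
            raise ValueError(f"SC must be an integer count, got {self.SC}")


@dataclass(frozen=True)
class ChoiceSet:
    """One selection event: exactly 4 alternatives, exactly 1 used."""

    set_id: object
    covey_id: object
    season: int  # fall (Nov) = 0, winter (Dec-Jan) = 1
    alternatives: tuple[Alternative, ...]
    date: object = None

    def __post_init__(self) -> None:
        if len(self.alternatives) != 4:
            raise ValueError(
                f"choice set {self.set_id!r}: expected 4 alternatives, "
                f"got {len(self.alternatives)}")
        n_used = sum(a.used for a in self.alternatives)
        if n_used != 1:
            raise ValueError(
                f"choice set {self.set_id!r}: expected exactly 1 used "
                f"alternative, got {n_used}")
        if self.season not in (0, 1):
            raise ValueError(
                f"choice set {self.set_id!r}: season must be 0 or 1, "
                f"got {self.season}")

    @property
    def used_index(self) -> int:
        return next(i for i, a in enumerate(self.alternatives) if a.used)


def season_from_date(date) -> int:
    """Map a date to the seasonal flag: November -> 0, December/January -> 1."""
    month = pd.Timestamp(date).month
    if month == 11:
        return 0
    if month in (12, 1):
        return 1
    raise ValueError(f"date {date} falls outside the November-January study window")


def sample_available_locations(used: Point, n: int = 3,
                               min_dist: float = 50.0, max_dist: float = 400.0,
                               seed=None) -> list[Point]:
    """Sample available locations around a used point.

    Distances are uniform on [min_dist, max_dist] (default 50-400 m, the
    upper bound being a 90% movement quantile) and azimuths uniform on
    (0, 360] degrees clockwise from north.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 available locations, got {n}")
    if not (0 < min_dist < max_dist):
        raise ValueError(f"degenerate distance interval [{min_dist}, {max_dist}]")
    rng = np.random.default_rng(seed)
    d = rng.uniform(min_dist, max_dist, size=n)
    az = np.deg2rad(360.0 - rng.uniform(0.0, 360.0, size=n))  # (0, 360] deg
    return [Point(used.x + di * math.sin(a), used.y + di * math.cos(a))
            for di, a in zip(d, az)]


def assemble_choice_sets(rows: pd.DataFrame) -> list[ChoiceSet]:
    """Build validated ChoiceSets from a long table (one row per alternative).

    Required columns: set_id, covey_id, season (or date), used, and the nine
    covariates.  Every malformed group is rejected with an error naming the
    set.  Assembly is lossless: :func:`sets_to_frame` reproduces the input
    rows up to row order.
    """
    missing = [c for c in ("set_id", "covey_id", "used", *COVARIATES)
               if c not in rows.columns]
    if missing:
        raise ValueError(f"choice table is missing columns {missing}")
    if "season" not in rows.columns:
        if "date" not in rows.columns:
            raise ValueError("choice table needs a season or date column")
        rows = rows.assign(season=rows["date"].map(season_from_date))
    sets: list[ChoiceSet] = []
    for set_id, grp in rows.groupby("set_id", sort=False):
        if grp["covey_id"].nunique() != 1 or grp["season"].nunique() != 1:
            raise ValueError(
                f"choice set {set_id!r}: covey_id/season differ within the set")
        alts = []
        for _, r in grp.iterrows():
            alt = Alternative(**{c: float(r[c]) for c in COVARIATES},
                              used=bool(r["used"]))
            try:
                alt.validate()
            except ValueError as err:
                raise ValueError(f"choice set {set_id!r}: {err}") from None
            alts.append(alt)
        sets.append(ChoiceSet(
            set_id=set_id,
            covey_id=grp["covey_id"].iloc[0],
            season=int(grp["season"].iloc[0]),
            date=grp["date"].iloc[0] if "date" in grp.columns else None,
            alternatives=tuple(alts),
        ))
    return sets


def sets_to_frame(sets: list[ChoiceSet]) -> pd.DataFrame:
    """Flatten ChoiceSets back to the long exchange table."""
    records = []
    for cs in sets:
        for alt in cs.alternatives:
            rec = {"set_id": cs.set_id, "covey_id": cs.covey_id,
                   "date": cs.date, "season": cs.season, "used": alt.used}
            rec.update({c: getattr(alt, c) for c in COVARIATES})
            records.append(rec)
    return pd.DataFrame.from_records(records, columns=CSV_COLUMNS)


def read_choice_csv(path) -> list[ChoiceSet]:
    return assemble_choice_sets(pd.read_csv(path))


def write_choice_csv(sets: list[ChoiceSet], path) -> None:
    sets_to_frame(sets).to_csv(path, index=False)


@dataclass(frozen=True)
class StandardizationParams:
    """Pooled mean and sd per term, for transform and back-transform.

    Computed over ALL alternatives (used and available jointly), once over
    the full dataset, so that within-choice-set contrasts stay meaningful.
    The NG_PG entry refers to the raw NG x PG product standardized as its
    own column.
    """

    mean: dict[str, float]
    sd: dict[str, float]

    def transform(self, term: str, x):
        return (np.asarray(x, dtype=float) - self.mean[term]) / self.sd[term]

    def back_transform(self, term: str, z):
        return np.asarray(z, dtype=float) * self.sd[term] + self.mean[term]


def fit_standardization(sets: list[ChoiceSet],
                        terms=ALL_TERMS) -> StandardizationParams:
    """Pooled mean/sd (ddof=1) per term over every alternative."""
    mean, sd = {}, {}
    for term in terms:
        vals = np.array([a.value(term) for cs in sets for a in cs.alternatives])
        s = float(vals.std(ddof=1))
        if not s > 0:
            raise ValueError(f"covariate {term} has zero pooled variance")
        mean[term], sd[term] = float(vals.mean()), s
    return StandardizationParams(mean, sd)


def standardize_covariates(sets: list[ChoiceSet],
                           params: StandardizationParams | None = None,
                           ) -> tuple[list[ChoiceSet], StandardizationParams]:
    """Rescale the nine stored covariates to pooled mean 0, sd 1.

    Returns the transformed sets together with the parameters (fitted on
    ``sets`` when not supplied), including NG_PG parameters for the
    design-matrix pathway.  Standardized sets bypass raw-range validation.
    """
    if params is None:
        params = fit_standardization(sets)
    out = []
    for cs in sets:
        alts = tuple(
            replace(alt, **{c: float(params.transform(c, getattr(alt, c)))
                            for c in COVARIATES})
            for alt in cs.alternatives)
        out.append(replace(cs, alternatives=alts))
    return out, params


def design_matrix(sets: list[ChoiceSet], terms,
                  params: StandardizationParams | None = None) -> np.ndarray:
    """(n_sets, 4, len(terms)) covariate array, standardized when params given.

    NG_PG is always formed from the raw NG x PG product and standardized
    with its own pooled parameters.
    """
    terms = tuple(terms)
    X = np.empty((len(sets), 4, len(terms)))
    for i, cs in enumerate(sets):
        for j, alt in enumerate(cs.alternatives):
            for k, t in enumerate(terms):
                X[i, j, k] = alt.value(t)
    if params is not None:
        for k, t in enumerate(terms):
            X[:, :, k] = params.transform(t, X[:, :, k])
    return X


def vif_screen(sets: list[ChoiceSet], covariate_combo, threshold: float = 2.5):
    """Variance inflation factors over the pooled alternatives table.

    VIF_k = 1 / (1 - R^2_k) from an intercept-included OLS of covariate k on
    the remaining covariates in the combo.  The combo passes iff every VIF
    is below ``threshold``; exact collinearity yields +inf and a fail.
    Returns (pandas Series of VIFs, passed flag).
    """
    import statsmodels.api as sm

    combo = list(covariate_combo)
    if len(combo) < 2:
        raise ValueError("VIF screen needs at least 2 covariates")
    X = design_matrix(sets, combo).reshape(-1, len(combo))
    if X.shape[0] <= len(combo):
        raise ValueError("fewer pooled rows than covariates")
    vifs = {}
    for k, term in enumerate(combo):
        others = sm.add_constant(np.delete(X, k, axis=1))
        r2 = sm.OLS(X[:, k], others).fit().rsquared
        vifs[term] = math.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
    vifs = pd.Series(vifs, name="VIF")
    return vifs, bool(np.all(vifs < threshold))
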