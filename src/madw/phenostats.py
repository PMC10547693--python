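"""Genotype-phenotype association statistics.

The screen's statistical model is a one-way group-means linear model per
locus: trait ~ allele level, treatment-coded against the wildtype level,
with two-sided t-tests on the coefficients (alpha = 0.05).  Residual
normality is checked with Shapiro-Wilk and a Kruskal-Wallis rank-sum test
is run as the non-parametric companion.  A combined multi-locus model is
additive in locus factors with no interactions; aliased (perfectly
confounded) columns are dropped and reported as singularities.

Accessions whose locus status is uncharacterized or heterozygous_carrier
have an ambiguous allele level and are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .errors import ValidationError

DEFAULT_ALPHA = 0.05
EXCLUDED_STATUSES = {"uncharacterized", "heterozygous_carrier"}


@dataclass
class AssociationResult:
    locus: str
    trait: str
    reference_level: str
    n_per_level: dict[str, int]
    coefficients: pd.DataFrame  # level, estimate, se, t, p
    dropped_levels: list[str] = field(default_factory=list)
    shapiro_w: Optional[float] = None
    shapiro_p: Optional[float] = None
    kruskal_h: Optional[float] = None
    kruskal_df: Optional[int] = None
    kruskal_p: Optional[float] = None
    alpha: float = DEFAULT_ALPHA

    def significant_levels(self) -> list[str]:
        sig = self.coefficients[self.coefficients["p"] < self.alpha]
        return list(sig["level"])

    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "trait": self.trait,
            "reference_level": self.reference_level,
            "n_per_level": self.n_per_level,
            "coefficients": self.coefficients.to_dict(orient="records"),
            "dropped_levels": self.dropped_levels,
            "shapiro": {"W": self.shapiro_w, "p": self.shapiro_p},
            "kruskal": {
                "H": self.kruskal_h,
                "df": self.kruskal_df,
                "p": self.kruskal_p,
            },
            "alpha": self.alpha,
        }


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; W is location/scale invariant."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValidationError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with mid-ranks and tie correction; p from chi-square.

    Returns (H, df, p) with df = k - 1.  All-identical values raise: the
    statistic is undefined after tie correction.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [a[~np.isnan(a)] for a in arrays]
    arrays = [a for a in arrays if a.size > 0]
    if len(arrays) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 non-empty groups")
    if sum(a.size for a in arrays) < 3:
        raise ValidationError("Kruskal-Wallis needs total n >= 3")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        raise ValidationError(
            "Kruskal-Wallis undefined: all values identical (tie correction is zero)"
        )
    try:
        h, p = sps.kruskal(*arrays)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc
    return float(h), len(arrays) - 1, float(p)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns accession, trait, value[, unit]."""
    df = pd.read_csv(path, sep="\t")
    needed = {"accession", "trait", "value"}
    if not needed <= set(df.columns):
        raise ValidationError(f"{path}: phenotype TSV needs columns {sorted(needed)}")
    return df


def fit_allele_means(
    values: Sequence[float],
    alleles: Sequence[str],
    locus: str = "",
    trait: str = "",
    reference: str = "wildtype",
    alpha: float = DEFAULT_ALPHA,
) -> AssociationResult:
    """One-way group-means model with treatment coding against `reference`.

    Missing trait values are dropped; levels left with zero observations are
    reported as singularities.  Needs >= 2 usable levels with >= 2
    observations each.
    """
    df = pd.DataFrame({"value": values, "allele": alleles}).dropna(subset=["value"])
    counts = df["allele"].value_counts().to_dict()
    usable = {lvl for lvl, n in counts.items() if n >= 2}
    dropped = sorted(set(alleles) - usable)
    df = df[df["allele"].isin(usable)]
    if len(usable) < 2:
        raise ValidationError(
            f"{locus or 'locus'}: need >= 2 allele levels with >= 2 observations, "
            f"got {sorted(usable)}"
        )
    if reference not in usable:
        reference = df["allele"].value_counts().idxmax()

    levels = [reference] + sorted(l for l in usable if l != reference)
    design = pd.get_dummies(
        pd.Categorical(df["allele"], categories=levels), drop_first=True, dtype=float
    )
    design.insert(0, "Intercept", 1.0)
    fit = sm.OLS(df["value"].to_numpy(), design.to_numpy()).fit()

    rows = []
    names = list(design.columns)
    for i, name in enumerate(names):
        level = reference if name == "Intercept" else str(name)
        rows.append(
            {
                "level": level,
                "estimate": float(fit.params[i]),
                "se": float(fit.bse[i]),
                "t": float(fit.tvalues[i]),
                "p": float(fit.pvalues[i]),
            }
        )
    coef = pd.DataFrame(rows)

    resid = np.asarray(fit.resid, dtype=float)
    shapiro_w = shapiro_p = None
    if resid.size >= 3 and np.ptp(resid) > 0:
        shapiro_w, shapiro_p = shapiro_wilk(resid)
    groups = [g["value"].to_numpy() for _, g in df.groupby("allele")]
    kh = kdf = kp = None
    try:
        kh, kdf, kp = kruskal_wallis(groups)
    except ValidationError:
        pass

    return AssociationResult(
        locus=locus,
        trait=trait,
        reference_level=reference,
        n_per_level={str(l): int(counts.get(l, 0)) for l in levels},
        coefficients=coef,
        dropped_levels=dropped,
        shapiro_w=shapiro_w,
        shapiro_p=shapiro_p,
        kruskal_h=kh,
        kruskal_df=kdf,
        kruskal_p=kp,
        alpha=alpha,
    )


def fit_multi_locus(
    values: Sequence[float],
    locus_alleles: Mapping[str, Sequence[str]],
    trait: str = "",
    reference: str = "wildtype",
    alpha: float = DEFAULT_ALPHA,
) -> AssociationResult:
    """Additive multi-locus model: trait ~ sum of locus factors, no interactions.

    Aliased columns (perfectly confounded across loci) are detected by QR
    and dropped with a singularity report, and the reduced model is refit.
    """
    df = pd.DataFrame({"value": values})
    for locus, alleles in locus_alleles.items():
        df[locus] = list(alleles)
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValidationError("no usable observations")

    design = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for locus in locus_alleles:
        lvls = sorted(df[locus].unique())
        ref = reference if reference in lvls else lvls[0]
        ordered = [ref] + [l for l in lvls if l != ref]
        dummies = pd.get_dummies(
            pd.Categorical(df[locus], categories=ordered), drop_first=True, dtype=float
        )
        dummies.columns = [f"{locus}[{c}]" for c in dummies.columns]
        dummies.index = df.index
        design = pd.concat([design, dummies], axis=1)

    x = design.to_numpy()
    _q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    keep = diag > tol
    aliased = [c for c, k in zip(design.columns, keep) if not k]
    design = design.loc[:, keep]

    fit = sm.OLS(df["value"].to_numpy(), design.to_numpy()).fit()
    rows = []
    for i, name in enumerate(design.columns):
        rows.append(
            {
                "level": str(name),
                "estimate": float(fit.params[i]),
                "se": float(fit.bse[i]),
                "t": float(fit.tvalues[i]),
                "p": float(fit.pvalues[i]),
            }
        )
    resid = np.asarray(fit.resid, dtype=float)
    shapiro_w = shapiro_p = None
    if resid.size >= 3 and np.ptp(resid) > 0:
        shapiro_w, shapiro_p = shapiro_wilk(resid)
    n_per = {}
    for locus in locus_alleles:
        for lvl, n in df[locus].value_counts().items():
            n_per[f"{locus}[{lvl}]"] = int(n)
    return AssociationResult(
        locus="+".join(locus_alleles),
        trait=trait,
        reference_level=reference,
        n_per_level=n_per,
        coefficients=pd.DataFrame(rows),
        dropped_levels=aliased,
        shapiro_w=shapiro_w,
        shapiro_p=shapiro_p,
        alpha=alpha,
    )


def allele_levels_from_calls(
    calls,  # Iterable[LocusCall]
    locus: str,
    exclude_statuses: set[str] = EXCLUDED_STATUSES,
) -> dict[str, str]:
    """Map accession -> allele level for one locus.

    named -> the matched allele name(s, joined by '+'); novel_deleterious ->
    'novel'; wildtype -> 'wildtype'.  Ambiguous statuses are excluded.
    """
    out = {}
    for c in calls:
        if c.locus != locus or c.status in exclude_statuses:
            continue
        if c.status == "named":
            out[c.accession] = "+".join(c.matched_alleles)
        elif c.status == "novel_deleterious":
            out[c.accession] = "novel"
        elif c.status == "wildtype":
            out[c.accession] = "wildtype"
    return out
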