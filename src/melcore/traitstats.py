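"""Morphological diversity statistics.

Implements the quantitative-trait side of a germplasm diversity
assessment: coefficient of variation, Shannon diversity H' on binned
continuous traits, one-way random-effects variance components for
unbalanced species designs, and the phenotypic differentiation
coefficient

    Pst = sigma2_among / (sigma2_among + sigma2_within),

the phenotypic analogue of Qst/Fst, with species labels playing the role
of populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from melcore.containers import TraitMatrix
from melcore.errors import InsufficientDataError, UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """One-way random-effects ANOVA decomposition of a trait.

    ``sigma2_among`` is the among-species component (clamped at zero when
    the method-of-moments estimate is negative), ``sigma2_within`` the
    pooled within-species variance, ``n0`` the effective per-group size
    for unbalanced designs (Sokal & Rohlf).
    """

    sigma2_among: float
    sigma2_within: float
    f_statistic: float
    p_value: float
    n0: float
    df_among: int
    df_within: int


def coefficient_of_variation(values) -> float:
    """Sample CV: sd (n-1 denominator) over mean.

    Raises
    ------
    InsufficientDataError
        For fewer than two observations.
    UndefinedStatisticError
        For a zero mean, where CV is not defined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"CV needs >=2 values, got {x.size}")
    mean = x.mean()
    if mean == 0.0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def bin_values(values, n_classes: int = 10, method: str = "sigma") -> np.ndarray:
    """Assign continuous values to phenotype classes.

    ``method="sigma"`` (default, the germplasm-diversity convention):
    classes are defined on standardized values z = (x - mean)/sd; the
    lowest class is z < -2, the highest z >= +2, and the remaining
    ``n_classes - 2`` classes partition [-2, 2) into equal widths (for the
    default 10 classes the interior width is 0.5 sd). Constant input maps
    everything to one class.

    ``method="equal"``: ``n_classes`` equal-width bins between min and max.

    Returns zero-based class indices.
    """
    x = np.asarray(values, dtype=float)
    if n_classes < 2:
        raise UndefinedStatisticError("need at least 2 phenotype classes")
    if method == "sigma":
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0.0:
            return np.zeros(x.size, dtype=int)
        z = (x - x.mean()) / sd
        edges = np.linspace(-2.0, 2.0, n_classes - 1)
        return np.searchsorted(edges, z, side="right")
    if method == "equal":
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros(x.size, dtype=int)
        edges = np.linspace(lo, hi, n_classes + 1)[1:-1]
        return np.searchsorted(edges, x, side="right")
    raise UndefinedStatisticError(f"unknown binning method {method!r}")


def shannon_from_counts(counts) -> float:
    """H' = -sum p_i ln p_i over non-empty classes, in nats."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise InsufficientDataError("no occupied classes")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def shannon_index(values, n_classes: int = 10, method: str = "sigma") -> float:
    """Shannon diversity of a quantitative trait over phenotype classes.

    Values are binned (see :func:`bin_values`), then
    H' = -sum p_i ln p_i over the occupied classes. Bounded by
    ln(n_classes); 0 for constant input (single occupied class).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"Shannon index needs >=2 values, got {x.size}")
    classes = bin_values(x, n_classes=n_classes, method=method)
    counts = np.bincount(classes)
    if (counts > 0).sum() == 1:
        logger.info("constant or single-class input: H' = 0")
        return 0.0
    return shannon_from_counts(counts)


def variance_components(values, partition) -> VarianceComponents:
    """One-way random-effects ANOVA of a trait over species groups.

    MS_within = SS_within/(N-k), MS_among = SS_among/(k-1);
    sigma2_within = MS_within and
    sigma2_among = max(0, (MS_among - MS_within)/n0) with
    n0 = (N - sum n_i^2 / N)/(k-1). F = MS_among/MS_within with the
    p-value from F(k-1, N-k).
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(partition)
    if x.size != labels.size:
        raise InsufficientDataError("values and partition differ in length")
    groups = [x[labels == g] for g in pd.unique(labels)]
    k = len(groups)
    n_total = x.size
    if k < 2:
        raise InsufficientDataError(f"need >=2 groups, got {k}")
    if max(len(g) for g in groups) < 2:
        raise InsufficientDataError("all groups are singletons; no within-group variance")
    grand = x.mean()
    sizes = np.array([len(g) for g in groups], dtype=float)
    ss_among = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_among = k - 1
    df_within = n_total - k
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n_total - (sizes**2).sum() / n_total) / df_among
    sigma2_among = max(0.0, (ms_among - ms_within) / n0)
    if ms_within > 0:
        f_stat = ms_among / ms_within
        p = float(stats.f.sf(f_stat, df_among, df_within))
    else:
        f_stat = np.inf if ms_among > 0 else np.nan
        p = 0.0 if ms_among > 0 else np.nan
    return VarianceComponents(
        sigma2_among=sigma2_among,
        sigma2_within=ms_within,
        f_statistic=float(f_stat),
        p_value=p,
        n0=float(n0),
        df_among=df_among,
        df_within=df_within,
    )


def pst(values, partition) -> float:
    """Phenotypic differentiation coefficient of one trait across species.

    Pst = sigma2_among/(sigma2_among + sigma2_within) from the one-way
    random-effects decomposition; 0 when the among component clamps to
    zero, 1 only for zero within-species variance.
    """
    vc = variance_components(values, partition)
    denom = vc.sigma2_among + vc.sigma2_within
    if denom == 0.0:
        raise UndefinedStatisticError("Pst undefined: trait constant everywhere")
    return float(vc.sigma2_among / denom)


def trait_summary(
    tm: TraitMatrix, n_classes: int = 10, binning: str = "sigma"
) -> dict[str, pd.DataFrame]:
    """Per-species and per-trait diversity summary of a collection.

    Returns two tables. ``per_species`` has one row per species x trait
    plus an "ALL" row per trait, with n, mean, sd, CV, min, max (sd and
    CV are NaN for singleton species). ``per_trait`` carries the
    across-collection diversity numbers: Shannon H' over accessions, the
    among-species CV computed over species means, the ANOVA F and
    p-value, and Pst — provided the collection has at least two species.
    """
    species = tm.species_labels
    rows = []
    for trait in tm.trait_names:
        col = tm.trait(trait)
        for sp in species:
            vals = col[np.asarray(tm.species) == sp]
            n = vals.size
            sd = float(vals.std(ddof=1)) if n > 1 else np.nan
            mean = float(vals.mean())
            cv = sd / mean if n > 1 and mean != 0 else np.nan
            rows.append(
                dict(species=sp, trait=trait, n=n, mean=mean, sd=sd, cv=cv,
                     min=float(vals.min()), max=float(vals.max()))
            )
        rows.append(
            dict(species="ALL", trait=trait, n=col.size, mean=float(col.mean()),
                 sd=float(col.std(ddof=1)), cv=coefficient_of_variation(col),
                 min=float(col.min()), max=float(col.max()))
        )
    per_species = pd.DataFrame(rows)

    trait_rows = []
    multi = len(species) > 1
    for trait in tm.trait_names:
        col = tm.trait(trait)
        entry: dict[str, object] = dict(trait=trait)
        entry["shannon_h"] = shannon_index(col, n_classes=n_classes, method=binning)
        if multi:
            sp_means = np.array(
                [col[np.asarray(tm.species) == sp].mean() for sp in species]
            )
            entry["among_species_cv"] = coefficient_of_variation(sp_means)
            try:
                vc = variance_components(col, tm.species)
                entry["f_statistic"] = vc.f_statistic
                entry["p_value"] = vc.p_value
                entry["pst"] = pst(col, tm.species)
            except (InsufficientDataError, UndefinedStatisticError) as exc:
                logger.warning("trait %s: %s", trait, exc)
                entry.update(f_statistic=np.nan, p_value=np.nan, pst=np.nan)
        trait_rows.append(entry)
    return {"per_species": per_species, "per_trait": pd.DataFrame(trait_rows)}
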