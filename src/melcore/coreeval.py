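"""Core-versus-initial evaluation.

Four standard percentages summarize how faithfully a core collection
represents the initial collection over m evaluated traits:

* MD% — share of traits whose core and initial means differ
  significantly (two-sample t-test, alpha = 0.05 by default);
* VD% — share of traits whose variances differ significantly (F-test);
* CR% — coincidence rate of range: mean per-trait ratio of core range to
  initial range, times 100 (<= 100 always, = 100 iff every per-trait
  extreme is retained);
* VR% — changeable rate of CV: mean per-trait ratio of core CV to
  initial CV, times 100 (> 100 means the core is relatively more
  variable, the expected signature of removing near-duplicates).

A Table-style diversity comparison (Shannon H' per trait, Hd and pi per
locus) and a strategy-by-proportion sweep complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from melcore import coreselect, seqdiv, traitstats
from melcore.containers import Alignment, CoreSet, TraitMatrix
from melcore.errors import InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

#: Trait subset used by default for evaluation tables; the three seed
#: traits whose diversity is tracked locus-by-locus in the comparison
#: tables. Falls back to all traits when a matrix lacks these columns.
DEFAULT_EVAL_TRAITS = ("width_length_ratio", "circumference", "hundred_seed_weight")


@dataclass
class EvalReport:
    """MD/VD/CR/VR percentages plus per-trait detail."""

    md_percent: float
    vd_percent: float
    cr_percent: float
    vr_percent: float
    alpha: float
    n_traits: int
    per_trait: pd.DataFrame = field(repr=False, default=None)


def _eval_traits(tm: TraitMatrix, traits) -> list[str]:
    if traits:
        missing = [t for t in traits if t not in tm.trait_names]
        if missing:
            raise ParameterError(f"unknown evaluation traits: {missing}")
        return list(traits)
    if all(t in tm.trait_names for t in DEFAULT_EVAL_TRAITS):
        return list(DEFAULT_EVAL_TRAITS)
    return list(tm.trait_names)


def _variance_f_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test for equality of variances."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 and va == 0:
        return np.nan, 1.0
    if vb == 0 or va == 0:
        return np.inf, 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2 * min(stats.f.sf(f, dfa, dfb), stats.f.cdf(f, dfa, dfb))
    return float(f), float(min(1.0, p))


def evaluate_core(
    tm: TraitMatrix,
    core: CoreSet,
    traits: list[str] | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> EvalReport:
    """Compare a core set with its initial collection trait by trait.

    Per trait: a two-sample t-test of means (pooled variance by default,
    Welch with ``welch=True``) and a two-sided F-test of variances, both
    at level ``alpha``; then MD% and VD% count significant tests, CR%
    averages range ratios and VR% averages CV ratios. A trait with zero
    initial range or CV is excluded with a warning and m decremented.
    """
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if core.size < 2:
        raise InsufficientDataError("core must contain >= 2 accessions to evaluate")
    missing = set(core.accession_ids) - set(tm.accession_ids)
    if missing:
        raise ParameterError(f"core accessions absent from collection: {sorted(missing)}")
    names = _eval_traits(tm, traits)
    sub = tm.subset(core.accession_ids)

    rows = []
    for t in names:
        init, cor = tm.trait(t), sub.trait(t)
        rng_init = init.max() - init.min()
        cv_init = init.std(ddof=1) / init.mean() if init.mean() != 0 else 0.0
        if rng_init == 0 or cv_init == 0:
            logger.warning("trait %s has zero initial range or CV; excluded", t)
            continue
        t_stat, t_p = stats.ttest_ind(cor, init, equal_var=not welch)
        f_stat, f_p = _variance_f_test(cor, init)
        rows.append(
            dict(
                trait=t,
                mean_initial=init.mean(), mean_core=cor.mean(),
                var_initial=init.var(ddof=1), var_core=cor.var(ddof=1),
                range_initial=rng_init, range_core=cor.max() - cor.min(),
                cv_initial=cv_init, cv_core=cor.std(ddof=1) / cor.mean(),
                t_statistic=float(t_stat), t_p=float(t_p),
                f_statistic=f_stat, f_p=f_p,
                mean_significant=bool(t_p < alpha),
                var_significant=bool(f_p < alpha),
            )
        )
    if not rows:
        raise InsufficientDataError("no evaluable traits (all zero range or CV)")
    per_trait = pd.DataFrame(rows)
    m = len(per_trait)
    return EvalReport(
        md_percent=100.0 * per_trait["mean_significant"].sum() / m,
        vd_percent=100.0 * per_trait["var_significant"].sum() / m,
        cr_percent=float(100.0 / m * (per_trait["range_core"] / per_trait["range_initial"]).sum()),
        vr_percent=float(100.0 / m * (per_trait["cv_core"] / per_trait["cv_initial"]).sum()),
        alpha=alpha,
        n_traits=m,
        per_trait=per_trait,
    )


def diversity_comparison(
    tm: TraitMatrix,
    alignments: dict[str, Alignment],
    core: CoreSet,
    n_classes: int = 10,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Shannon H' per trait and Hd/pi per locus, core versus initial.

    Core accessions missing from an alignment are dropped with a
    warning; a locus whose core subset holds fewer than two sequences is
    skipped for that subset. Loci are never pooled.
    """
    names = _eval_traits(tm, traits)
    out = []
    for subset_name, ids in (("initial", tm.accession_ids), ("core", core.accession_ids)):
        row: dict[str, object] = {"subset": subset_name, "n": len(ids)}
        sub = tm.subset(ids)
        for t in names:
            row[f"H_{t}"] = traitstats.shannon_index(sub.trait(t), n_classes=n_classes)
        for locus, aln in alignments.items():
            present = [a for a in ids if a in set(aln.accession_ids)]
            if len(present) < len(ids):
                logger.warning(
                    "%s/%s: %d accessions absent from alignment, dropped",
                    subset_name, locus, len(ids) - len(present),
                )
            if len(present) < 2:
                logger.warning("%s/%s: <2 sequences, locus skipped", subset_name, locus)
                row[f"Hd_{locus}"] = np.nan
                row[f"pi_{locus}"] = np.nan
                continue
            sub_aln = aln.subset(present)
            row[f"Hd_{locus}"] = seqdiv.haplotype_diversity(seqdiv.haplotype_spectrum(sub_aln))
            row[f"pi_{locus}"] = seqdiv.nucleotide_diversity(sub_aln)
        out.append(row)
    return pd.DataFrame(out)


def proportion_sweep(
    tm: TraitMatrix,
    alignments: dict[str, Alignment] | None,
    proportions: list[float],
    strategies: list[str] = ("random", "preferred"),
    seeds: list[int] = (0,),
    traits_select: list[str] | None = None,
    traits_eval: list[str] | None = None,
    alpha: float = 0.05,
    n_classes: int = 10,
) -> pd.DataFrame:
    """Build and evaluate cores for every strategy x proportion (x seed).

    Returns one row per run with MD/VD/CR/VR and, when alignments are
    given, the diversity-comparison columns for the core subset. The
    preferred strategy is deterministic, so it runs once per proportion.
    """
    rows = []
    for strategy in strategies:
        run_seeds = list(seeds) if strategy == "random" else [None]
        for proportion in proportions:
            for seed in run_seeds:
                core = coreselect.stepwise_core(
                    tm, proportion, strategy=strategy, seed=seed, traits=traits_select
                )
                rep = evaluate_core(tm, core, traits=traits_eval, alpha=alpha)
                row = dict(
                    strategy=strategy,
                    proportion=proportion,
                    seed=seed,
                    core_size=core.size,
                    rounds=core.rounds,
                    truncated=core.truncated,
                    md_percent=rep.md_percent,
                    vd_percent=rep.vd_percent,
                    cr_percent=rep.cr_percent,
                    vr_percent=rep.vr_percent,
                )
                if alignments:
                    div = diversity_comparison(
                        tm, alignments, core, n_classes=n_classes, traits=traits_eval
                    )
                    core_row = div[div["subset"] == "core"].iloc[0]
                    for col in div.columns:
                        if col not in ("subset", "n"):
                            row[col] = core_row[col]
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of the evaluation percentages over seeds per cell."""
    metrics = [c for c in ("md_percent", "vd_percent", "cr_percent", "vr_percent")
               if c in sweep.columns]
    g = sweep.groupby(["strategy", "proportion"])[metrics]
    agg = g.agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
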