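"""Longitudinal and histology statistics for the loading study.

CoF analysis: a Gaussian linear mixed model on the natural log of the
3-trial mean CoF with a random intercept per animal (both limbs of a pair
share the animal).  Because control limbs are measured only at the two
wall-clock times shared with the experimental schedule, a free limb x time
interaction is not identifiable; the fixed effects are therefore
parameterised cell-means style as genotype crossed with the measurement
condition (limb@wall-clock-hour), which saturates every observed
genotype x limb x time cell and contains the identifiable parts of the
limb, time and interaction effects.  Reported effect tests are Wald
chi-square tests of marginal-mean contrasts: genotype (averaged over
conditions), time (within the experimental limb, averaged over genotypes)
and limb (at the shared times, averaged over genotypes), plus the
genotype x condition interaction.  Genotype contrasts at named design
points (baseline and final time, experimental limb by default) are Wald
t-tests with ``df = n_animals - n_genotypes`` (between-animal contrasts).

Histology: per-joint aggregation (plateau means per category, categories
summed to a 0-11 total), classical two-way ANOVA (genotype x treatment,
with interaction) per category and total, and a Spearman rank correlation
between final CoF and total histology score (the scores are ordinal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .study import CATEGORY_MAXIMA, HISTOLOGY_CATEGORIES, StudyDataset

__all__ = [
    "HistologyScore",
    "EffectsTable",
    "aggregate_histology",
    "aggregate_joint_scores",
    "fit_cof_mixed_model",
    "anova_histology",
    "correlate_cof_histology",
]

MAX_TOTAL_SCORE = sum(CATEGORY_MAXIMA.values())  # 11


@dataclass
class HistologyScore:
    """Per-joint scores after plateau averaging; total = structure + surface + safranin."""

    structure: float
    surface: float
    safranin: float

    @property
    def total(self) -> float:
        return self.structure + self.surface + self.safranin


@dataclass
class EffectsTable:
    """Mixed-model fixed-effect tests, contrasts and variance components."""

    fixed_effects: pd.DataFrame  # term, wald chi2, df, p
    contrasts: pd.DataFrame  # label, estimate (log-CoF), se, t, df, p
    animal_variance: float
    residual_variance: float
    alpha: float = 0.05
    singular: bool = False
    converged: bool = True


def aggregate_histology(plateau_scores: dict[str, list[float]]) -> HistologyScore:
    """Average the plateau scores per category and sum the category means.

    ``plateau_scores`` maps each category to its (usually two) plateau
    scores.  A single plateau is accepted with a warning; scores outside a
    category's range raise a validation error.  With all categories at their
    ceilings (4, 3, 4 on both plateaus) the total is exactly 11.
    """
    values = {}
    for category in HISTOLOGY_CATEGORIES:
        if category not in plateau_scores:
            raise ValueError(f"missing category {category!r}")
        scores = np.atleast_1d(np.asarray(plateau_scores[category], dtype=float))
        if len(scores) == 0:
            raise ValueError(f"no plateau scores for {category!r}")
        if len(scores) == 1:
            warnings.warn(f"only one plateau score for {category!r}; using it as-is", stacklevel=2)
        hi = CATEGORY_MAXIMA[category]
        if np.any(scores < 0) or np.any(scores > hi):
            raise ValueError(f"{category!r} score outside [0, {hi}]: {scores.tolist()}")
        values[category] = float(scores.mean())
    return HistologyScore(**values)


def aggregate_joint_scores(histology: pd.DataFrame) -> pd.DataFrame:
    """Per-joint wide table of aggregated category scores and the total."""
    rows = []
    for (animal_id, genotype, limb), grp in histology.groupby(
        ["animal_id", "genotype", "limb"], sort=False
    ):
        per_cat = {
            cat: grp.loc[grp["category"] == cat, "score"].tolist()
            for cat in HISTOLOGY_CATEGORIES
        }
        agg = aggregate_histology(per_cat)
        rows.append(
            (animal_id, genotype, limb, agg.structure, agg.surface, agg.safranin, agg.total)
        )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "genotype", "limb", "structure", "surface", "safranin", "total"],
    )


def _collapse_trials(cof: pd.DataFrame) -> pd.DataFrame:
    if (cof["cof"] <= 0).any():
        raise ValueError("non-positive CoF values cannot be log-transformed")
    keys = ["animal_id", "genotype", "limb", "timepoint_id", "cumulative_loading_h", "wallclock_h"]
    out = cof.groupby(keys, as_index=False)["cof"].mean()
    out["log_cof"] = np.log(out["cof"])
    out["time_h"] = out["wallclock_h"].round(6)
    out["condition"] = out["limb"] + "@" + out["time_h"].map("{:g}".format)
    return out


def fit_cof_mixed_model(
    dataset: StudyDataset | pd.DataFrame,
    alpha: float = 0.05,
    contrast_limb: str = "experimental",
) -> EffectsTable:
    """Fit the log-CoF mixed model and report effect tests and contrasts.

    The response is the natural log of the per-measurement 3-trial mean CoF.
    Contrasts reported: each genotype pair at the first (baseline) and last
    wall-clock time on ``contrast_limb``, unadjusted at the stated alpha.
    A fit with (near-)zero animal variance proceeds with ``singular=True``.
    """
    cof = dataset.cof if isinstance(dataset, StudyDataset) else dataset
    if cof["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    if cof["limb"].nunique() < 2 or cof["wallclock_h"].nunique() < 2:
        raise ValueError("need both limbs and >= 2 time points")
    df = _collapse_trials(cof)

    formula = "log_cof ~ C(genotype) * C(condition)"
    zero_var = df.groupby("animal_id")["log_cof"].var().fillna(0.0).max() < 1e-14
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["animal_id"])
        try:
            result = model.fit(method="lbfgs", reml=True, maxiter=200)
            converged = bool(getattr(result, "converged", True))
        except Exception:
            result = model.fit(method="powell", reml=True, maxiter=500)
            converged = bool(getattr(result, "converged", True))

    resid_var = float(result.scale)
    animal_var = float(np.asarray(result.cov_re).ravel()[0]) if np.asarray(result.cov_re).size else 0.0
    singular = zero_var or animal_var < 1e-8 * max(resid_var, 1e-30)
    if singular:
        warnings.warn("animal variance component is (near) zero; singular fit", stacklevel=2)

    fe = result.fe_params
    cov = np.asarray(result.cov_params())[: len(fe), : len(fe)]
    design_info = model.data.design_info
    genotypes = sorted(df["genotype"].unique())

    def _design_row(genotype: str, condition: str) -> np.ndarray:
        (mat,) = build_design_matrices(
            [design_info], {"genotype": [genotype], "condition": [condition]}
        )
        return np.asarray(mat)[0]

    def _wald(L: np.ndarray) -> tuple[float, int, float]:
        L = np.atleast_2d(L)
        est = L @ fe.to_numpy()
        V = L @ cov @ L.T
        try:
            stat = float(est @ np.linalg.solve(V, est))
        except np.linalg.LinAlgError:
            return float("nan"), L.shape[0], float("nan")
        return stat, L.shape[0], float(sps.chi2.sf(stat, L.shape[0]))

    conditions = sorted(df["condition"].unique())
    exp_conditions = sorted(
        df.loc[df["limb"] == "experimental", "condition"].unique(),
        key=lambda c: float(c.split("@")[1]),
    )
    shared_times = sorted(
        set(df.loc[df["limb"] == "experimental", "time_h"]).intersection(
            df.loc[df["limb"] == "control", "time_h"]
        )
    )

    def _avg_over_genotypes(condition: str) -> np.ndarray:
        return np.mean([_design_row(g, condition) for g in genotypes], axis=0)

    terms: list[tuple[str, float, int, float]] = []
    # genotype: pairwise vs reference, averaged over all observed conditions
    L_geno = np.array(
        [
            np.mean([_design_row(g, c) - _design_row(genotypes[0], c) for c in conditions], axis=0)
            for g in genotypes[1:]
        ]
    )
    terms.append(("genotype", *_wald(L_geno)))
    # time: experimental-limb condition means vs baseline, averaged over genotypes
    if len(exp_conditions) > 1:
        L_time = np.array(
            [
                _avg_over_genotypes(c) - _avg_over_genotypes(exp_conditions[0])
                for c in exp_conditions[1:]
            ]
        )
        terms.append(("time (experimental limb)", *_wald(L_time)))
    # limb: experimental vs control at the shared times, averaged over genotypes
    if shared_times:
        L_limb = np.mean(
            [
                _avg_over_genotypes(f"experimental@{t:g}") - _avg_over_genotypes(f"control@{t:g}")
                for t in shared_times
            ],
            axis=0,
        )
        terms.append(("limb (shared times)", *_wald(L_limb)))
    # genotype x condition interaction: the raw model term
    sl = design_info.term_name_slices["C(genotype):C(condition)"]
    idx = np.arange(len(fe))[sl]
    L_int = np.zeros((len(idx), len(fe)))
    L_int[np.arange(len(idx)), idx] = 1.0
    terms.append(("genotype x condition", *_wald(L_int)))
    fixed_effects = pd.DataFrame(terms, columns=["term", "wald_chi2", "df", "p_value"])

    n_animals = df["animal_id"].nunique()
    t_df = max(n_animals - len(genotypes), 1)
    times = sorted(df.loc[df["limb"] == contrast_limb, "time_h"].unique())
    rows = []
    for time_label, time_h in (("baseline", times[0]), ("final", times[-1])):
        condition = f"{contrast_limb}@{time_h:g}"
        for i in range(len(genotypes)):
            for j in range(i + 1, len(genotypes)):
                L = _design_row(genotypes[j], condition) - _design_row(genotypes[i], condition)
                est = float(L @ fe.to_numpy())
                se = float(np.sqrt(L @ cov @ L))
                tval = est / se if se > 0 else float("nan")
                p = 2.0 * float(sps.t.sf(abs(tval), t_df))
                rows.append(
                    (
                        f"{genotypes[j]} vs {genotypes[i]} @ {time_label}",
                        time_h,
                        est,
                        se,
                        tval,
                        t_df,
                        p,
                    )
                )
    contrasts = pd.DataFrame(
        rows, columns=["label", "time_h", "estimate", "se", "t", "df", "p_value"]
    )

    return EffectsTable(
        fixed_effects=fixed_effects,
        contrasts=contrasts,
        animal_variance=animal_var,
        residual_variance=resid_var,
        alpha=alpha,
        singular=singular,
        converged=converged,
    )


def anova_histology(
    joint_scores: pd.DataFrame,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Two-way ANOVA (genotype x treatment, with interaction) per category and total.

    ``joint_scores`` is the per-joint wide table from
    :func:`aggregate_joint_scores`.  Returns, per response, the ANOVA table
    and the cell means +/- SD in genotype x treatment layout.  Empty cells
    and designs without residual degrees of freedom raise errors.
    """
    responses = list(HISTOLOGY_CATEGORIES) + ["total"]
    counts = joint_scores.groupby(["genotype", "limb"]).size()
    for genotype in joint_scores["genotype"].unique():
        for limb in joint_scores["limb"].unique():
            if (genotype, limb) not in counts.index:
                raise ValueError(f"empty cell: genotype={genotype!r}, limb={limb!r}")
    if (counts <= 1).all():
        raise ValueError("single-replicate cells cannot support an interaction model")
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for resp in responses:
        model = smf.ols(f"{resp} ~ C(genotype) * C(limb)", data=joint_scores).fit()
        if model.df_resid <= 0:
            raise ValueError(f"no residual degrees of freedom for {resp!r}")
        table = sm.stats.anova_lm(model, typ=2)
        cells = (
            joint_scores.groupby(["genotype", "limb"])[resp]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        out[resp] = {"anova": table, "cells": cells}
    return out


def correlate_cof_histology(
    dataset: StudyDataset,
    joint_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Spearman correlation of final per-joint CoF against total histology score.

    Reported overall and within each genotype; a constant input yields an
    undefined correlation flagged with ``constant=True``.
    """
    if joint_scores is None:
        joint_scores = aggregate_joint_scores(dataset.histology)
    cof = dataset.cof
    final = (
        cof.loc[cof.groupby(["animal_id", "limb"])["wallclock_h"].transform("max") == cof["wallclock_h"]]
        .groupby(["animal_id", "genotype", "limb"], as_index=False)["cof"]
        .mean()
        .rename(columns={"cof": "final_cof"})
    )
    merged = final.merge(joint_scores[["animal_id", "limb", "total"]], on=["animal_id", "limb"])
    if len(merged) < 3:
        raise ValueError("need at least 3 joints for a correlation")

    def _spearman(sub: pd.DataFrame, label: str):
        constant = sub["final_cof"].nunique() < 2 or sub["total"].nunique() < 2
        if constant:
            return (label, len(sub), float("nan"), float("nan"), True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = sps.spearmanr(sub["final_cof"], sub["total"])
        return (label, len(sub), float(rho), float(p), False)

    rows = [_spearman(merged, "overall")]
    for genotype, sub in merged.groupby("genotype", sort=True):
        if len(sub) >= 3:
            rows.append(_spearman(sub, str(genotype)))
    return pd.DataFrame(rows, columns=["group", "n", "rho", "p_value", "constant"])
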