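"""Statistical stage: aggregation, mixed model, ANOVA, correlation."""

import numpy as np
import pandas as pd
import pytest

from jointcof.stats import (
    aggregate_histology,
    aggregate_joint_scores,
    anova_histology,
    correlate_cof_histology,
    fit_cof_mixed_model,
)
from jointcof.study import (
    GenotypeProfile,
    StudyDesign,
    default_profiles,
    generate_study,
)


def _null_profiles(cv=0.2, trial_frac=0.1):
    """All genotypes share the wild-type trajectory (no genotype effect)."""
    base = default_profiles()["Prg4+/+"]
    shared = GenotypeProfile(
        baseline_mean=base.baseline_mean,
        baseline_sd=base.baseline_sd,
        final_mean=base.final_mean,
        final_sd=base.final_sd,
        onset_hours=base.onset_hours,
        animal_cv=cv,
        trial_sd=trial_frac * base.baseline_mean,
    )
    return {g: shared for g in default_profiles()}


REDUCED_DESIGN = StudyDesign(
    experimental_timepoints=[(0.0, 0.0), (2.0, 2.0), (2.0, 14.0), (26.0, 38.0)],
)


class TestAggregation:
    def test_ceiling_totals_eleven(self):
        agg = aggregate_histology(
            {"structure": [4, 4], "surface": [3, 3], "safranin": [4, 4]}
        )
        assert agg.total == 11.0

    def test_all_zero_totals_zero(self):
        agg = aggregate_histology({"structure": [0, 0], "surface": [0, 0], "safranin": [0, 0]})
        assert agg.total == 0.0

    def test_plateau_means_and_sum(self):
        agg = aggregate_histology(
            {"structure": [2, 2], "surface": [2, 2.5], "safranin": [1, 1]}
        )
        assert (agg.structure, agg.surface, agg.safranin) == (2.0, 2.25, 1.0)
        assert agg.total == 5.25

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            aggregate_histology({"structure": [5, 2], "surface": [1, 1], "safranin": [1, 1]})

    def test_single_plateau_accepted_with_warning(self):
        with pytest.warns(UserWarning, match="one plateau"):
            agg = aggregate_histology({"structure": [2], "surface": [1], "safranin": [3]})
        assert agg.total == 6.0

    def test_idempotent_on_aggregated_scores(self):
        once = aggregate_histology({"structure": [2, 3], "surface": [1, 2], "safranin": [0, 1]})
        again = aggregate_histology(
            {"structure": [once.structure], "surface": [once.surface], "safranin": [once.safranin]}
        )
        assert (again.structure, again.surface, again.safranin) == (
            once.structure,
            once.surface,
            once.safranin,
        )


class TestMixedModel:
    def test_baseline_contrast_recovers_generator_truth(self):
        """Null-vs-wild-type baseline contrast within 2 SE of the generator truth.

        On the log scale the truth is log(0.077/0.036) plus the Jensen
        offset (sigma_wt^2 - sigma_ko^2)/2, because the unit-mean log-normal
        animal effect has E[log] = -sigma^2/2 and the genotypes have
        different between-animal CVs.
        """
        profiles = default_profiles()
        s2 = {g: np.log1p(p.animal_cv**2) for g, p in profiles.items()}
        truth = np.log(0.077 / 0.036) + 0.5 * (s2["Prg4+/+"] - s2["Prg4-/-"])
        hits = 0
        for seed in range(10):
            ds = generate_study(design=REDUCED_DESIGN, seed=100 + seed)
            eff = fit_cof_mixed_model(ds)
            row = eff.contrasts.set_index("label").loc["Prg4-/- vs Prg4+/+ @ baseline"]
            hits += abs(row["estimate"] - truth) <= 2 * row["se"]
        assert hits >= 9

    def test_zero_noise_dataset_flags_singular_fit(self):
        profiles = {
            g: GenotypeProfile(**{**vars(p), "animal_cv": 0.0, "trial_sd": 0.0})
            for g, p in default_profiles().items()
        }
        ds = generate_study(design=REDUCED_DESIGN, profiles=profiles, seed=0)
        # break exact degeneracy so the likelihood is finite but the animal
        # variance component is still zero
        rng = np.random.default_rng(0)
        ds.cof["cof"] = ds.cof["cof"] * np.exp(rng.normal(0, 1e-6, len(ds.cof)))
        with pytest.warns(UserWarning, match="singular"):
            eff = fit_cof_mixed_model(ds)
        assert eff.singular

    def test_non_positive_cof_rejected(self):
        ds = generate_study(design=REDUCED_DESIGN, seed=1)
        ds.cof.loc[0, "cof"] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_cof_mixed_model(ds)

    def test_requires_two_genotypes(self):
        ds = generate_study(design=REDUCED_DESIGN, seed=1)
        sub = ds.cof[ds.cof["genotype"] == "Prg4+/+"]
        from jointcof.study import StudyDataset

        with pytest.raises(ValueError, match="genotype"):
            fit_cof_mixed_model(StudyDataset(cof=sub, histology=ds.histology))

    def test_reports_all_fixed_effect_terms(self):
        ds = generate_study(design=REDUCED_DESIGN, seed=4)
        eff = fit_cof_mixed_model(ds)
        terms = set(eff.fixed_effects["term"])
        assert {"genotype", "time (experimental limb)", "limb (shared times)",
                "genotype x condition"} <= terms
        assert eff.fixed_effects["p_value"].between(0, 1).all()
        assert eff.animal_variance >= 0


class TestAnova:
    def test_balanced_sums_of_squares_decompose(self):
        ds = generate_study(seed=9)
        scores = aggregate_joint_scores(ds.histology)
        tables = anova_histology(scores)
        for resp in ("structure", "total"):
            table = tables[resp]["anova"]
            y = scores[resp]
            total_ss = float(np.sum((y - y.mean()) ** 2))
            assert np.isclose(table["sum_sq"].sum(), total_ss, rtol=1e-8)

    def test_genotype_effect_power_on_structure(self):
        """Structure scores separate genotypes at p < 0.001 in >= 95% of runs."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            ds = generate_study(design=REDUCED_DESIGN, seed=2000 + seed)
            tables = anova_histology(aggregate_joint_scores(ds.histology))
            p = tables["structure"]["anova"].loc["C(genotype)", "PR(>F)"]
            hits += p < 0.001
        assert hits / n_rep >= 0.95

    def test_type_i_error_with_identical_cells(self):
        """Same population in every cell: genotype rejections near 5%."""
        rng = np.random.default_rng(7)
        n_rep, hits = 200, 0
        genotypes = ["A", "B", "C"]
        for _ in range(n_rep):
            rows = []
            for g in genotypes:
                for limb in ("experimental", "control"):
                    for i in range(12):
                        rows.append((f"{g}{i}", g, limb, rng.normal(1.0, 0.5)))
            df = pd.DataFrame(rows, columns=["animal_id", "genotype", "limb", "structure"])
            df["surface"] = rng.normal(1.0, 0.5, len(df))
            df["safranin"] = rng.normal(1.0, 0.5, len(df))
            df["total"] = df[["structure", "surface", "safranin"]].sum(axis=1)
            p = anova_histology(df)["structure"]["anova"].loc["C(genotype)", "PR(>F)"]
            hits += p < 0.05
        assert 0.02 <= hits / n_rep <= 0.09

    def test_single_replicate_cells_rejected(self):
        df = pd.DataFrame(
            {
                "animal_id": ["a", "b", "c", "d"],
                "genotype": ["A", "A", "B", "B"],
                "limb": ["experimental", "control", "experimental", "control"],
                "structure": [1.0, 2.0, 3.0, 4.0],
                "surface": [1.0, 2.0, 3.0, 1.0],
                "safranin": [1.0, 2.0, 3.0, 1.0],
                "total": [3.0, 6.0, 9.0, 6.0],
            }
        )
        with pytest.raises(ValueError):
            anova_histology(df)

    def test_empty_cell_named_in_error(self):
        ds = generate_study(seed=3)
        scores = aggregate_joint_scores(ds.histology)
        scores = scores[~((scores["genotype"] == "Prg4-/-") & (scores["limb"] == "control"))]
        with pytest.raises(ValueError, match="Prg4-/-"):
            anova_histology(scores)


class TestCorrelation:
    def test_monotone_pairing_gives_rho_one(self):
        ds = generate_study(design=REDUCED_DESIGN, seed=6)
        scores = aggregate_joint_scores(ds.histology)
        final = (
            ds.cof.loc[
                ds.cof.groupby(["animal_id", "limb"])["wallclock_h"].transform("max")
                == ds.cof["wallclock_h"]
            ]
            .groupby(["animal_id", "limb"], as_index=False)["cof"]
            .mean()
        )
        ranked = final.merge(scores[["animal_id", "limb"]], on=["animal_id", "limb"])
        scores = scores.merge(final, on=["animal_id", "limb"])
        scores["total"] = scores["cof"].rank()  # perfectly monotone by construction
        result = correlate_cof_histology(ds, scores)
        overall = result.set_index("group").loc["overall"]
        assert overall["rho"] == pytest.approx(1.0)

    def test_constant_scores_flagged(self):
        ds = generate_study(design=REDUCED_DESIGN, seed=6)
        scores = aggregate_joint_scores(ds.histology)
        scores["total"] = 2.0
        result = correlate_cof_histology(ds, scores)
        assert bool(result.set_index("group").loc["overall", "constant"])
        assert np.isnan(result.set_index("group").loc["overall", "rho"])

    def test_null_scores_show_no_association(self):
        """Histology drawn identically for every cell: overall rho weak and
        non-significant in >= 90% of replicate studies."""
        from jointcof.study import default_score_profiles, generate_histology

        shared = default_score_profiles()[("Prg4+/+", "control")]
        null_profiles = {key: shared for key in default_score_profiles()}
        ok = 0
        n_rep = 100
        for seed in range(n_rep):
            ds = generate_study(design=REDUCED_DESIGN, seed=3000 + seed)
            ds.histology = generate_histology(
                StudyDesign(), score_profiles=null_profiles, seed=9000 + seed
            )
            row = correlate_cof_histology(ds).set_index("group").loc["overall"]
            ok += (abs(row["rho"]) < 0.4) and (row["p_value"] > 0.05)
        assert ok / n_rep >= 0.90

    def test_too_few_joints_rejected(self):
        ds = generate_study(design=REDUCED_DESIGN, seed=1)
        from jointcof.study import StudyDataset

        small = ds.cof[ds.cof["animal_id"] == "Prg4+/+_01"]
        hist = ds.histology[ds.histology["animal_id"] == "Prg4+/+_01"]
        with pytest.raises(ValueError, match="3 joints"):
            correlate_cof_histology(StudyDataset(cof=small, histology=hist))
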