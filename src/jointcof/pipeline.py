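"""End-to-end study runner: generate -> (measure) -> analyse -> report."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import write_manifest, write_study_tables, write_trajectory
from .pendulum import MarkerLayout, PendulumConfig
from .stats import (
    aggregate_joint_scores,
    anova_histology,
    correlate_cof_histology,
    fit_cof_mixed_model,
)
from .study import GenotypeProfile, StudyDesign, default_profiles, generate_study

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one run needs: pendulum, design, profiles, analysis, seed."""

    pendulum: PendulumConfig = field(default_factory=PendulumConfig)
    design: StudyDesign = field(default_factory=StudyDesign)
    profiles: dict[str, GenotypeProfile] = field(default_factory=default_profiles)
    layout: MarkerLayout | None = None
    fidelity: str = "summary"
    alpha: float = 0.05
    seed: int = 0
    out_dir: Path | None = None

    def as_dict(self) -> dict:
        return {
            "pendulum": vars(self.pendulum),
            "design": {
                "genotypes": list(self.design.genotypes),
                "n_per_genotype": self.design.n_per_genotype,
                "experimental_timepoints": self.design.experimental_timepoints,
                "control_timepoints": self.design.control_timepoints,
                "trials_per_measurement": self.design.trials_per_measurement,
                "marker_noise_sd": self.design.marker_noise_sd,
            },
            "profiles": {g: vars(p) for g, p in self.profiles.items()},
            "fidelity": self.fidelity,
            "alpha": self.alpha,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    dataset: object
    effects: object
    histology_anova: dict
    correlation: pd.DataFrame
    summary: pd.DataFrame


def _group_summary(cof: pd.DataFrame, profiles: dict[str, GenotypeProfile]) -> pd.DataFrame:
    """Observed baseline/final experimental group means next to the profile anchors."""
    rows = []
    exp = cof[cof["limb"] == "experimental"]
    t0 = exp["wallclock_h"].min()
    t1 = exp["wallclock_h"].max()
    for genotype, grp in exp.groupby("genotype", sort=True):
        prof = profiles[genotype]
        rows.append(
            {
                "genotype": genotype,
                "baseline_mean_observed": grp.loc[grp["wallclock_h"] == t0, "cof"].mean(),
                "baseline_mean_target": prof.baseline_mean,
                "final_mean_observed": grp.loc[grp["wallclock_h"] == t1, "cof"].mean(),
                "final_mean_target": prof.final_mean,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the whole chain and, if ``out_dir`` is set, write all artifacts.

    Stages: study generation (optionally full-physics per trial), the
    log-CoF mixed model, histology aggregation + two-way ANOVA, and the
    CoF-histology correlation.  A failing stage aborts with the stage name.
    Deterministic given ``seed``.
    """
    stage = "generate"
    try:
        dataset = generate_study(
            design=config.design,
            profiles=config.profiles,
            fidelity=config.fidelity,
            seed=config.seed,
            pendulum_config=config.pendulum,
            layout=config.layout,
            keep_trajectories=config.out_dir is not None and config.fidelity == "physics",
        )
        stage = "mixed-model"
        effects = fit_cof_mixed_model(dataset, alpha=config.alpha)
        stage = "histology-anova"
        joint_scores = aggregate_joint_scores(dataset.histology)
        hist_anova = anova_histology(joint_scores)
        stage = "correlation"
        correlation = correlate_cof_histology(dataset, joint_scores)
        stage = "summary"
        summary = _group_summary(dataset.cof, config.profiles)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_study_tables(out, dataset)
        effects.fixed_effects.to_csv(out / "fixed_effects.csv", index=False)
        effects.contrasts.to_csv(out / "contrasts.csv", index=False)
        joint_scores.to_csv(out / "joint_scores.csv", index=False)
        for resp, tables in hist_anova.items():
            tables["anova"].to_csv(out / f"anova_{resp}.csv")
            tables["cells"].to_csv(out / f"cells_{resp}.csv", index=False)
        correlation.to_csv(out / "correlation.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        if dataset.trajectories:
            traj_dir = out / "trajectories"
            traj_dir.mkdir(exist_ok=True)
            for (animal_id, limb, tp, trial), frames in dataset.trajectories.items():
                safe = animal_id.replace("/", "").replace("+", "p").replace("-", "m")
                write_trajectory(traj_dir / f"{safe}_{limb}_t{tp:02d}_trial{trial}.csv", frames)
        write_manifest(out, config.as_dict(), config.seed)

    return PipelineResult(
        dataset=dataset,
        effects=effects,
        histology_anova=hist_anova,
        correlation=correlation,
        summary=summary,
    )
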