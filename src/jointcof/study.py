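"""Synthetic lubricin gene-dosage loading study.

Generates a complete dataset with the statistical structure of the ex vivo
experiment: three Prg4 genotypes (2, 1 or 0 functional lubricin alleles),
12 animals each, paired experimental (cyclically loaded) and contralateral
control limbs, whole-joint coefficient of friction (CoF) measured at 16
time points on the experimental limb (baseline, a 2-hour loading block, a
point after 12 hours unloaded, and an additional 24-hour loading block) and
2 time points on the control limb (0 h and 38 h wall-clock), three pendulum
trials per measurement, plus ordinal cartilage-histology scores per tibial
plateau.

The genotype CoF trajectories are parameterised by their baseline and
end-of-loading group means/SDs and a genotype-specific wear onset: the true
CoF is flat at baseline until ``onset_hours`` of cumulative loading, then
ramps linearly to the final mean at 26 h.  Control limbs stay at baseline
(no change was seen in unloaded joints).  Noise is multiplicative
(log-normal) at the animal level (shared by both limbs of a pair) and at
the trial level, consistent with analysing CoF on the log scale.

Two fidelity levels: ``summary`` draws CoF values directly from the noise
model; ``physics`` runs a full simulate -> render markers -> track ->
estimate round trip per trial with the true Coulomb coefficient set to the
animal-level trajectory value and the release angle drawn uniformly from
[10, 14] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cof import auto_duration, estimate_cof_from_series
from .pendulum import (
    FrictionParams,
    MarkerLayout,
    PendulumConfig,
    render_markers,
    simulate_free_oscillation,
)
from .tracking import estimate_angles

__all__ = [
    "GENOTYPES",
    "LIMBS",
    "HISTOLOGY_CATEGORIES",
    "CATEGORY_MAXIMA",
    "StudyDesign",
    "GenotypeProfile",
    "StudyDataset",
    "default_profiles",
    "default_score_profiles",
    "default_experimental_schedule",
    "default_control_schedule",
    "true_cof_trajectory",
    "generate_histology",
    "generate_study",
]

GENOTYPES = ("Prg4+/+", "Prg4+/-", "Prg4-/-")
LIMBS = ("experimental", "control")
HISTOLOGY_CATEGORIES = ("structure", "surface", "safranin")
CATEGORY_MAXIMA = {"structure": 4.0, "surface": 3.0, "safranin": 4.0}
PLATEAUS = ("medial", "lateral")

TOTAL_LOADING_HOURS = 26.0


def default_experimental_schedule() -> list[tuple[float, float]]:
    """(cumulative loading h, wall-clock h) for the 16 experimental time points.

    Baseline, six points through the 2-h loading block, one point after the
    12-h unloaded rest, and eight points through the additional 24-h block.
    The exact within-block sampling times are a package choice (the protocol
    only fixes the block structure and the total of 16).
    """
    points = [(0.0, 0.0)]
    points += [(h, h) for h in (1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3, 2.0)]
    points.append((2.0, 14.0))  # after the 12-h unloaded rest
    points += [(h, h + 12.0) for h in (5.0, 8.0, 11.0, 14.0, 17.0, 20.0, 23.0, 26.0)]
    return points


def default_control_schedule() -> list[tuple[float, float]]:
    """Control limbs: baseline and end of the 38-h experiment, unloaded throughout."""
    return [(0.0, 0.0), (0.0, 38.0)]


@dataclass
class StudyDesign:
    """Who is measured when: genotypes, animals, limbs, schedules, trials."""

    genotypes: tuple[str, ...] = GENOTYPES
    n_per_genotype: int = 12
    experimental_timepoints: list[tuple[float, float]] = field(
        default_factory=default_experimental_schedule
    )
    control_timepoints: list[tuple[float, float]] = field(default_factory=default_control_schedule)
    trials_per_measurement: int = 3
    marker_noise_sd: float = 0.05  # mm, physics fidelity only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype < 1:
            raise ValueError("n_per_genotype must be >= 1")
        if self.trials_per_measurement < 1:
            raise ValueError("trials_per_measurement must be >= 1")
        for sched in (self.experimental_timepoints, self.control_timepoints):
            loads = [p[0] for p in sched]
            walls = [p[1] for p in sched]
            if any(w1 > w2 for w1, w2 in zip(walls, walls[1:])):
                raise ValueError("wall-clock times must be non-decreasing")
            if any(l1 > l2 for l1, l2 in zip(loads, loads[1:])):
                raise ValueError("cumulative loading must be non-decreasing")
            if any(not (0.0 <= l <= TOTAL_LOADING_HOURS) for l in loads):
                raise ValueError(f"cumulative loading must lie in [0, {TOTAL_LOADING_HOURS}] h")


@dataclass
class GenotypeProfile:
    """CoF trajectory and noise parameters for one Prg4 genotype.

    ``onset_hours`` is the cumulative loading before wear-driven CoF rise
    begins; ``animal_cv`` the between-animal log-normal coefficient of
    variation (shared by both limbs of a pair); ``trial_sd`` the
    within-measurement replicate noise on the CoF scale.
    """

    baseline_mean: float
    baseline_sd: float
    final_mean: float
    final_sd: float
    onset_hours: float
    animal_cv: float
    trial_sd: float

    def __post_init__(self) -> None:
        for name in ("baseline_mean", "baseline_sd", "final_mean", "final_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.final_mean < self.baseline_mean:
            raise ValueError("final_mean must be >= baseline_mean")
        if not (0.0 <= self.onset_hours <= TOTAL_LOADING_HOURS):
            raise ValueError(f"onset_hours must lie in [0, {TOTAL_LOADING_HOURS}]")
        if self.animal_cv < 0 or self.trial_sd < 0:
            raise ValueError("animal_cv and trial_sd must be >= 0")


def default_profiles() -> dict[str, GenotypeProfile]:
    """Calibration profiles anchored to the reported group means and SDs.

    Baselines 0.036/0.030/0.077 and 26-h finals 0.061/0.12/0.13 for 2/1/0
    functional lubricin alleles.  Wear onset: immediate for Prg4-/- (CoF
    rose from the start of loading), 5 h for Prg4+/- (no change through 4 h,
    a mild rise by 6 h) and 7 h for Prg4+/+ (no change through 6 h).
    Between-animal CV is set from the baseline SD/mean ratio; trial noise
    defaults to 10% of baseline.
    """
    spec = {
        "Prg4+/+": (0.036, 0.0096, 0.061, 0.034, 7.0),
        "Prg4+/-": (0.030, 0.0044, 0.12, 0.049, 5.0),
        "Prg4-/-": (0.077, 0.0095, 0.13, 0.014, 0.0),
    }
    return {
        g: GenotypeProfile(
            baseline_mean=b,
            baseline_sd=bs,
            final_mean=f,
            final_sd=fs,
            onset_hours=onset,
            animal_cv=bs / b,
            trial_sd=0.1 * b,
        )
        for g, (b, bs, f, fs, onset) in spec.items()
    }


def default_score_profiles() -> dict[tuple[str, str], dict[str, tuple[float, float]]]:
    """Histology cell (mean, SD) per genotype x treatment x category.

    Values are the reported per-cell group statistics for articular
    cartilage surface structure (0-4), surface layer morphology (0-3) and
    pericellular Safranin O loss (0-4).
    """
    return {
        ("Prg4+/+", "experimental"): {
            "structure": (0.21, 0.33),
            "surface": (0.38, 0.43),
            "safranin": (0.88, 0.74),
        },
        ("Prg4+/+", "control"): {
            "structure": (0.21, 0.40),
            "surface": (0.30, 0.33),
            "safranin": (0.83, 0.65),
        },
        ("Prg4+/-", "experimental"): {
            "structure": (0.40, 0.52),
            "surface": (0.65, 0.47),
            "safranin": (1.55, 0.99),
        },
        ("Prg4+/-", "control"): {
            "structure": (0.20, 0.26),
            "surface": (0.25, 0.26),
            "safranin": (1.40, 1.17),
        },
        ("Prg4-/-", "experimental"): {
            "structure": (2.05, 0.52),
            "surface": (2.09, 0.20),
            "safranin": (1.14, 0.60),
        },
        ("Prg4-/-", "control"): {
            "structure": (1.91, 0.77),
            "surface": (1.59, 0.86),
            "safranin": (1.18, 0.98),
        },
    }


def true_cof_trajectory(profile: GenotypeProfile, limb: str, cumulative_loading_h: float) -> float:
    """Noise-free CoF as a function of cumulative loading hours.

    Control limbs stay at the baseline mean; experimental limbs stay at
    baseline until ``onset_hours`` then ramp linearly to ``final_mean`` at
    26 h of cumulative loading.  The trajectory depends on loading hours
    only, so it is constant through unloading gaps by construction.
    """
    if limb not in LIMBS:
        raise ValueError(f"limb must be one of {LIMBS}, got {limb!r}")
    h = float(cumulative_loading_h)
    if not (0.0 <= h <= TOTAL_LOADING_HOURS):
        raise ValueError(f"cumulative loading {h} h outside [0, {TOTAL_LOADING_HOURS}]")
    if limb == "control" or h <= profile.onset_hours:
        return profile.baseline_mean
    frac = (h - profile.onset_hours) / (TOTAL_LOADING_HOURS - profile.onset_hours)
    return profile.baseline_mean + (profile.final_mean - profile.baseline_mean) * frac


@dataclass
class StudyDataset:
    """Tidy long-format study tables.

    ``cof``: one row per animal x limb x time point x trial.
    ``histology``: one row per animal x limb x plateau x category.
    ``trajectories``: physics fidelity only, (animal_id, limb, timepoint_id,
    trial_id) -> MarkerFrames.
    """

    cof: pd.DataFrame
    histology: pd.DataFrame
    trajectories: dict | None = None


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean log-normal multipliers with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(() if size is None else size)
    sigma = math.sqrt(math.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def generate_histology(
    design: StudyDesign,
    score_profiles: dict | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Consensus ordinal histology scores per joint and tibial plateau.

    Per joint, plateau and category a latent Gaussian is drawn at the cell
    mean/SD, truncated (clipped) to the category range and rounded to the
    nearest 0.5 (the consensus scale; ties follow round-half-even).
    """
    if score_profiles is None:
        score_profiles = default_score_profiles()
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in design.genotypes:
        for i in range(design.n_per_genotype):
            animal_id = f"{genotype}_{i + 1:02d}"
            for limb in LIMBS:
                cell = score_profiles[(genotype, limb)]
                for plateau in PLATEAUS:
                    for category in HISTOLOGY_CATEGORIES:
                        mean, sd = cell[category]
                        latent = rng.normal(mean, sd)
                        clipped = float(np.clip(latent, 0.0, CATEGORY_MAXIMA[category]))
                        score = float(np.round(clipped / 0.5) * 0.5)
                        rows.append((animal_id, genotype, limb, plateau, category, score))
    return pd.DataFrame(
        rows, columns=["animal_id", "genotype", "limb", "plateau", "category", "score"]
    )


def generate_study(
    design: StudyDesign | None = None,
    profiles: dict[str, GenotypeProfile] | None = None,
    fidelity: str = "summary",
    seed: int | None = None,
    pendulum_config: PendulumConfig | None = None,
    layout: MarkerLayout | None = None,
    keep_trajectories: bool = False,
) -> StudyDataset:
    """Generate the full study dataset, reproducibly for a given seed.

    Per animal a unit-mean log-normal effect (CV ``animal_cv``) is drawn and
    shared by both limbs; per trial an independent unit-mean log-normal
    multiplier reproduces the replicate noise (``trial_sd`` mapped to a CV
    against the baseline mean).  With ``fidelity="physics"`` each trial's
    CoF instead comes from a full pendulum round trip with the true Coulomb
    coefficient set to the animal-level trajectory value.
    """
    if design is None:
        design = StudyDesign()
    if profiles is None:
        profiles = default_profiles()
    if fidelity not in ("summary", "physics"):
        raise ValueError(f"fidelity must be 'summary' or 'physics', got {fidelity!r}")
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    if pendulum_config is None:
        pendulum_config = PendulumConfig()

    rows = []
    trajectories: dict | None = {} if (fidelity == "physics" and keep_trajectories) else None
    for genotype in design.genotypes:
        profile = profiles[genotype]
        trial_cv = profile.trial_sd / profile.baseline_mean
        for i in range(design.n_per_genotype):
            animal_id = f"{genotype}_{i + 1:02d}"
            animal_mult = float(_lognormal_multipliers(rng, profile.animal_cv, None))
            for limb, schedule in (
                ("experimental", design.experimental_timepoints),
                ("control", design.control_timepoints),
            ):
                for tp_id, (load_h, wall_h) in enumerate(schedule):
                    true_level = true_cof_trajectory(profile, limb, load_h) * animal_mult
                    for trial_id in range(design.trials_per_measurement):
                        if fidelity == "summary":
                            cof = true_level * float(
                                _lognormal_multipliers(rng, trial_cv, None)
                            )
                        else:
                            start = float(rng.uniform(10.0, 14.0))
                            cfg = replace(pendulum_config, start_angle=start)
                            friction = FrictionParams(mu=true_level)
                            traj = simulate_free_oscillation(
                                cfg, friction, auto_duration(cfg, friction)
                            )
                            frames = render_markers(
                                traj,
                                layout=layout,
                                noise_sd=design.marker_noise_sd,
                                seed=int(rng.integers(2**31)),
                            )
                            series = estimate_angles(frames, layout=layout)
                            cof = estimate_cof_from_series(series, cfg).mu_hat
                            if trajectories is not None:
                                trajectories[(animal_id, limb, tp_id, trial_id)] = frames
                        rows.append(
                            (
                                animal_id,
                                genotype,
                                limb,
                                tp_id,
                                load_h,
                                wall_h,
                                trial_id,
                                cof,
                            )
                        )
    cof_df = pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "genotype",
            "limb",
            "timepoint_id",
            "cumulative_loading_h",
            "wallclock_h",
            "trial_id",
            "cof",
        ],
    )
    histology = generate_histology(design, seed=int(rng.integers(2**31)))
    return StudyDataset(cof=cof_df, histology=histology, trajectories=trajectories)
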