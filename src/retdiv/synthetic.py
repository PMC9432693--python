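"""Synthetic capture data emulating the retention experiment, with known truth.

The generator reproduces the hierarchical structure of the field study —
10 complete blocks of 5 retention treatments (plus rotation-aged reference
stands in 9 blocks), paired trapping grids per stand (2x48, 4x24 or 8x12
traps depending on treatment), 4 consecutive trap nights per stand-year over
3 summers — and a ~21-species community with a strongly right-skewed
abundance distribution (the four commonest species contribute ~85% of
captures at the defaults).

The abundance/detection process matches the Royle-Nichols community model
fit downstream: per species i and subplot-year j,

    N_ij ~ Poisson(lambda_ij),  log lambda_ij = beta0_i + beta_i[class(j)] + alpha_stand(j)
    each of the N_ij individuals is captured independently with probability
    r_ij per night, logit r_ij = a0_i + a1_i * week_j (standardised week)

so the per-night species detection probability is 1 - (1 - r_ij)^N_ij and
marginal occupancy is 1 - exp(-lambda_ij).  Arboreal species receive a
positive riparian-patch effect by default, mirroring the flying-squirrel
pattern, which gives recovery tests a signed truth.

Ground truth (all parameters, latent abundances and occupancy states) is
returned alongside the capture table so every downstream estimator has a
recoverable target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from retdiv.capture_data import (
    CaptureTable,
    DetectionArray,
    SurveyDesign,
    CAPTURE_COLUMNS,
    SUBPLOT_CLASSES,
    subplot_class,
)
from retdiv.functional import TraitTable, DIET_GUILDS, ACTIVITY_STRATA

#: Subplot layout per treatment: (cover_type, patch_context, n_traps).
#: RA/UA pair one 48-trap patch grid with one 48-trap clearcut grid; S/SS use
#: four 24-trap grids; DS eight 12-trap grids; rotation stands a single
#: 48-trap grid.
TREATMENT_GRIDS: Mapping[str, tuple[tuple[str, str, int], ...]] = {
    "RA": (("patch", "riparian", 48), ("clearcut", "none", 48)),
    "UA": (("patch", "upland", 48), ("clearcut", "none", 48)),
    "S": (
        ("patch", "riparian", 24),
        ("patch", "upland", 24),
        ("clearcut", "none", 24),
        ("clearcut", "none", 24),
    ),
    "SS": (
        ("patch", "riparian", 24),
        ("patch", "upland", 24),
        ("clearcut", "none", 24),
        ("clearcut", "none", 24),
    ),
    "DS": tuple(
        [("patch", "upland", 12)] * 4 + [("clearcut", "none", 12)] * 4
    ),
    "ROT": (("rotation", "none", 48),),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults emulate the field study: 10 blocks x 5 treatments (+ rotation
    stands in 9 blocks), 3 years, 4 trap nights, 21 species whose log-normal
    abundance intercepts put ~85% of captures in the top 4 species, and a
    positive riparian effect for arboreal species.
    """

    n_blocks: int = 10
    treatments: tuple[str, ...] = ("RA", "UA", "S", "SS", "DS")
    include_rotation: bool = True
    n_rotation_stands: int = 9
    n_years: int = 3
    n_occasions: int = 4
    n_species: int = 21
    n_arboreal: int | None = None  # default: scaled from the observed 2/21
    #: centre and dispersion of species log-abundance intercepts.  Intercepts
    #: follow the log-normal rank-abundance curve (Gaussian quantiles scaled
    #: by ``abundance_sd_log``) with per-species noise ``rank_noise_sd``, so
    #: the community reliably has a few dominant and many rare species.
    mean_log_lambda: float = -2.7
    abundance_sd_log: float = 2.3
    rank_noise_sd: float = 0.3
    #: community-mean subplot-class effects on log-abundance, by species group
    class_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "arboreal": {"upland_patch": 0.0, "riparian_patch": 1.0, "rotation": 0.5},
            "other": {"upland_patch": 0.0, "riparian_patch": 0.3, "rotation": -0.3},
        }
    )
    #: SD of species-level deviations around the group-mean class effects
    class_effect_sd: float = 0.5
    detection_logit_mean: float = -0.7
    detection_logit_sd: float = 0.5
    week_effect_mean: float = 0.0
    week_effect_sd: float = 0.2
    stand_sd: float = 0.3
    #: emulate the study's unsampled units (one UA stand-year skipped, one S
    #: stand trapped 3 nights in the final year, two rotation stands logged)
    missingness: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.abundance_sd_log, self.class_effect_sd, self.detection_logit_sd,
               self.week_effect_sd, self.stand_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_species < 1 or self.n_blocks < 1 or self.n_years < 1:
            raise ValueError("counts must be positive")


@dataclass
class TruthRecord:
    """Generator ground truth for recovery tests.

    ``beta_class`` columns follow ``class_names`` (clearcut omitted: it is
    the reference, effect 0).  ``n_latent[i, j]`` is the realized abundance
    of species i at unit j (aligned with the returned DetectionArray's full
    species list, not the observed subset); ``z = (n_latent >= 1)``.
    """

    species: tuple[str, ...]
    class_names: tuple[str, ...]
    beta0: np.ndarray
    beta_class: np.ndarray  # (n_species, len(class_names))
    a0: np.ndarray
    a1: np.ndarray
    alpha_stand: dict[str, float]
    lambda_by_class: np.ndarray  # (n_species, 4), at alpha=0
    n_latent: np.ndarray
    z: np.ndarray
    arboreal_species: tuple[str, ...]
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": list(self.species),
            "class_names": list(self.class_names),
            "beta0": self.beta0.tolist(),
            "beta_class": self.beta_class.tolist(),
            "a0": self.a0.tolist(),
            "a1": self.a1.tolist(),
            "alpha_stand": self.alpha_stand,
            "lambda_by_class": self.lambda_by_class.tolist(),
            "arboreal_species": list(self.arboreal_species),
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
                if not isinstance(v, Mapping)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_traits(
    n_species: int, seed: int, n_arboreal: int | None = None
) -> TraitTable:
    """Synthetic species trait table (mass, diet guild, activity stratum).

    Diet guild counts are proportional to the observed community (3
    carnivores / 4 insectivores / 14 granivore-mycophages of 21); body
    masses are log-normal (a few grams for shrews up to several hundred for
    squirrels).  ``n_arboreal`` overrides the default number of arboreal
    species (2 of 21, scaled).  Insectivores are flagged untagged (shrews are
    not ear-tagged in the field, every capture counts as a new individual).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    codes = tuple(f"SP{i + 1:02d}" for i in range(n_species))

    n_carn = max(1, round(3 / 21 * n_species)) if n_species >= 3 else 0
    n_ins = max(1, round(4 / 21 * n_species)) if n_species >= 2 else 0
    n_carn = min(n_carn, n_species)
    n_ins = min(n_ins, n_species - n_carn)
    diets = (
        ["carnivore"] * n_carn
        + ["insectivore"] * n_ins
        + ["granivore_mycophage"] * (n_species - n_carn - n_ins)
    )

    if n_arboreal is None:
        n_arboreal = max(1, round(2 / 21 * n_species)) if n_species >= 4 else 0
    n_arboreal = min(n_arboreal, n_species)
    n_semi = min(max(0, round(3 / 21 * n_species)), n_species - n_arboreal)
    n_foss = min(max(0, round(3 / 21 * n_species)), n_species - n_arboreal - n_semi)
    strata = (
        ["arboreal"] * n_arboreal
        + ["semi_arboreal"] * n_semi
        + ["fossorial"] * n_foss
        + ["ground"] * (n_species - n_arboreal - n_semi - n_foss)
    )
    rng.shuffle(diets)
    rng.shuffle(strata)
    mass = np.round(np.exp(rng.normal(np.log(40.0), 1.1, size=n_species)), 1)
    mass = np.clip(mass, 3.0, 999.0)
    df = pd.DataFrame(
        {
            "species": codes,
            "mass_g": mass,
            "diet": diets,
            "stratum": strata,
            "tagged": [d != "insectivore" for d in diets],
        }
    )
    return TraitTable(df)


def build_design(config: SimulationConfig) -> SurveyDesign:
    """Enumerate all subplot-years of the experiment as a survey design.

    Stand labels are ``B{b}-{treatment}``; subplot labels append the grid
    index.  Sampling week rotates across blocks and years the way field
    crews rotated stand schedules.  When ``config.missingness`` is on, the
    units the study could not sample are flagged (0 or 3 realized occasions).
    """
    rows = []
    treatments = list(config.treatments)
    block_ids = [f"B{b + 1:02d}" for b in range(config.n_blocks)]
    for bi, block in enumerate(block_ids):
        stand_treats = list(treatments)
        if config.include_rotation and bi < config.n_rotation_stands:
            stand_treats.append("ROT")
        for treat in stand_treats:
            stand = f"{block}-{treat}"
            for gi, (cover, context, n_traps) in enumerate(TREATMENT_GRIDS[treat]):
                subplot = f"{stand}-G{gi + 1}"
                for year in range(1, config.n_years + 1):
                    week = 1 + (bi * 3 + (year - 1) * 5) % 14
                    rows.append(
                        {
                            "unit": f"{subplot}:{year}",
                            "block": block,
                            "stand": stand,
                            "treatment": treat,
                            "subplot": subplot,
                            "cover_type": cover,
                            "patch_context": context,
                            "subplot_class": subplot_class(cover, context),
                            "n_traps": n_traps,
                            "year": year,
                            "week": week,
                            "occasions_sampled": config.n_occasions,
                        }
                    )
    units = pd.DataFrame(rows)
    if config.missingness and config.n_years >= 3:
        last = config.n_years
        # one UA stand not trapped in the final year
        ua_mask = (units["stand"] == "B01-UA") & (units["year"] == last)
        units.loc[ua_mask, "occasions_sampled"] = 0
        # one Split stand sampled for only three nights in the final year
        s_mask = (units["stand"] == "B01-S") & (units["year"] == last)
        units.loc[s_mask, "occasions_sampled"] = min(3, config.n_occasions)
        # two rotation stands logged before the final year
        if config.include_rotation and config.n_rotation_stands >= 2:
            logged = [f"B{config.n_rotation_stands - 1:02d}-ROT",
                      f"B{config.n_rotation_stands:02d}-ROT"]
            rot_mask = units["stand"].isin(logged) & (units["year"] == last)
            units.loc[rot_mask, "occasions_sampled"] = 0
    return SurveyDesign(units=units)


def simulate_experiment(
    config: SimulationConfig, traits: TraitTable | None = None
) -> tuple[CaptureTable, DetectionArray, TruthRecord]:
    """Simulate the full experiment; returns captures, detections and truth.

    The returned DetectionArray covers only species with at least one
    capture (sorted by code), exactly as :func:`build_detection_histories`
    would produce from the capture table; the TruthRecord covers all
    ``config.n_species`` species.
    """
    rng = np.random.default_rng(config.seed)
    if traits is None:
        traits = simulate_traits(config.n_species, seed=config.seed, n_arboreal=config.n_arboreal)
    if len(traits) != config.n_species:
        raise ValueError("trait table size does not match config.n_species")
    design = build_design(config)
    units = design.units
    n_units = len(units)
    species = traits.species
    S = config.n_species

    strata = traits.table["stratum"].to_numpy()
    arboreal = strata == "arboreal"
    class_names = ("upland_patch", "riparian_patch", "rotation")

    # log-normal rank-abundance curve: quantile backbone + per-species noise,
    # rank order randomly assigned to species codes
    from scipy.stats import norm as _norm

    z = _norm.ppf((np.arange(1, S + 1) - 0.5) / S)
    beta0 = (
        config.mean_log_lambda
        + config.abundance_sd_log * rng.permutation(z)
        + rng.normal(0.0, config.rank_noise_sd, size=S)
    )
    beta_class = np.empty((S, 3))
    for ci, cname in enumerate(class_names):
        mean_arb = config.class_effects["arboreal"][cname]
        mean_oth = config.class_effects["other"][cname]
        means = np.where(arboreal, mean_arb, mean_oth)
        beta_class[:, ci] = rng.normal(means, config.class_effect_sd)
    a0 = rng.normal(config.detection_logit_mean, config.detection_logit_sd, size=S)
    a1 = rng.normal(config.week_effect_mean, config.week_effect_sd, size=S)

    stands = sorted(units["stand"].unique())
    alpha = {s: float(rng.normal(0.0, config.stand_sd)) for s in stands}

    week = units["week"].to_numpy(dtype=float)
    week_std = (week - week.mean()) / (week.std() if week.std() > 0 else 1.0)
    class_idx = units["subplot_class"].map(
        {c: i for i, c in enumerate(class_names)}
    ).to_numpy()  # NaN for clearcut
    class_eff = np.zeros((S, n_units))
    for ci in range(3):
        mask = class_idx == ci
        class_eff[:, mask] = beta_class[:, ci][:, None]
    alpha_unit = units["stand"].map(alpha).to_numpy(dtype=float)

    log_lam = beta0[:, None] + class_eff + alpha_unit[None, :]
    lam = np.exp(log_lam)
    r = expit(a0[:, None] + a1[:, None] * week_std[None, :])
    if np.any((r < 0) | (r > 1)):
        raise ValueError("config implies detection probability outside [0, 1]")

    N = rng.poisson(lam)
    occ_sampled = units["occasions_sampled"].to_numpy(dtype=int)

    tagged_flag = traits.table["tagged"].to_numpy() if "tagged" in traits.table else np.ones(S, bool)
    mass = traits.table["mass_g"].to_numpy(dtype=float)

    y_full = np.zeros((S, n_units, config.n_occasions), dtype=float)
    for j in range(n_units):
        y_full[:, j, occ_sampled[j]:] = np.nan

    records: list[dict] = []
    tag_serial = 0
    unit_rows = units.to_dict("records")
    for i in range(S):
        for j in range(n_units):
            n_ij = int(N[i, j])
            if n_ij == 0 or occ_sampled[j] == 0:
                continue
            # each individual captured independently each realized night
            caps = rng.random((n_ij, occ_sampled[j])) < r[i, j]
            if not caps.any():
                continue
            u = unit_rows[j]
            det_occ = caps.any(axis=0)
            y_full[i, j, : occ_sampled[j]] = det_occ.astype(float)
            for ind in range(n_ij):
                occs = np.nonzero(caps[ind])[0]
                if occs.size == 0:
                    continue
                if tagged_flag[i]:
                    tag_serial += 1
                    tag = f"{species[i]}-{tag_serial:05d}"
                else:
                    tag = None
                for k in occs:
                    records.append(
                        {
                            "block": u["block"],
                            "stand": u["stand"],
                            "treatment": u["treatment"],
                            "subplot": u["subplot"],
                            "cover_type": u["cover_type"],
                            "patch_context": u["patch_context"],
                            "year": u["year"],
                            "week": u["week"],
                            "occasion": int(k) + 1,
                            "species": species[i],
                            "individual_tag": tag,
                            "tail_mm": round(float(rng.normal(45, 6)), 1)
                            if not tagged_flag[i]
                            else np.nan,
                            "mass_g": round(float(mass[i] * rng.lognormal(0, 0.15)), 1),
                        }
                    )
    df = pd.DataFrame(records, columns=list(CAPTURE_COLUMNS))
    df = df.sort_values(
        ["year", "week", "stand", "subplot", "occasion", "species"], kind="stable"
    ).reset_index(drop=True)
    table = CaptureTable(records=df, species_registry=frozenset(species))

    observed = sorted(df["species"].unique()) if len(df) else []
    obs_idx = [species.index(s) for s in observed]
    detections = DetectionArray(
        y=y_full[obs_idx], species=tuple(observed), units=units
    )

    lam_by_class = np.exp(
        beta0[:, None] + np.concatenate([np.zeros((S, 1)), beta_class], axis=1)
    )
    truth = TruthRecord(
        species=species,
        class_names=class_names,
        beta0=beta0,
        beta_class=beta_class,
        a0=a0,
        a1=a1,
        alpha_stand=alpha,
        lambda_by_class=lam_by_class,
        n_latent=N,
        z=(N >= 1),
        arboreal_species=tuple(str(s) for s in np.array(species)[arboreal]),
        config=config,
    )
    return table, detections, truth


def simulate_richness_table(
    effects: Mapping[str, float],
    sd_components: Mapping[str, float],
    seed: int,
    n_blocks: int = 10,
    n_years: int = 3,
    baseline: float = 6.6,
    treatments: Sequence[str] = ("RA", "UA", "S", "SS", "DS"),
) -> pd.DataFrame:
    """Gaussian stand-scale response table with a known variance decomposition.

    response = baseline + effect[treatment] + block + stand + residual, with
    ``sd_components`` keys ``block``, ``stand``, ``residual``.  One row per
    stand-year, matching the design the richness models expect; used to test
    the mixed models in isolation.
    """
    for k in ("block", "stand", "residual"):
        if sd_components.get(k, 0.0) < 0:
            raise ValueError(f"negative SD for component {k!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for bi in range(n_blocks):
        block = f"B{bi + 1:02d}"
        b_eff = rng.normal(0.0, sd_components.get("block", 0.0))
        for treat in treatments:
            stand = f"{block}-{treat}"
            s_eff = rng.normal(0.0, sd_components.get("stand", 0.0))
            for year in range(1, n_years + 1):
                resp = (
                    baseline
                    + effects.get(treat, 0.0)
                    + b_eff
                    + s_eff
                    + rng.normal(0.0, sd_components.get("residual", 0.0))
                )
                rows.append(
                    {
                        "unit": f"{stand}:{year}",
                        "block": block,
                        "stand": stand,
                        "treatment": treat,
                        "year": year,
                        "week": 1 + (bi * 3 + (year - 1) * 5) % 14,
                        "response": resp,
                    }
                )
    return pd.DataFrame(rows)
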