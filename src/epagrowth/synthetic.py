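"""Synthetic experiment generator.

Emulates the design of the motivating growth study: 12 clonal *Daphnia*
lineages from three species (four clones each of the small-bodied
*D. longispina* complex, the medium-bodied *D. pulicaria* and the
large-bodied *D. magna*), grown for 6 days at seven dietary EPA levels
spanning 0-10 ug EPA mg C^-1 with three replicate beakers per treatment,
plus neonate and day-6 fatty-acid samples for an eight-clone sub-panel.

The generative model for growth is the same Monod-like saturation curve
the analysis fits: each clone's parameters are the fixed values plus
clone-level Gaussian deviations (on the parameters named in
``random_effect_sd``), and each beaker observation adds Gaussian residual
noise.  The true half-saturation constant of every clone follows the
linear body-size law ``KS = K0 + KL * L``.

Everything is driven by a :class:`SimulationConfig`; the same seed and
config always produce bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    CloneInfo,
    ClutchRecord,
    FattyAcidProfile,
    GrowthRecord,
)
from .growth import SizeLaw, monod_growth, MonodParams

__all__ = [
    "DEFAULT_CLONES",
    "SimulationConfig",
    "default_config",
    "reference_size_law",
    "simulate_growth",
    "simulate_clutch",
    "simulate_fattyacids",
]

# The 12-clone default panel: species, body size at first reproduction (mm)
# and its SE.  Body sizes span 1.43-3.54 mm.
DEFAULT_CLONES: tuple[CloneInfo, ...] = (
    CloneInfo("DlE", "longispina_complex", 1.43, 0.02),
    CloneInfo("Dl4", "longispina_complex", 1.49, 0.02),
    CloneInfo("Dh", "longispina_complex", 1.59, 0.02),
    CloneInfo("Dg", "longispina_complex", 1.77, 0.02),
    CloneInfo("DpBrA3", "pulicaria", 1.90, 0.01),
    CloneInfo("DpBrS", "pulicaria", 2.09, 0.03),
    CloneInfo("DpGr8", "pulicaria", 2.28, 0.04),
    CloneInfo("DpGr49", "pulicaria", 2.31, 0.03),
    CloneInfo("IL-M1-12", "magna", 3.06, 0.02),
    CloneInfo("IL-M1-8", "magna", 3.18, 0.02),
    CloneInfo("FI-N26-8c", "magna", 3.33, 0.09),
    CloneInfo("FI-N47-20", "magna", 3.54, 0.04),
)

#: empirical anchors for each clone's half-saturation constant
#: (ug EPA mg C^-1); they increase with body size and define the default
#: size law by least squares.
KS_ANCHORS: dict[str, float] = {
    "DlE": 0.25, "Dl4": 0.31, "Dh": 0.41, "Dg": 0.60,
    "DpBrA3": 0.74, "DpBrS": 0.93, "DpGr8": 1.13, "DpGr49": 1.16,
    "IL-M1-12": 1.94, "IL-M1-8": 2.07, "FI-N26-8c": 2.22, "FI-N47-20": 2.44,
}

#: species-level baseline growth rate without EPA (day^-1)
G0_ANCHORS: dict[str, float] = {
    "longispina_complex": 0.174,
    "pulicaria": 0.312,
    "magna": 0.432,
}

#: per-clone growth rate on optimal green-algal food (day^-1); reference
#: ceiling values for the asymptote ginf.
GINF_ANCHORS: dict[str, float] = {
    "DlE": 0.268, "Dl4": 0.318, "Dh": 0.247, "Dg": 0.320,
    "DpBrA3": 0.288, "DpBrS": 0.347, "DpGr8": 0.460, "DpGr49": 0.484,
    "IL-M1-12": 0.534, "IL-M1-8": 0.542, "FI-N26-8c": 0.559, "FI-N47-20": 0.537,
}

#: default common true asymptote (day^-1): the optimal-food growth of the
#: largest species, above every species baseline.  The default scenario is
#: generated from the structure of model B1 (common fixed ginf, clone
#: variation only in g0 and in the size law for KS), so that the model
#: series has a well-defined true member; per-clone asymptotes can be set
#: explicitly via ``true_ginf_by_clone``.
GINF_COMMON = 0.55

#: species-level mean clutch size anchors (eggs per female)
CLUTCH_ANCHORS: dict[str, float] = {
    "longispina_complex": 1.31,
    "pulicaria": 1.35,
    "magna": 2.48,
}

#: clones that never develop eggs under the default scenario
DEFAULT_EGGLESS: tuple[str, ...] = ("Dg", "Dh")

#: eight-clone fatty-acid sub-panel with per-clone totals anchors
#: (ng ug^-1 dwt): neonate contents and newly-built-biomass quotas for
#: (total_FA, total_PUFA, total_w3, EPA).  The DlE quota row has only a
#: total-FA anchor; its PUFA/w3/EPA entries are synthetic plausible fills
#: so that simulated datasets are complete.
FA_NEONATE_ANCHORS: dict[str, tuple[float, float, float, float]] = {
    "DlE": (47.36, 25.53, 24.81, 1.55),
    "Dl4": (35.80, 19.24, 17.79, 0.36),
    "DpBrS": (37.42, 14.91, 13.48, 0.06),
    "DpBrA3": (43.35, 9.76, 8.88, 0.38),
    "IL-M1-12": (37.76, 20.35, 18.89, 0.34),
    "IL-M1-8": (37.26, 17.52, 16.11, 0.11),
    "FI-N26-8c": (50.16, 29.68, 27.97, 0.23),
    "FI-N47-20": (14.81, 5.99, 5.32, 0.35),
}

FA_QUOTA_ANCHORS: dict[str, tuple[float, float, float, float]] = {
    "DlE": (9.23, 1.20, 1.10, 0.30),  # PUFA/w3/EPA synthetic fills
    "Dl4": (52.56, 5.53, 5.03, 0.78),
    "DpBrS": (79.46, 0.96, 1.01, 0.25),
    "DpBrA3": (99.55, 2.59, 2.20, 0.16),
    "IL-M1-12": (27.51, 1.71, 1.34, 0.86),
    "IL-M1-8": (47.99, 2.45, 2.08, 1.22),
    "FI-N26-8c": (69.43, 2.64, 1.42, 1.86),
    "FI-N47-20": (64.28, 2.21, 1.82, 0.24),
}

NEONATE_DWT_UG = 489.55
DAY6_DWT_UG = 575.91
NEONATE_DWT_SD = 32.21
DAY6_DWT_SD = 31.85

RANDOM_PARAMS = ("g0", "ginf", "KS")


def reference_size_law() -> SizeLaw:
    """Ordinary least squares of the per-clone KS anchors on body size.

    Gives K0 ~ -1.24 ug EPA mg C^-1 and KL ~ 1.04 ug EPA mg C^-1 mm^-1;
    the anchors deviate from the fitted line by < 0.005 everywhere, so the
    linear size law reproduces them essentially exactly.
    """
    L = np.array([c.body_size_L for c in DEFAULT_CLONES])
    ks = np.array([KS_ANCHORS[c.clone_id] for c in DEFAULT_CLONES])
    X = np.column_stack([np.ones_like(L), L])
    (k0, kl), *_ = np.linalg.lstsq(X, ks, rcond=None)
    return SizeLaw(K0=float(k0), KL=float(kl))


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated experiment.

    Growth truth: per-clone ``true_g0`` / ``true_ginf`` (day^-1) and a
    size law ``(true_K0, true_KL)`` giving each clone's half-saturation
    constant.  ``random_effect_sd`` maps a subset of {"g0", "ginf", "KS"}
    to the SD of clone-level Gaussian deviations (KS deviations are
    redrawn until the clone's KS stays positive).  ``residual_sd`` is the
    beaker-level Gaussian noise SD (day^-1).
    """

    clones: tuple[CloneInfo, ...] = DEFAULT_CLONES
    epa_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0)
    n_replicates: int = 3
    duration_t: float = 6.0
    true_g0_by_clone: Mapping[str, float] = field(default_factory=dict)
    true_ginf_by_clone: Mapping[str, float] = field(default_factory=dict)
    true_K0: float = 0.0
    true_KL: float = 0.0
    random_effect_sd: Mapping[str, float] = field(default_factory=dict)
    residual_sd: float = 0.02
    seed: int = 0
    # clutch scenario
    clutch_species_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(CLUTCH_ANCHORS)
    )
    eggless_clones: tuple[str, ...] = DEFAULT_EGGLESS
    clutch_sd: float = 0.1  # SD on the saturation-fraction scale
    clutch_scale: float = 8.0  # maximum attainable clutch, eggs
    # fatty-acid scenario
    fa_panel: tuple[str, ...] = tuple(FA_NEONATE_ANCHORS)
    n_fa_replicates: int = 3
    fa_noise_cv: float = 0.15
    neonate_dwt_ug: float = NEONATE_DWT_UG
    day6_dwt_ug: float = DAY6_DWT_UG
    neonate_dwt_sd: float = NEONATE_DWT_SD
    day6_dwt_sd: float = DAY6_DWT_SD

    def true_ks(self, clone: CloneInfo) -> float:
        return self.true_K0 + self.true_KL * clone.body_size_L

    def true_params(self, clone: CloneInfo) -> MonodParams:
        return MonodParams(
            g0=self.true_g0_by_clone[clone.clone_id],
            ginf=self.true_ginf_by_clone[clone.clone_id],
            KS=self.true_ks(clone),
        )

    def validate(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if any(sd < 0 for sd in self.random_effect_sd.values()):
            raise ValueError("random_effect_sd values must be >= 0")
        unknown = set(self.random_effect_sd) - set(RANDOM_PARAMS)
        if unknown:
            raise ValueError(f"unknown random-effect parameter(s): {sorted(unknown)}")
        grid = np.asarray(self.epa_grid, dtype=float)
        if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("epa_grid must be non-negative and strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone ids in config")
        for c in self.clones:
            c.validate()
            if c.clone_id not in self.true_g0_by_clone:
                raise ValueError(f"missing true g0 for clone {c.clone_id!r}")
            if c.clone_id not in self.true_ginf_by_clone:
                raise ValueError(f"missing true ginf for clone {c.clone_id!r}")
            if not self.true_ks(c) > 0:
                raise ValueError(
                    f"true KS non-positive for clone {c.clone_id!r} "
                    f"(K0={self.true_K0}, KL={self.true_KL}, L={c.body_size_L})"
                )

    def noise_free(self) -> "SimulationConfig":
        """Copy of this config with every noise source set to zero."""
        return replace(
            self,
            random_effect_sd={k: 0.0 for k in self.random_effect_sd},
            residual_sd=0.0,
            clutch_sd=0.0,
            fa_noise_cv=0.0,
            neonate_dwt_sd=0.0,
            day6_dwt_sd=0.0,
        )


def default_config(seed: int = 0) -> SimulationConfig:
    """The default simulation scenario.

    Truth values anchor to the motivating study design: baseline growth
    g0 by species (0.174 / 0.312 / 0.432 day^-1 for the small, medium and
    large species), a common asymptote ginf of 0.55 day^-1 (the optimal-
    food growth of the largest species; a common fixed asymptote keeps the
    generative structure inside the fitted model family, with clone
    variation entering through g0 and the size law only), and a
    body-size-dependent half-saturation constant from
    :func:`reference_size_law`.  Clone-level random variation acts on g0
    (SD 0.02 day^-1); beaker residual SD is 0.02 day^-1.
    """
    law = reference_size_law()
    g0 = {c.clone_id: G0_ANCHORS[c.species] for c in DEFAULT_CLONES}
    ginf = {c.clone_id: GINF_COMMON for c in DEFAULT_CLONES}
    cfg = SimulationConfig(
        true_g0_by_clone=g0,
        true_ginf_by_clone=ginf,
        true_K0=law.K0,
        true_KL=law.KL,
        random_effect_sd={"g0": 0.02},
        residual_sd=0.02,
        seed=seed,
    )
    cfg.validate()
    return cfg


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent substreams per simulated product, all keyed to one seed
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def _draw_clone_deviations(
    config: SimulationConfig, clone: CloneInfo, rng: np.random.Generator
) -> dict[str, float]:
    dev = {}
    for p in RANDOM_PARAMS:
        sd = float(config.random_effect_sd.get(p, 0.0))
        dev[p] = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
    if dev["KS"]:
        # truncate: keep the clone's realised KS positive
        base = config.true_ks(clone)
        while base + dev["KS"] <= 0:
            dev["KS"] = float(rng.normal(0.0, config.random_effect_sd["KS"]))
    return dev


def simulate_growth(config: SimulationConfig) -> list[GrowthRecord]:
    """One growth dataset: clone x EPA level x replicate beaker records.

    Each observation is the clone's Monod mean (truth parameters plus the
    clone's random deviations) plus Gaussian residual noise.  With all
    noise SDs zero, every record equals the model mean exactly.
    """
    config.validate()
    rng = _rng(config, 0)
    records = []
    for clone in config.clones:
        dev = _draw_clone_deviations(config, clone, rng)
        p = MonodParams(
            g0=config.true_g0_by_clone[clone.clone_id] + dev["g0"],
            ginf=config.true_ginf_by_clone[clone.clone_id] + dev["ginf"],
            KS=config.true_ks(clone) + dev["KS"],
        )
        for S in config.epa_grid:
            mean = monod_growth(S, p)
            for rep in range(1, config.n_replicates + 1):
                noise = (
                    float(rng.normal(0.0, config.residual_sd))
                    if config.residual_sd > 0
                    else 0.0
                )
                records.append(
                    GrowthRecord(
                        clone_id=clone.clone_id,
                        epa_conc_S=float(S),
                        replicate=rep,
                        growth_rate_g=mean + noise,
                        duration_t=config.duration_t,
                    )
                )
    return records


def _clutch_ainf(config: SimulationConfig, clone: CloneInfo) -> float:
    """Transformed-scale asymptote calibrated so that the grid-average
    clutch of an egg-bearing clone matches its species anchor."""
    from scipy.optimize import brentq

    target = float(config.clutch_species_mean.get(clone.species, 0.0))
    if target <= 0:
        return 0.0
    grid = np.asarray(config.epa_grid, dtype=float)
    m = grid / (grid + config.true_ks(clone))
    cmax = config.clutch_scale

    def grid_mean(ainf):
        return float(np.mean(cmax * np.sin(np.pi * ainf * m / 2.0) ** 2)) - target

    if grid_mean(1.0) < 0:
        raise ValueError(
            f"clutch anchor {target} unattainable for clone {clone.clone_id!r} "
            f"with clutch_scale {cmax}"
        )
    return float(brentq(grid_mean, 0.0, 1.0, xtol=1e-12))


def simulate_clutch(config: SimulationConfig) -> list[ClutchRecord]:
    """One clutch-size dataset on the same treatment grid.

    The generative model mirrors the assumption of the clutch analysis:
    on the arcsin-square-root scale the clutch mean follows the Monod
    curve a(S) = a_inf * S/(S + KS) with each clone's growth
    half-saturation constant, so raw clutches are
    c(S) = clutch_scale * sin(pi*a/2)^2.  The asymptote a_inf is
    calibrated so the grid-average clutch of egg-bearing clones matches
    the species-level anchors (1.31 / 1.35 / 2.48 eggs).  Noise acts on
    the saturation fraction x = c/clutch_scale with SD
    clutch_sd * sqrt(x*(1-x)) — a quasi-binomial mean-variance
    relationship that the arcsin-square-root transform stabilises.
    Clones listed in ``eggless_clones`` produce all-zero clutches; so
    does the S = 0 treatment (no eggs without EPA).
    """
    config.validate()
    rng = _rng(config, 1)
    grid = np.asarray(config.epa_grid, dtype=float)
    records = []
    for clone in config.clones:
        ks = config.true_ks(clone)
        eggless = clone.clone_id in config.eggless_clones
        ainf = 0.0 if eggless else _clutch_ainf(config, clone)
        for S in grid:
            a = ainf * S / (S + ks)
            x = math.sin(math.pi * a / 2.0) ** 2
            for rep in range(1, config.n_replicates + 1):
                if config.clutch_sd > 0 and not eggless:
                    x_obs = x + float(
                        rng.normal(0.0, config.clutch_sd * math.sqrt(x * (1.0 - x)))
                    )
                    x_obs = min(max(x_obs, 0.0), 1.0)
                else:
                    x_obs = x
                records.append(
                    ClutchRecord(
                        clone_id=clone.clone_id,
                        epa_conc_S=float(S),
                        replicate=rep,
                        clutch_size_c=config.clutch_scale * x_obs,
                    )
                )
    return records


def _decompose_totals(
    total_fa: float, total_pufa: float, total_w3: float, epa: float
) -> dict[str, float]:
    """Split totals anchors into FAME-level contents.

    LIN = PUFA - w3 and ALA+ETE = w3 - EPA (clamped at zero where printed
    anchors are internally inconsistent at their rounding precision); the
    w3 remainder is split 80/20 between ALA and ETE; everything that is
    not PUFA is pooled as "other".
    """
    ala_ete = max(total_w3 - epa, 0.0)
    lin = max(total_pufa - total_w3, 0.0)
    pufa = lin + ala_ete + epa
    return {
        "18:2w6": lin,
        "18:3w3": 0.8 * ala_ete,
        "20:3w3": 0.2 * ala_ete,
        "20:5w3": epa,
        "other": max(total_fa - pufa, 0.0),
    }


def _quota_to_day6_content(
    quota: dict[str, float], neonate: dict[str, float], m0: float, m6: float
) -> dict[str, float]:
    # invert the newly-built-biomass quota: C6 = (q*(m6-m0) + C0*m0) / m6
    dm = m6 - m0
    return {k: (quota[k] * dm + neonate[k] * m0) / m6 for k in quota}


def simulate_fattyacids(config: SimulationConfig) -> list[FattyAcidProfile]:
    """Neonate and day-6 fatty-acid samples for the eight-clone sub-panel.

    Clone-level FAME centers derive from the neonate anchors and from the
    newly-built-biomass quota anchors (inverted to day-6 contents using the
    mean sample dry masses).  Sample noise is multiplicative lognormal with
    coefficient of variation ``fa_noise_cv`` and mean one, so clone means
    stay on the centers; dry masses get additive Gaussian noise.
    """
    config.validate()
    rng = _rng(config, 2)
    cv = float(config.fa_noise_cv)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    profiles = []
    for clone_id in config.fa_panel:
        neo = _decompose_totals(*FA_NEONATE_ANCHORS[clone_id])
        quota = _decompose_totals(*FA_QUOTA_ANCHORS[clone_id])
        day6 = _quota_to_day6_content(
            quota, neo, config.neonate_dwt_ug, config.day6_dwt_ug
        )
        for stage, centers, dwt, dwt_sd in (
            ("neonate", neo, config.neonate_dwt_ug, config.neonate_dwt_sd),
            ("day6", day6, config.day6_dwt_ug, config.day6_dwt_sd),
        ):
            for rep in range(1, config.n_fa_replicates + 1):
                mass = dwt + (
                    float(rng.normal(0.0, dwt_sd)) if dwt_sd > 0 else 0.0
                )
                fa = {}
                for k, center in centers.items():
                    if sigma > 0:
                        # mean-one lognormal factor
                        factor = math.exp(
                            float(rng.normal(0.0, sigma)) - 0.5 * sigma * sigma
                        )
                    else:
                        factor = 1.0
                    fa[k] = center * factor
                profiles.append(
                    FattyAcidProfile(
                        clone_id=clone_id,
                        stage=stage,
                        replicate=rep,
                        dry_mass_ug=max(mass, 1.0),
                        fa_content=fa,
                    )
                )
    return profiles
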