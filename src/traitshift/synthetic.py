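"""Synthetic trait-table generator with stored ground truth.

The generator emulates the data structure the analyses assume: a two-factor
latent covariance among eight traits (a hydraulic safety-efficiency axis and
a tissue-investment axis), seedling-to-adult shifts with site, phenology and
growth-form effects, partial pairing of stages within populations, and
per-cell missingness.  Traits are generated on the transformed standardized
scale (log scale for the log-registered traits, z-scored), where the models
operate, and then mapped to natural units through a fixed per-trait
location/scale — log-registered traits therefore have log-normal marginals
and the rest approximately normal marginals.

Generative model for population i with latent factors f_i ~ N(0, diag(factor_sd^2)):

    seedling_i = L_s f_i + eps_i,          eps_i ~ N(0, diag(resid_sd^2))
    adult_i    = L f_i + eps_i + delta_i,  delta_i,t ~ N(alpha_t[site] +
                      beta1_t * deciduous_i + beta2_t * liana_i, sd_t^2)

where L is the full loading matrix and L_s zeroes the axis-1 loadings of the
traits listed in ``decouple_seedling_traits`` (rescaling any remaining
entries of the row to preserve its norm).  For traits that are not
decoupled, adult = seedling + delta exactly, so paired differences follow
the shift model's normal law; decoupled traits regain their hydraulic-axis
component only in adults, reproducing stage-dependent trait coupling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data import LOG_TRAITS, TRAIT_NAMES, PopulationTraits

#: loadings on (hydraulic axis, tissue axis); rows ordered as TRAIT_NAMES;
#: row norms below 1 leave room for the residual SD so trait variance is ~1
DEFAULT_LOADINGS: dict[str, tuple[float, float]] = {
    "LA": (0.0, 0.30),
    "LDMC": (0.0, -0.83),
    "SLA": (0.0, 0.85),
    "WSG": (-0.35, -0.60),
    "TFW": (-0.50, 0.0),
    "d_h": (0.90, 0.0),
    "VD": (-0.87, 0.0),
    "DA_pit": (0.60, 0.0),
}

DEFAULT_RESID_SD: dict[str, float] = {
    "LA": 0.95,
    "LDMC": 0.56,
    "SLA": 0.53,
    "WSG": 0.72,
    "TFW": 0.87,
    "d_h": 0.44,
    "VD": 0.49,
    "DA_pit": 0.80,
}

#: natural-unit mapping on the transformed scale: value = center + scale * z
#: (exponentiated for log-registered traits); chosen to give realistic
#: magnitudes for tropical dry-forest woody plants
NATURAL_CENTER: dict[str, float] = {
    "LA": 2.5, "LDMC": 0.40, "SLA": 5.0, "WSG": 0.60,
    "TFW": 2.5, "d_h": 3.6, "VD": 4.6, "DA_pit": 1.0,
}
NATURAL_SCALE: dict[str, float] = {
    "LA": 1.0, "LDMC": 0.08, "SLA": 0.5, "WSG": 0.12,
    "TFW": 0.5, "d_h": 0.4, "VD": 0.7, "DA_pit": 0.4,
}


@dataclass(frozen=True)
class TraitShift:
    """Shift-model parameters for one trait: site intercepts and covariate effects."""

    alpha: tuple[float, float, float, float]
    beta_deciduous: float = 0.0
    beta_liana: float = 0.0
    sd: float = 0.75

    def mean(self, site: int, deciduous: int, liana: int) -> float:
        return self.alpha[site - 1] + self.beta_deciduous * deciduous + self.beta_liana * liana


def _default_trait_shifts() -> dict[str, TraitShift]:
    """Per-trait shift parameters with magnitudes typical of tropical
    dry-forest trees: SLA drops by about one pooled SD (more steeply for
    deciduous species), vessel diameter rises by about one SD (more steeply
    for lianas), DA_pit drops sharply (a measurement-protocol artifact
    between stages), LDMC/WSG/LA rise moderately and VD barely moves.
    Site intercepts are centred on each trait's overall shift with modest
    site-to-site spread; residual SDs reflect realistic per-population
    scatter in shift magnitude.
    """

    def centred(m: float, offsets: tuple[float, float, float, float]) -> tuple[float, ...]:
        return tuple(m + o for o in offsets)

    return {
        "LA": TraitShift(centred(0.41, (0.3, -0.1, 0.1, -0.3)), sd=0.60),
        "LDMC": TraitShift(centred(0.48, (-0.2, -0.2, 0.3, 0.1)), sd=0.85),
        "SLA": TraitShift(
            centred(-0.83, (0.3, 0.1, -0.2, -0.2)),
            beta_deciduous=-0.710, beta_liana=0.567, sd=0.80,
        ),
        "WSG": TraitShift(centred(0.33, (0.0, 0.25, -0.25, 0.0)), sd=0.65),
        "TFW": TraitShift(centred(0.36, (0.1, -0.6, 0.1, 0.4)), sd=1.10),
        "d_h": TraitShift(centred(0.90, (0.0, 0.0, 0.0, 0.0)), beta_liana=0.728, sd=0.95),
        "VD": TraitShift(centred(0.35, (0.0, 0.0, 0.0, 0.0)), beta_deciduous=-0.654, sd=1.05),
        "DA_pit": TraitShift(centred(-2.03, (0.0, 0.0, 0.0, 0.0)), sd=0.60),
    }


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a realistic field campaign.

    Four sites with ``n_populations_per_site`` populations each; a population
    is observed at both stages with probability ``p_paired``, otherwise only
    as an adult with conditional probability ``p_adult_only`` (else only as a
    seedling).  The defaults give roughly 40 paired, ~220 adult and ~60
    seedling populations — the kind of stage-imbalanced composition a
    dry-forest trait campaign actually yields (adults are censused in
    permanent plots; far fewer species are relocated as seedlings).
    """

    n_populations_per_site: int = 61
    p_paired: float = 0.16
    p_adult_only: float = 0.90
    trait_names: tuple[str, ...] = TRAIT_NAMES
    loadings_true: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    factor_sd: tuple[float, float] = (1.0, 1.0)
    resid_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RESID_SD))
    trait_shifts: Mapping[str, TraitShift] = field(default_factory=_default_trait_shifts)
    p_deciduous: float = 0.40
    p_liana: float = 0.15
    missing_rate: float = 0.03
    decouple_seedling_traits: tuple[str, ...] = ("DA_pit", "TFW")
    seed: int = 0

    @classmethod
    def uniform_shift(
        cls,
        shift_alpha: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
        shift_beta_deciduous: float = 0.0,
        shift_beta_liana: float = 0.0,
        shift_resid_sd: float = 0.75,
        **kwargs: object,
    ) -> "SyntheticConfig":
        """Config with one (alpha_k, beta1, beta2, sigma) set shared by all traits."""
        shift = TraitShift(
            tuple(float(a) for a in shift_alpha),
            float(shift_beta_deciduous),
            float(shift_beta_liana),
            float(shift_resid_sd),
        )
        return cls(trait_shifts={t: shift for t in TRAIT_NAMES}, **kwargs)

    def validate(self) -> None:
        if self.n_populations_per_site < 1:
            raise ValueError("n_populations_per_site must be >= 1")
        for name, p in (
            ("p_paired", self.p_paired),
            ("p_adult_only", self.p_adult_only),
            ("p_deciduous", self.p_deciduous),
            ("p_liana", self.p_liana),
            ("missing_rate", self.missing_rate),
        ):
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for t in self.trait_names:
            if t not in self.loadings_true:
                raise ValueError(f"loadings_true missing a row for trait {t}")
            if t not in self.resid_sd or self.resid_sd[t] <= 0:
                raise ValueError(f"resid_sd must be positive for trait {t}")
            if t not in self.trait_shifts:
                raise ValueError(f"trait_shifts missing trait {t}")
            if self.trait_shifts[t].sd < 0:
                raise ValueError(f"shift sd must be >= 0 for trait {t}")
            if len(self.trait_shifts[t].alpha) != 4:
                raise ValueError(f"shift alpha must have 4 site entries for trait {t}")
        if any(s <= 0 for s in self.factor_sd):
            raise ValueError("factor_sd entries must be positive")
        unknown = set(self.decouple_seedling_traits) - set(self.trait_names)
        if unknown:
            raise ValueError(f"decouple_seedling_traits not in trait set: {sorted(unknown)}")

    def loading_matrix(self, stage: str) -> np.ndarray:
        """Loading matrix for a stage; seedlings use the decoupled rows."""
        L = np.array([self.loadings_true[t] for t in self.trait_names], dtype=float)
        if stage == "seedling":
            for t in self.decouple_seedling_traits:
                i = self.trait_names.index(t)
                norm = np.linalg.norm(L[i])
                L[i, 0] = 0.0
                rest = np.linalg.norm(L[i])
                if rest > 0:  # preserve the row's communality where possible
                    L[i] *= norm / rest
        return L


@dataclass
class GroundTruth:
    """Generator bookkeeping for recovery tests."""

    trait_names: tuple[str, ...]
    loadings_seedling: np.ndarray
    loadings_adult: np.ndarray
    trait_shifts: dict[str, TraitShift]
    true_overall_shift: dict[str, float]  # E[delta] over the covariate mix
    realized_paired_shift: dict[str, float]  # mean mu_i over generated paired pops
    corr_seedling: np.ndarray
    corr_adult: np.ndarray
    factor_scores: dict[tuple[str, int], tuple[float, float]]
    paired_deltas: dict[str, dict[tuple[str, int], float]]  # generation-scale deltas
    reference_center: np.ndarray  # natural->generation-scale mapping, per trait
    reference_scale: np.ndarray

    def to_json(self, path: str | Path) -> None:
        def pop_key(k: tuple[str, int]) -> str:
            return f"{k[0]}|{k[1]}"

        payload = {
            "trait_names": list(self.trait_names),
            "loadings_seedling": self.loadings_seedling.tolist(),
            "loadings_adult": self.loadings_adult.tolist(),
            "trait_shifts": {t: asdict(s) for t, s in self.trait_shifts.items()},
            "true_overall_shift": self.true_overall_shift,
            "realized_paired_shift": self.realized_paired_shift,
            "corr_seedling": self.corr_seedling.tolist(),
            "corr_adult": self.corr_adult.tolist(),
            "factor_scores": {pop_key(k): list(v) for k, v in self.factor_scores.items()},
            "paired_deltas": {
                t: {pop_key(k): v for k, v in d.items()} for t, d in self.paired_deltas.items()
            },
            "reference_center": self.reference_center.tolist(),
            "reference_scale": self.reference_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def implied_correlation(config: SyntheticConfig, stage: str) -> np.ndarray:
    """Exact population correlation of the generator on the transformed scale.

    cov = L diag(factor_sd^2) L' + diag(resid_sd^2), with the shift noise
    sd^2 added to the adult diagonal (it is residual variance for adults).
    Conditional on site, phenology and growth form.
    """
    config.validate()
    if stage not in ("seedling", "adult"):
        raise ValueError("stage must be 'seedling' or 'adult'")
    L = config.loading_matrix(stage)
    resid = np.array([config.resid_sd[t] ** 2 for t in config.trait_names])
    if stage == "adult":
        resid = resid + np.array([config.trait_shifts[t].sd ** 2 for t in config.trait_names])
    cov = L @ np.diag(np.square(config.factor_sd)) @ L.T + np.diag(resid)
    d = 1.0 / np.sqrt(np.diag(cov))
    return cov * np.outer(d, d)


_BOUNDS = {"LDMC": (0.0, 1.0, True), "WSG": (0.0, 2.0, False), "TFW": (0.0, math.inf, False)}
_MAX_RETRIES = 200


def _natural_value(trait: str, z: float) -> float:
    x = NATURAL_CENTER[trait] + NATURAL_SCALE[trait] * z
    return math.exp(x) if trait in LOG_TRAITS else x


def _in_bounds(trait: str, value: float) -> bool:
    lo, hi, hi_incl = _BOUNDS.get(trait, (0.0, math.inf, False))
    if trait in LOG_TRAITS:
        return value > 0
    return value > lo and (value <= hi if hi_incl else value < hi)


def generate_dataset(config: SyntheticConfig) -> tuple[list[PopulationTraits], GroundTruth]:
    """Generate a trait table plus the ground truth needed for recovery tests.

    The RNG stream is fully determined by ``config.seed``; the same config
    yields a bit-identical table.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(int(config.seed)))
    traits = config.trait_names
    p = len(traits)
    L_s = config.loading_matrix("seedling")
    L_a = config.loading_matrix("adult")
    resid_sd = np.array([config.resid_sd[t] for t in traits])
    fac_sd = np.asarray(config.factor_sd, dtype=float)

    records: list[PopulationTraits] = []
    factor_scores: dict[tuple[str, int], tuple[float, float]] = {}
    paired_deltas: dict[str, dict[tuple[str, int], float]] = {t: {} for t in traits}
    realized_mu: dict[str, list[float]] = {t: [] for t in traits}

    counter = 0
    for site in (1, 2, 3, 4):
        for _ in range(config.n_populations_per_site):
            counter += 1
            species = f"sp{counter:04d}"
            pop = (species, site)
            deciduous = int(rng.random() < config.p_deciduous)
            liana = int(rng.random() < config.p_liana)
            f = fac_sd * rng.standard_normal(2)
            eps = resid_sd * rng.standard_normal(p)
            z_seedling = L_s @ f + eps
            mu = np.array(
                [config.trait_shifts[t].mean(site, deciduous, liana) for t in traits]
            )
            shift_sd = np.array([config.trait_shifts[t].sd for t in traits])
            delta = mu + shift_sd * rng.standard_normal(p)
            z_adult = L_a @ f + eps + delta

            # bounded traits: resample the offending residual/shift draw
            for j, t in enumerate(traits):
                for z_vec, redraw_shift in ((z_seedling, False), (z_adult, True)):
                    tries = 0
                    while not _in_bounds(t, _natural_value(t, z_vec[j])):
                        tries += 1
                        if tries > _MAX_RETRIES:
                            raise RuntimeError(
                                f"could not draw an in-bounds value for {t} "
                                f"(population {pop}); check natural-scale settings"
                            )
                        if redraw_shift:
                            delta[j] = mu[j] + shift_sd[j] * rng.standard_normal()
                            z_adult[j] = (L_a @ f)[j] + eps[j] + delta[j]
                        else:
                            eps[j] = resid_sd[j] * rng.standard_normal()
                            z_seedling[j] = (L_s @ f)[j] + eps[j]
                            z_adult[j] = (L_a @ f)[j] + eps[j] + delta[j]

            u = rng.random()
            if u < config.p_paired:
                stages = ("seedling", "adult")
            elif rng.random() < config.p_adult_only:
                stages = ("adult",)
            else:
                stages = ("seedling",)

            factor_scores[pop] = (float(f[0]), float(f[1]))
            if len(stages) == 2:
                for j, t in enumerate(traits):
                    paired_deltas[t][pop] = float(z_adult[j] - z_seedling[j])
                    realized_mu[t].append(float(mu[j]))

            for stage in stages:
                z_vec = z_seedling if stage == "seedling" else z_adult
                values: dict[str, float | None] = {}
                for j, t in enumerate(traits):
                    if config.missing_rate > 0 and rng.random() < config.missing_rate:
                        values[t] = None
                    else:
                        values[t] = _natural_value(t, z_vec[j])
                records.append(
                    PopulationTraits(
                        species_id=species,
                        site_id=site,
                        stage=stage,
                        phenology="deciduous" if deciduous else "evergreen",
                        growth_form="liana" if liana else "free_standing",
                        traits=values,
                    )
                )

    true_overall = {
        t: float(
            np.mean(config.trait_shifts[t].alpha)
            + config.trait_shifts[t].beta_deciduous * config.p_deciduous
            + config.trait_shifts[t].beta_liana * config.p_liana
        )
        for t in traits
    }
    truth = GroundTruth(
        trait_names=traits,
        loadings_seedling=L_s,
        loadings_adult=L_a,
        trait_shifts=dict(config.trait_shifts),
        true_overall_shift=true_overall,
        realized_paired_shift={
            t: (float(np.mean(v)) if v else math.nan) for t, v in realized_mu.items()
        },
        corr_seedling=implied_correlation(config, "seedling"),
        corr_adult=implied_correlation(config, "adult"),
        factor_scores=factor_scores,
        paired_deltas=paired_deltas,
        reference_center=np.array([NATURAL_CENTER[t] for t in traits]),
        reference_scale=np.array([NATURAL_SCALE[t] for t in traits]),
    )
    return records, truth
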