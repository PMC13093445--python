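"""Synthetic avian-style trait tables with known generative structure.

Real specimen tables of bird morphometrics have a characteristic shape:
strictly positive, right-skewed measurements that covary strongly through
overall body size (allometry), plus species-level shifts, a sex
dimorphism, and measurement noise. The generator reproduces exactly that
on the natural-log scale:

    log trait_t(i) = intercept_t + loading_t * size_i + u_species(i)
                     + sex_effect * sex_i + eps_{it}

with latent size ~ N(0, 1) per individual, species effects
u_s ~ N(0, species_sd^2) shared across that species' traits and
individuals, sex coded 0/1, and independent noise eps ~ N(0, noise_sd^2).
Raw traits are the exponentials, so they are always positive. Because the
model is linear-Gaussian on the log scale, the population R² of the best
predictor of any log trait from any subset of the others has a closed
form (:func:`oracle_ceiling`), which provides an exact performance
ceiling for testing imputers.

Missingness is injected per trait either completely at random (MCAR) or
at random conditional on an always-observed driver trait (MAR, logistic
in the driver with the intercept calibrated to hit the requested rate).
Default per-trait rates mirror the heterogeneous pattern typical of trait
databases: one trait missing in about half the rows, another in about a
third, the rest nearly complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .trait_io import CATEGORICAL, CONTINUOUS, TraitTable

__all__ = [
    "DEFAULT_TRAITS",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "inject_missingness",
    "simulate",
    "oracle_ceiling",
]

#: the 11 standard individual-level morphometric columns the generator emulates
DEFAULT_TRAITS = [
    "Beak.Length_Culmen",
    "Beak.Length_Nares",
    "Beak.Width",
    "Beak.Depth",
    "Tarsus.Length",
    "Wing.Length",
    "Kipps.Distance",
    "Secondary1",
    "Hand-wing.Index",
    "Tail.Length",
    "Mass",
]

# typical log-scale baselines (log mm, log g for Mass) for a mid-sized passerine
_DEFAULT_INTERCEPTS = {
    "Beak.Length_Culmen": 2.9,
    "Beak.Length_Nares": 2.4,
    "Beak.Width": 1.6,
    "Beak.Depth": 1.7,
    "Tarsus.Length": 3.2,
    "Wing.Length": 4.6,
    "Kipps.Distance": 3.2,
    "Secondary1": 4.3,
    "Hand-wing.Index": 3.3,
    "Tail.Length": 4.3,
    "Mass": 3.4,
}

_DEFAULT_MISSING_RATES = {
    "Beak.Length_Nares": 0.52,
    "Kipps.Distance": 0.36,
}
_DEFAULT_OTHER_RATE = 0.05

#: fraction of log-trait variance attributable to the shared structure
#: (size + species + sex) under the default configuration
DEFAULT_SIGNAL_FRACTION = 0.95


@dataclass
class SyntheticConfig:
    """Generative settings; defaults give ~95% shared (predictable) variance."""

    n_species: int = 40
    individuals_per_species: int = 25
    trait_loadings: dict[str, float] = field(default_factory=dict)
    trait_intercepts: dict[str, float] = field(default_factory=dict)
    species_sd: float = 0.3
    sex_effect: float = 0.1
    noise_sd: float | None = None  # None -> derived from DEFAULT_SIGNAL_FRACTION
    missing_rates: dict[str, float] = field(default_factory=dict)
    mechanism: str = "MCAR"
    mar_driver: str = "Mass"
    mar_slope: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.trait_loadings = {
            t: self.trait_loadings.get(t, 1.0) for t in self.traits
        }
        self.trait_intercepts = {
            t: self.trait_intercepts.get(t, _DEFAULT_INTERCEPTS.get(t, 3.0))
            for t in self.traits
        }
        if not self.missing_rates:
            self.missing_rates = {
                t: _DEFAULT_MISSING_RATES.get(t, _DEFAULT_OTHER_RATE)
                for t in self.traits
            }
        for t, r in self.missing_rates.items():
            if not (0.0 <= r < 1.0):
                raise ValueError(f"missing rate for {t!r} must lie in [0, 1): {r}")
        if self.species_sd < 0 or self.sex_effect < 0:
            raise ValueError("species_sd and sex_effect must be nonnegative")
        if self.noise_sd is None:
            self.noise_sd = self._noise_sd_for_signal_fraction(DEFAULT_SIGNAL_FRACTION)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")

    @property
    def traits(self) -> list[str]:
        if self.trait_loadings and set(self.trait_loadings) != set(DEFAULT_TRAITS):
            return list(self.trait_loadings)
        return list(DEFAULT_TRAITS)

    def _noise_sd_for_signal_fraction(self, fraction: float) -> float:
        # shared variance of a loading-1 trait: size (var 1) + species + sex
        signal = 1.0 + self.species_sd**2 + self.sex_effect**2 * 0.25
        return float(np.sqrt(signal * (1.0 - fraction) / fraction))


@dataclass
class GroundTruth:
    """Everything needed to score an imputer against the generative truth."""

    complete: TraitTable
    latent_size: np.ndarray
    species_effects: dict[str, float]
    mask: pd.DataFrame | None = None


def generate(config: SyntheticConfig) -> tuple[TraitTable, GroundTruth]:
    """Draw a complete (no missing cells) trait table from the model."""
    rng = np.random.default_rng(config.seed)
    traits = config.traits
    n = config.n_species * config.individuals_per_species

    species_names = [f"sp{s:03d}" for s in range(config.n_species)]
    species = np.repeat(species_names, config.individuals_per_species)
    u = rng.normal(0.0, config.species_sd, size=config.n_species)
    species_effects = dict(zip(species_names, u.tolist()))
    u_per_row = np.repeat(u, config.individuals_per_species)

    size = rng.normal(0.0, 1.0, size=n)
    sex_code = rng.integers(0, 2, size=n)
    sex = np.where(sex_code == 1, "M", "F")

    data = {}
    for t in traits:
        log_vals = (
            config.trait_intercepts[t]
            + config.trait_loadings[t] * size
            + u_per_row
            + config.sex_effect * sex_code
            + rng.normal(0.0, config.noise_sd, size=n)
        )
        data[t] = np.exp(log_vals)
    data["Species"] = species
    data["Sex"] = sex

    kinds = {t: CONTINUOUS for t in traits}
    kinds["Species"] = CATEGORICAL
    kinds["Sex"] = CATEGORICAL
    table = TraitTable(data=pd.DataFrame(data), column_kinds=kinds)
    truth = GroundTruth(
        complete=table.copy(), latent_size=size, species_effects=species_effects
    )
    return table, truth


def inject_missingness(
    table: TraitTable, config: SyntheticConfig
) -> tuple[TraitTable, pd.DataFrame]:
    """Mask trait cells per the configured mechanism; returns (table, mask).

    MCAR masks each cell independently at its per-trait rate. MAR masks
    with probability logistic in the (standardized) driver trait, with the
    intercept solved so the realized expected rate matches the request;
    the driver itself must remain fully observed.
    """
    if config.mechanism == "MAR":
        if config.missing_rates.get(config.mar_driver, 0.0) > 0:
            raise ValueError(
                f"MAR driver {config.mar_driver!r} must stay fully observed "
                "(set its missing rate to 0)"
            )
        if config.mar_driver not in table.columns:
            raise ValueError(f"MAR driver {config.mar_driver!r} not in table")

    rng = np.random.default_rng(config.seed + 1)  # independent of generation
    out = table.copy()
    mask = pd.DataFrame(False, index=table.data.index, columns=table.columns)

    if config.mechanism == "MAR":
        driver = np.log(table.data[config.mar_driver].to_numpy(dtype=float))
        z = (driver - driver.mean()) / max(driver.std(), 1e-12)

    for t, rate in config.missing_rates.items():
        if rate == 0 or t not in table.columns:
            continue
        if config.mechanism == "MCAR":
            hit = rng.random(table.n_rows) < rate
        else:
            def mean_rate(a, _z=z):
                return float(np.mean(expit(a + config.mar_slope * _z))) - rate

            a = brentq(mean_rate, -40.0, 40.0)
            hit = rng.random(table.n_rows) < expit(a + config.mar_slope * z)
        mask[t] = hit
        out.data.loc[mask[t].to_numpy(), t] = np.nan
    return out, mask


def simulate(config: SyntheticConfig) -> tuple[TraitTable, GroundTruth]:
    """Generate a table and inject missingness; the truth records the mask."""
    complete, truth = generate(config)
    masked, mask = inject_missingness(complete, config)
    truth.mask = mask
    return masked, truth


def _covariance(config: SyntheticConfig, variables: list[str]) -> np.ndarray:
    """Closed-form covariance of the listed log traits (plus optional 'Sex')."""
    n = len(variables)
    cov = np.empty((n, n))
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if a == "Sex" and b == "Sex":
                cov[i, j] = 0.25
            elif a == "Sex" or b == "Sex":
                cov[i, j] = config.sex_effect * 0.25
            else:
                c = (
                    config.trait_loadings[a] * config.trait_loadings[b]
                    + config.species_sd**2
                    + config.sex_effect**2 * 0.25
                )
                if a == b:
                    c += config.noise_sd**2
                cov[i, j] = c
    return cov


def oracle_ceiling(config: SyntheticConfig, target: str, combo: list[str]) -> float:
    """Population R² of the best linear predictor of the log target.

    Computed from the generative covariance structure; because the model
    is linear-Gaussian on the log scale, no predictor (linear or not) can
    exceed this in expectation. ``combo`` may contain trait names and
    ``"Sex"``; the integer-coded species column has no closed linear form
    and is rejected.
    """
    if "Species" in combo:
        raise ValueError("no closed-form ceiling for the species label column")
    variables = [target] + list(combo)
    cov = _covariance(config, variables)
    var_y = cov[0, 0]
    sigma_xy = cov[1:, 0]
    sigma_xx = cov[1:, 1:]
    explained = float(sigma_xy @ np.linalg.solve(sigma_xx, sigma_xy))
    return explained / var_y
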