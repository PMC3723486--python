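"""Synthetic cohort generation for the GRS x physical-activity study design.

Emulates the statistical structure the interaction analysis and the power
study assume: 12 bi-allelic genotypes under Hardy-Weinberg proportions, a
genetic risk score (GRS) ~ Normal(11.2, 5.06) in allele units, a binary
physical-activity exposure with 30% inactive (optionally correlated with
the GRS through a latent-Gaussian copula), and BMI as a linear function of
GRS, activity and their product with Gaussian residual noise.

Every generator takes an explicit integer seed; identical spec + seed
reproduces an identical cohort bit-for-bit.  Multi-cohort runs derive
per-cohort seeds from the master seed via ``SeedSequence((master, index))``
so each cohort is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grs import GenotypeMatrix, PANEL_RSIDS

# Default per-locus risk-allele frequencies: two blocks chosen so the
# genotype-built GRS matches the moments the power study assumes,
# sum(2f) = 11.2 alleles and sum(2f(1-f)) ~= 5.06 alleles^2.
_F_LO, _F_HI = 0.271527, 0.661806
DEFAULT_RISK_FREQS: tuple[float, ...] = (_F_LO, _F_HI) * 6


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of one simulated cohort.

    Effect sizes are on the BMI scale (kg/m^2): ``beta_g`` per GRS allele,
    ``beta_e`` for active (=1) vs inactive (=0), ``beta_ge`` per allele per
    activity unit.  ``sigma_bmi`` is the residual SD of BMI given the
    predictors.  Defaults are the base study conditions: GRS ~
    Normal(11.2, 5.06), 30% inactive, beta_g = 0.154, beta_e = -0.313,
    beta_ge = -0.07, sigma = 3.5.
    """

    n_participants: int
    risk_allele_freqs: tuple[float, ...] = DEFAULT_RISK_FREQS
    grs_mean: float = 11.2
    grs_variance: float = 5.06
    p_inactive: float = 0.30
    rho_grs_activity: float = 0.0
    beta_g: float = 0.154
    beta_e: float = -0.313
    beta_ge: float = -0.07
    sigma_bmi: float = 3.5
    intercept: float = 25.0
    seed: int = 0
    cohort_id: str = "cohort_1"
    with_genotypes: bool = False

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        freqs = np.asarray(self.risk_allele_freqs, dtype=float)
        if len(freqs) != 12:
            raise ValueError("risk_allele_freqs must list 12 loci")
        if not np.all((freqs > 0) & (freqs < 1)):
            bad = PANEL_RSIDS[int(np.argmax(~((freqs > 0) & (freqs < 1))))]
            raise ValueError(f"risk-allele frequency out of (0,1) at {bad}")
        if self.grs_variance <= 0:
            raise ValueError("grs_variance must be > 0")
        if not (0 < self.p_inactive < 1):
            raise ValueError("p_inactive must lie in (0,1)")
        if not (-1 < self.rho_grs_activity < 1):
            raise ValueError("rho_grs_activity must lie in (-1,1)")
        if self.sigma_bmi < 0:
            raise ValueError("sigma_bmi must be >= 0")
        for name in ("beta_g", "beta_e", "beta_ge", "intercept"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimulatedCohort:
    """One generated cohort: participant table plus optional genotypes."""

    data: pd.DataFrame
    spec: CohortSpec
    genotypes: GenotypeMatrix | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.data["bmi"]).all():
            raise ValueError("non-finite BMI generated")

    @property
    def cohort_id(self) -> str:
        return self.spec.cohort_id

    def __len__(self) -> int:
        return len(self.data)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(n: int, freqs: Sequence[float] = DEFAULT_RISK_FREQS,
                       seed=0) -> GenotypeMatrix:
    """Draw HWE genotypes: dosage at each locus ~ Binomial(2, freq), loci
    independent, columns in the canonical 12-locus panel order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    for rsid, f in zip(PANEL_RSIDS, freqs):
        if not np.isfinite(f) or not (0 < f < 1):
            raise ValueError(f"invalid risk-allele frequency {f!r} at {rsid}")
    rng = _rng(seed)
    dosages = rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)
    frame = pd.DataFrame(dosages, columns=list(PANEL_RSIDS[: len(freqs)]))
    return GenotypeMatrix(frame, coded_alleles={r: "A" for r in frame.columns})


def simulate_grs_direct(n: int, mean: float = 11.2, variance: float = 5.06,
                        seed=0) -> np.ndarray:
    """GRS drawn directly from Normal(mean, variance), bypassing genotypes."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    rng = _rng(seed)
    return rng.normal(mean, np.sqrt(variance), size=n)


def latent_correlation(rho: float, p_inactive: float) -> float:
    """Latent-Gaussian correlation inducing a target GRS-activity
    point-biserial correlation.

    The active indicator is A = 1{Z >= z_p} with z_p the p_inactive
    quantile of the latent standard normal Z, correlated rho_lat with the
    standardized GRS.  Then corr(GRS, A) = rho_lat * phi(z_p) /
    sqrt(p(1-p)), so rho_lat = rho * sqrt(p(1-p)) / phi(z_p).
    """
    z_p = norm.ppf(p_inactive)
    rho_lat = rho * np.sqrt(p_inactive * (1 - p_inactive)) / norm.pdf(z_p)
    if abs(rho_lat) >= 1:
        raise ValueError(
            f"requested correlation {rho} infeasible at p_inactive={p_inactive}"
        )
    return float(rho_lat)


def simulate_activity(grs: np.ndarray, p_inactive: float = 0.30,
                      rho: float = 0.0, seed=0) -> np.ndarray:
    """Binary activity (0 = inactive, 1 = active) with marginal inactive
    proportion ``p_inactive``.

    rho = 0 gives i.i.d. Bernoulli(1 - p_inactive).  Otherwise a Gaussian
    copula: a latent normal correlated with the standardized GRS (see
    :func:`latent_correlation`) is thresholded at the p_inactive quantile,
    preserving the marginal exactly in expectation while the realized
    point-biserial GRS-activity correlation approximates rho.
    """
    grs = np.asarray(grs, dtype=float)
    if grs.size == 0:
        raise ValueError("empty GRS vector")
    if not (0 < p_inactive < 1):
        raise ValueError("p_inactive must lie in (0,1)")
    rng = _rng(seed)
    n = grs.size
    z_p = norm.ppf(p_inactive)
    if rho == 0:
        return (rng.random(n) >= p_inactive).astype(float)
    rho_lat = latent_correlation(rho, p_inactive)
    sd = grs.std()
    z_g = (grs - grs.mean()) / sd if sd > 0 else np.zeros(n)
    latent = rho_lat * z_g + np.sqrt(1 - rho_lat**2) * rng.standard_normal(n)
    return (latent >= z_p).astype(float)


def simulate_bmi(grs: np.ndarray, activity: np.ndarray, spec: CohortSpec,
                 seed=0) -> np.ndarray:
    """BMI_i = intercept + b_G GRS_i + b_E A_i + b_GE GRS_i A_i + eps_i,
    eps ~ Normal(0, sigma^2); activity coded 1 = active."""
    grs = np.asarray(grs, dtype=float)
    activity = np.asarray(activity, dtype=float)
    if grs.shape != activity.shape:
        raise ValueError("grs and activity must be conformable")
    rng = _rng(seed)
    mu = (spec.intercept + spec.beta_g * grs + spec.beta_e * activity
          + spec.beta_ge * grs * activity)
    return mu + rng.normal(0.0, spec.sigma_bmi, size=grs.shape)


def inject_missing_genotypes(geno: GenotypeMatrix, rate: float,
                             seed=0) -> GenotypeMatrix:
    """Set each dosage entry missing (NaN) independently with probability
    ``rate``; supports testing of the GRS imputation rule."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0,1]")
    out = geno.copy()
    if rate == 0:
        return out
    rng = _rng(seed)
    mask = rng.random(out.dosages.shape) < rate
    vals = out.dosages.to_numpy(dtype=float)
    vals[mask] = np.nan
    out.dosages = pd.DataFrame(vals, columns=out.dosages.columns,
                               index=out.dosages.index)
    return out


# Conditional CPAI level probabilities among the active (levels 2-4),
# shaped after the observed activity distribution of large European cohorts.
_ACTIVE_LEVEL_P = (0.382, 0.328, 0.290)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate one full cohort table per ``spec``.

    GRS is drawn from its normal law (or built by summing HWE genotypes
    when ``spec.with_genotypes``); activity, BMI follow the linear
    interaction model.  Age ~ Uniform(30, 70) and sex ~ Bernoulli(0.5) are
    pure noise covariates (no effect on BMI), included so downstream model
    adjustment is exercised.  A 4-level CPAI consistent with the binary
    variable is attached (level 1 = inactive).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    genotypes = None
    if spec.with_genotypes:
        genotypes = simulate_genotypes(n, spec.risk_allele_freqs, seed=rng)
        grs = genotypes.dosages.sum(axis=1).to_numpy(dtype=float)
    else:
        grs = simulate_grs_direct(n, spec.grs_mean, spec.grs_variance, seed=rng)
    activity = simulate_activity(grs, spec.p_inactive, spec.rho_grs_activity,
                                 seed=rng)
    bmi = simulate_bmi(grs, activity, spec, seed=rng)
    cpai = np.ones(n, dtype=int)
    active_idx = activity == 1
    cpai[active_idx] = rng.choice([2, 3, 4], size=int(active_idx.sum()),
                                  p=_ACTIVE_LEVEL_P)
    data = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "cohort_id": spec.cohort_id,
        "grs": grs,
        "activity_binary": activity,
        "activity_cpai": cpai,
        "age": rng.uniform(30, 70, size=n),
        "sex": rng.integers(0, 2, size=n),
        "height_m": rng.normal(1.70, 0.09, size=n),
        "bmi": bmi,
    })
    return SimulatedCohort(data=data, spec=spec, genotypes=genotypes)


def simulate_multi_cohort(
    specs: Sequence[CohortSpec],
    between_cohort_sd_of_beta_ge: float = 0.0,
    master_seed: int = 0,
) -> list[SimulatedCohort]:
    """Generate several cohorts with (optionally) heterogeneous interaction
    effects.

    Each cohort's beta_ge is drawn Normal(its spec's beta_ge,
    between_cohort_sd^2); per-cohort data seeds come from
    ``SeedSequence((master_seed, index))`` so any single cohort can be
    regenerated without the others.
    """
    if not specs:
        raise ValueError("at least one CohortSpec required")
    if between_cohort_sd_of_beta_ge < 0:
        raise ValueError("between-cohort SD must be >= 0")
    effect_rng = np.random.default_rng(np.random.SeedSequence((master_seed, 2**16)))
    out = []
    for i, spec in enumerate(specs):
        beta_ge_i = effect_rng.normal(spec.beta_ge, between_cohort_sd_of_beta_ge)
        child_seed = int(np.random.SeedSequence((master_seed, i)).generate_state(1)[0] % (2**31))
        cohort_spec = replace(
            spec, beta_ge=float(beta_ge_i), seed=child_seed,
            cohort_id=spec.cohort_id if spec.cohort_id != "cohort_1" else f"cohort_{i + 1}",
        )
        out.append(simulate_cohort(cohort_spec))
    return out
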