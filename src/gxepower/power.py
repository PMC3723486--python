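"""Monte-Carlo power and sample-size framework for GRS x activity
interaction tests.

The data-generating model is the linear BMI model
``y = b0 + bG*G + bE*A + bGE*G*A + eps`` with ``eps ~ N(0, sigma^2)``,
G a Normal(grs_mean, grs_variance) genetic risk score (optionally
dichotomized at its mean into a 0/1 indicator of variance ~0.25) and A a
binary activity variable with a given inactive prevalence (optionally a
normal variable with the same mean/variance, the coding under which
predictor correlation raises power).  Each iteration fits OLS with both
marginal terms and the product term and performs a two-sided Wald z test
on the interaction coefficient.

A closed-form oracle uses the noncentrality parameter
``lambda = n * bGE^2 * v / sigma^2`` where ``v`` is the residualized
variance of the product term: ``Var(G_eff) * p(1-p)`` for independent
predictors, times ``(1 + rho^2)`` for jointly normal correlated
predictors.  Power = Phi(sqrt(lambda) - z_{1-a/2}) +
Phi(-sqrt(lambda) - z_{1-a/2}).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import latent_correlation

logger = logging.getLogger(__name__)

#: Variance of a mean-cut indicator of a normal variable: p(1-p) at p = 1/2.
DICHOTOMIZED_GRS_VARIANCE = 0.25

_SWEEPABLE = ("n", "beta_g", "beta_e", "beta_ge", "grs_mean", "grs_variance",
              "grs_binary", "p_inactive", "rho", "activity_normal", "sigma",
              "alpha", "n_iter")


@dataclass(frozen=True)
class PowerScenario:
    """One fully parameterized simulation setting.

    Defaults are the base study conditions: beta_G = 0.154 kg/m^2 per
    allele, beta_E = -0.313 kg/m^2 (active vs inactive), beta_GE = -0.07,
    GRS ~ Normal(11.2, 5.06), 30% inactive, residual BMI SD 3.5, two-sided
    alpha 0.05, 1,000 Monte-Carlo iterations.
    """

    n: int
    beta_ge: float = -0.07
    beta_g: float = 0.154
    beta_e: float = -0.313
    grs_mean: float = 11.2
    grs_variance: float = 5.06
    grs_binary: bool = False
    p_inactive: float = 0.30
    rho: float = 0.0
    activity_normal: bool = False
    sigma: float = 3.5
    alpha: float = 0.05
    n_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0,1)")
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if self.grs_variance <= 0 or self.sigma <= 0:
            raise ValueError("grs_variance and sigma must be > 0")
        if not (0 < self.p_inactive < 1):
            raise ValueError("p_inactive must lie in (0,1)")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must lie in (-1,1)")


@dataclass
class PowerResult:
    """Monte-Carlo power estimate with its binomial uncertainty."""

    power: float
    mc_se: float
    ci95: tuple[float, float]
    n_rejected: int
    n_iter: int
    n_redrawn: int
    analytic_power: float | None
    scenario: PowerScenario

    def __post_init__(self) -> None:
        if not (0 <= self.power <= 1):
            raise ValueError("power must lie in [0,1]")


@dataclass
class RequiredN:
    """Required-sample-size search result."""

    n: int                     # exact (smallest n reaching the target)
    n_rounded: int             # nearest 1,000, for reporting
    target_power: float
    power_at_n: float          # analytic (or simulated) power at n
    method: str                # "analytic" or "simulation"
    confirmation: PowerResult | None = None


def analytic_power(scenario: PowerScenario) -> float:
    """Closed-form Wald power for the interaction test.

    Valid for independent predictors (rho = 0) and, via the joint-normal
    product-variance identity Var_resid(G*A) = Var(G) Var(A) (1 + rho^2),
    for correlated normal activity.  Correlated *binary* activity has no
    closed form here; use :func:`simulate_power`.
    """
    if scenario.rho != 0 and not scenario.activity_normal:
        raise ValueError(
            "no closed form for correlated binary activity; use simulate_power"
        )
    var_g = DICHOTOMIZED_GRS_VARIANCE if scenario.grs_binary else scenario.grs_variance
    p = scenario.p_inactive
    v = var_g * p * (1 - p)
    if scenario.activity_normal and scenario.rho != 0:
        v *= 1 + scenario.rho**2
    lam = scenario.n * scenario.beta_ge**2 * v / scenario.sigma**2
    z = norm.ppf(1 - scenario.alpha / 2)
    root = np.sqrt(lam)
    return float(norm.cdf(root - z) + norm.cdf(-root - z))


def _draw_predictors(scenario: PowerScenario, rng: np.random.Generator):
    """One iteration's (G, A) draw under the scenario's coding choices."""
    n, p = scenario.n, scenario.p_inactive
    g = rng.normal(scenario.grs_mean, np.sqrt(scenario.grs_variance), n)
    if scenario.activity_normal:
        mu_a, sd_a = 1 - p, np.sqrt(p * (1 - p))
        if scenario.rho != 0:
            zg = (g - scenario.grs_mean) / np.sqrt(scenario.grs_variance)
            a = mu_a + sd_a * (scenario.rho * zg
                               + np.sqrt(1 - scenario.rho**2) * rng.standard_normal(n))
        else:
            a = rng.normal(mu_a, sd_a, n)
    elif scenario.rho != 0:
        rho_lat = latent_correlation(scenario.rho, p)
        zg = (g - g.mean()) / g.std()
        latent = rho_lat * zg + np.sqrt(1 - rho_lat**2) * rng.standard_normal(n)
        a = (latent >= norm.ppf(p)).astype(float)
    else:
        a = (rng.random(n) >= p).astype(float)
    if scenario.grs_binary:
        g = (g > scenario.grs_mean).astype(float)
    return g, a


def simulate_power(scenario: PowerScenario) -> PowerResult:
    """Monte-Carlo power: fraction of iterations whose interaction Wald
    test rejects at the scenario's two-sided alpha.

    Iterations with a singular design (e.g. an all-active draw at tiny n)
    are redrawn and counted in ``n_redrawn``.
    """
    rng = np.random.default_rng(scenario.seed)
    z_crit = norm.ppf(1 - scenario.alpha / 2)
    n, n_iter = scenario.n, scenario.n_iter
    rejected = 0
    redrawn = 0
    it = 0
    while it < n_iter:
        g, a = _draw_predictors(scenario, rng)
        y = (25.0 + scenario.beta_g * g + scenario.beta_e * a
             + scenario.beta_ge * g * a
             + rng.normal(0.0, scenario.sigma, n))
        X = np.column_stack([np.ones(n), g, a, g * a])
        xtx = X.T @ X
        try:
            xtx_inv = np.linalg.inv(xtx)
        except np.linalg.LinAlgError:
            redrawn += 1
            if redrawn > 100 * n_iter:
                raise RuntimeError("persistent singular designs; check scenario")
            continue
        b = xtx_inv @ (X.T @ y)
        resid = y - X @ b
        s2 = resid @ resid / (n - 4)
        se = np.sqrt(s2 * xtx_inv[3, 3])
        if abs(b[3] / se) > z_crit:
            rejected += 1
        it += 1
    if redrawn:
        logger.info("redrew %d singular iteration(s)", redrawn)
    power = rejected / n_iter
    mc_se = float(np.sqrt(power * (1 - power) / n_iter))
    try:
        analytic = analytic_power(scenario)
    except ValueError:
        analytic = None
    return PowerResult(
        power=power, mc_se=mc_se,
        ci95=(max(0.0, power - 1.96 * mc_se), min(1.0, power + 1.96 * mc_se)),
        n_rejected=rejected, n_iter=n_iter, n_redrawn=redrawn,
        analytic_power=analytic, scenario=scenario,
    )


def required_sample_size(
    scenario: PowerScenario,
    target_power: float = 0.80,
    confirm: bool = False,
    confirm_iter: int = 500,
    n_max: int = 50_000_000,
) -> RequiredN:
    """Smallest n reaching the target power.

    With independent predictors (or correlated normal activity) the search
    bisects the analytic power curve; otherwise it bisects on simulated
    power (coarser, using the scenario's n_iter).  ``confirm=True`` runs a
    Monte-Carlo check at the returned n (``confirm_iter`` iterations).
    The rounded value (nearest 1,000) is for reporting; the exact n is
    retained.
    """
    if scenario.beta_ge == 0:
        raise ValueError("target power unreachable: beta_ge = 0")
    if not (scenario.alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")
    analytic_ok = scenario.rho == 0 or scenario.activity_normal

    def power_at(n: int) -> float:
        s = replace(scenario, n=n)
        if analytic_ok:
            return analytic_power(s)
        return simulate_power(s).power

    lo, hi = 4, n_max
    if power_at(hi) < target_power:
        raise ValueError(f"target power not reached even at n = {n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    confirmation = None
    if confirm:
        confirmation = simulate_power(
            replace(scenario, n=hi, n_iter=confirm_iter)
        )
    return RequiredN(
        n=hi, n_rounded=int(round(hi / 1000.0) * 1000),
        target_power=target_power, power_at_n=power_at(hi),
        method="analytic" if analytic_ok else "simulation",
        confirmation=confirmation,
    )


def scenario_sweep(
    base: PowerScenario,
    parameter: str,
    values: Sequence,
    simulate: bool = False,
    required_n: bool = False,
    target_power: float = 0.80,
) -> pd.DataFrame:
    """Evaluate power (and optionally required n) over a one-parameter grid.

    Returns one row per grid point with the swept value, analytic power,
    simulated power and MC-SE (when ``simulate``), and the required sample
    size for ``target_power`` (when ``required_n``).
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(
            f"unknown parameter {parameter!r}; sweepable: {', '.join(_SWEEPABLE)}"
        )
    if len(values) == 0:
        raise ValueError("empty sweep grid")
    rows = []
    for i, value in enumerate(values):
        s = replace(base, **{parameter: value},
                    seed=int(np.random.SeedSequence((base.seed, i)).generate_state(1)[0]
                             % (2**31)))
        row = {parameter: value}
        try:
            row["analytic_power"] = analytic_power(s)
        except ValueError:
            row["analytic_power"] = np.nan
        if simulate:
            res = simulate_power(s)
            row["power"] = res.power
            row["mc_se"] = res.mc_se
        if required_n:
            req = required_sample_size(s, target_power=target_power)
            row["required_n"] = req.n
            row["required_n_rounded"] = req.n_rounded
        rows.append(row)
    return pd.DataFrame(rows)
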