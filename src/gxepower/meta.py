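"""Meta-analysis of per-cohort interaction coefficients.

Primary pooling is weighted by cohort sample size (w_i = n_i), matching
the study's main analysis; inverse-variance fixed-effect and
DerSimonian-Laird random-effects pooling are available as sensitivity
methods.  Heterogeneity (Cochran's Q, I-squared, and its chi-square
p-value) is always computed with inverse-variance weights, the
conventional reporting scale, regardless of how the point estimate is
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm


@dataclass(frozen=True)
class CohortEstimate:
    """One cohort's interaction coefficient for pooling."""

    cohort: str
    n: int
    beta: float
    se: float
    group: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort {self.cohort!r}: n must be >= 1")
        if not (self.se > 0):
            raise ValueError(f"cohort {self.cohort!r}: se must be > 0")


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity statistics."""

    beta: float
    se: float
    z: float
    p: float
    q: float
    df: int
    i2: float          # percent
    p_het: float
    tau2: float        # 0 except for random effects
    method: str
    weights: pd.Series  # normalized to percent, summing to 100
    k: int

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        zq = norm.ppf(1 - alpha / 2)
        return self.beta - zq * self.se, self.beta + zq * self.se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return (
            f"Meta-analysis ({self.method}), k = {self.k}\n"
            f"  pooled beta = {self.beta:.4f} (SE {self.se:.4f}), "
            f"95% CI [{lo:.4f}, {hi:.4f}], p = {self.p:.3g}\n"
            f"  heterogeneity: Q = {self.q:.2f} on {self.df} df, "
            f"I2 = {self.i2:.1f}%, p = {self.p_het:.3f}, tau2 = {self.tau2:.4g}"
        )


def heterogeneity_from_q(q: float, df: int) -> tuple[float, float]:
    """(I-squared percent, heterogeneity p) from a Q statistic and its df."""
    if df < 1:
        raise ValueError("heterogeneity needs df >= 1 (k >= 2 estimates)")
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return i2, float(chi2.sf(q, df))


def heterogeneity(estimates: Sequence[CohortEstimate]) -> tuple[float, int, float, float]:
    """Cochran's Q with inverse-variance weights, plus df, I2 (%), p.

    Q = sum w_i (beta_i - beta_fixed)^2, w_i = 1/se_i^2, df = k - 1.
    """
    if len(estimates) < 2:
        raise ValueError("heterogeneity needs >= 2 estimates")
    beta = np.array([e.beta for e in estimates])
    w = np.array([1.0 / e.se**2 for e in estimates])
    beta_fixed = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - beta_fixed) ** 2))
    df = len(estimates) - 1
    i2, p_het = heterogeneity_from_q(q, df)
    return q, df, i2, p_het


class MetaAnalysis:
    """Pool per-cohort estimates; ``fit`` returns a :class:`MetaResult`.

    Accepts a sequence of :class:`CohortEstimate` or a DataFrame with
    columns cohort, n, beta, se (and optionally group).
    """

    def __init__(self, estimates):
        if isinstance(estimates, pd.DataFrame):
            estimates = [
                CohortEstimate(cohort=str(r["cohort"]), n=int(r["n"]),
                               beta=float(r["beta"]), se=float(r["se"]),
                               group=(str(r["group"]) if "group" in estimates.columns
                                      and pd.notna(r.get("group")) else None))
                for _, r in estimates.iterrows()
            ]
        self.estimates: list[CohortEstimate] = list(estimates)
        if not self.estimates:
            raise ValueError("at least one estimate required")

    def _arrays(self):
        e = self.estimates
        return (np.array([x.beta for x in e]), np.array([x.se for x in e]),
                np.array([x.n for x in e], dtype=float))

    def _het(self) -> tuple[float, int, float, float]:
        if len(self.estimates) >= 2:
            return heterogeneity(self.estimates)
        return 0.0, 0, 0.0, 1.0

    def _result(self, beta: float, se: float, w: np.ndarray, method: str,
                tau2: float = 0.0) -> MetaResult:
        q, df, i2, p_het = self._het()
        z = beta / se
        labels = [e.cohort for e in self.estimates]
        return MetaResult(
            beta=float(beta), se=float(se), z=float(z),
            p=float(2 * norm.sf(abs(z))), q=q, df=df, i2=i2, p_het=p_het,
            tau2=float(tau2), method=method,
            weights=pd.Series(100.0 * w / w.sum(), index=labels, name="weight_pct"),
            k=len(self.estimates),
        )

    def fit(self, method: str = "sample_size") -> MetaResult:
        if method == "sample_size":
            return self.pool_sample_size_weighted()
        if method == "fixed":
            return self.pool_inverse_variance(random=False)
        if method == "random":
            return self.pool_inverse_variance(random=True)
        raise ValueError(f"unknown method {method!r}; use sample_size, fixed or random")

    def pool_sample_size_weighted(self) -> MetaResult:
        """Primary pooling: w_i = n_i; pooled beta = sum(w b)/sum(w);
        pooled SE = sqrt(sum(w^2 se^2)) / sum(w) (weighted-sum variance
        under independence)."""
        beta, se, n = self._arrays()
        w = n
        pooled = np.sum(w * beta) / np.sum(w)
        pooled_se = np.sqrt(np.sum(w**2 * se**2)) / np.sum(w)
        return self._result(pooled, pooled_se, w, "sample_size")

    def pool_inverse_variance(self, random: bool = False) -> MetaResult:
        """Fixed: w_i = 1/se_i^2.  Random: DerSimonian-Laird
        tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)), then
        w_i = 1/(se_i^2 + tau2)."""
        beta, se, _ = self._arrays()
        w_fixed = 1.0 / se**2
        tau2 = 0.0
        if random:
            if len(self.estimates) < 2:
                raise ValueError("random effects needs >= 2 estimates")
            q, df, _, _ = self._het()
            c = np.sum(w_fixed) - np.sum(w_fixed**2) / np.sum(w_fixed)
            tau2 = max(0.0, (q - df) / c)
        w = 1.0 / (se**2 + tau2)
        pooled = np.sum(w * beta) / np.sum(w)
        pooled_se = float(np.sqrt(1.0 / np.sum(w)))
        return self._result(pooled, pooled_se, w,
                            "random (DL)" if random else "fixed", tau2)


def forest_export(estimates: Sequence[CohortEstimate], meta: MetaResult,
                  alpha: float = 0.05, by_group: bool = False) -> pd.DataFrame:
    """Forest-plot table: one row per cohort (label, n, beta, CI, weight %)
    plus a pooled summary row; weights sum to 100.

    With ``by_group`` and grouped estimates, each group also gets its own
    pooled summary row (re-pooled with the same method).
    """
    zq = norm.ppf(1 - alpha / 2)
    rows = []

    def _cohort_rows(ests, weights):
        for e in ests:
            rows.append({
                "label": e.cohort, "row_type": "cohort", "group": e.group,
                "n": e.n, "beta": e.beta, "se": e.se,
                "lower": e.beta - zq * e.se, "upper": e.beta + zq * e.se,
                "weight_pct": float(weights[e.cohort]),
            })

    def _summary_row(label, res, group=None):
        lo, hi = res.conf_int(alpha)
        rows.append({
            "label": label, "row_type": "summary", "group": group,
            "n": int(sum(e.n for e in estimates if group is None or e.group == group)),
            "beta": res.beta, "se": res.se, "lower": lo, "upper": hi,
            "weight_pct": 100.0,
        })

    method = {"sample_size": "sample_size", "fixed": "fixed",
              "random (DL)": "random"}[meta.method]
    if by_group:
        groups = sorted({e.group for e in estimates if e.group is not None})
        for g in groups:
            sub = [e for e in estimates if e.group == g]
            sub_res = MetaAnalysis(sub).fit(method)
            _cohort_rows(sub, sub_res.weights)
            _summary_row(f"{g} (pooled)", sub_res, group=g)
    else:
        _cohort_rows(estimates, meta.weights)
    _summary_row("Overall (pooled)", meta)
    return pd.DataFrame(rows)


def forest_plot(table: pd.DataFrame, path=None, title: str | None = None):
    """Render a forest-export table with matplotlib; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    for yi, (_, row) in zip(y, table.iterrows()):
        if row["row_type"] == "summary":
            ax.plot([row["lower"], row["upper"]], [yi, yi], color="k", lw=2)
            ax.plot(row["beta"], yi, marker="D", color="k", ms=8)
        else:
            ax.plot([row["lower"], row["upper"]], [yi, yi], color="0.4")
            ax.plot(row["beta"], yi, marker="s", color="0.2",
                    ms=3 + 8 * row["weight_pct"] / 100.0)
    ax.axvline(0.0, color="0.7", ls="--", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(table["label"])
    ax.set_xlabel("interaction coefficient (kg/m$^2$ per allele per activity unit)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
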