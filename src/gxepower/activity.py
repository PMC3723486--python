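"""Cambridge Physical Activity Index (CPAI) derivation and the 80/20
binary activity variable.

The CPAI cross-tabulates a 4-category occupational activity measure with a
4-category leisure-time exercise frequency into a four-level total
activity index (1 inactive ... 4 active).  Participants missing leisure
data are assigned the lowest leisure category before lookup; participants
missing occupational data cannot receive a CPAI and fall back to the
binary variable, which splits any ordered activity measure at its 20th
percentile (bottom 20% inactive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default occupational x leisure -> CPAI crosswalk: level = min(4, occ + leis - 1).
#: The published index's exact cell assignments are cohort-consortium
#: internal; this mapping honours its anchor cells (sedentary job +
#: occasional exercise -> inactive; physically straining job -> active)
#: and is monotone in both inputs.  Override with any 4x4 matrix whose
#: cells are in {1..4} and non-decreasing along both axes.
DEFAULT_CROSSWALK = np.array(
    [[min(4, o + l - 1) for l in range(1, 5)] for o in range(1, 5)], dtype=int
)


def _validate_crosswalk(crosswalk: np.ndarray) -> np.ndarray:
    cw = np.asarray(crosswalk, dtype=int)
    if cw.shape != (4, 4):
        raise ValueError("crosswalk must be 4x4")
    if not np.isin(cw, [1, 2, 3, 4]).all():
        raise ValueError("crosswalk cells must be CPAI levels 1-4")
    if (np.diff(cw, axis=0) < 0).any() or (np.diff(cw, axis=1) < 0).any():
        raise ValueError("crosswalk must be non-decreasing along both axes")
    return cw


def build_cpai(occupational, leisure, crosswalk=None) -> pd.Series:
    """CPAI level per participant from occupational and leisure categories.

    Missing leisure is treated as category 1 ('occasionally') before the
    crosswalk lookup.  Missing occupational activity yields NaN — such
    participants are analysed through the binary variable only.
    """
    cw = _validate_crosswalk(DEFAULT_CROSSWALK if crosswalk is None else crosswalk)
    occ = pd.Series(occupational, dtype="float64").to_numpy()
    leis = pd.Series(leisure, dtype="float64").to_numpy()
    if occ.shape != leis.shape:
        raise ValueError("occupational and leisure vectors must be conformable")
    for name, arr in (("occupational", occ), ("leisure", leis)):
        called = arr[~np.isnan(arr)]
        if not np.isin(called, [1, 2, 3, 4]).all():
            raise ValueError(f"{name} categories must be integers 1-4 or missing")
    leis = np.where(np.isnan(leis), 1.0, leis)  # lowest intensity score
    out = np.full(occ.shape, np.nan)
    ok = ~np.isnan(occ)
    out[ok] = cw[occ[ok].astype(int) - 1, leis[ok].astype(int) - 1]
    n_flagged = int((~ok).sum())
    if n_flagged:
        logger.info("%d record(s) missing occupational activity: "
                    "flagged for binary-only analysis", n_flagged)
    return pd.Series(out, name="cpai")


@dataclass
class ActivitySplit:
    """Binary activity classification and how it was obtained."""

    binary: pd.Series           # 0 = inactive, 1 = active
    threshold: float            # values <= threshold are inactive
    inactive_quantile: float
    realized_inactive_fraction: float


def dichotomize_activity(values, inactive_quantile: float = 0.20) -> ActivitySplit:
    """Split an ordered activity measure into active (top 80%) vs inactive
    (bottom 20%).

    The threshold is the empirical ``inactive_quantile`` of the
    distribution; all values at or below it are inactive, so with heavy
    ties the realized inactive fraction can exceed the nominal quantile
    (reported, and logged when it does).  Invariant to strictly monotone
    transforms of the measure.
    """
    if not (0 < inactive_quantile < 1):
        raise ValueError("inactive_quantile must lie in (0,1)")
    vals = pd.Series(values, dtype="float64")
    obs = vals.dropna().to_numpy()
    if obs.size == 0:
        raise ValueError("no observed activity values")
    if np.all(obs == obs[0]):
        raise ValueError("constant activity measure: no split possible")
    threshold = float(np.quantile(obs, inactive_quantile, method="inverted_cdf"))
    binary = (vals > threshold).astype(float)
    binary[vals.isna()] = np.nan
    realized = float((vals <= threshold).sum() / obs.size)
    if realized > inactive_quantile + 1e-12:
        logger.info("ties at the threshold: realized inactive fraction %.3f "
                    "exceeds nominal %.2f", realized, inactive_quantile)
    return ActivitySplit(binary=binary.rename("activity_binary"),
                         threshold=threshold,
                         inactive_quantile=inactive_quantile,
                         realized_inactive_fraction=realized)
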