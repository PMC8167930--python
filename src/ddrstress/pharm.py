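"""Viability normalisation, 4PL dose-response fitting, and stratified tests.

Raw plate signals (MTS absorbance or luminescence) are normalised per
(sample, compound) group to a 0–100% viability scale: the media-blank mean
is subtracted from every well, 0% is anchored at the actinomycin-D kill
control and 100% at the vehicle control. Values outside [0, 100] are kept
(clipping would bias the curve plateaus).

Dose-response curves use the four-parameter logistic in log-dose space,

    v(c) = bottom + (top - bottom) / (1 + (c / EC50)^hill),

with the *relative* EC50 (the inflection of the fitted curve) reported.
Fitting is deterministic multi-start least squares from a fixed grid of
data-quantile initialisations. A fit is flagged ``no_response`` when the
fitted span is under 20 percentage points or the EC50 lands more than two
decades outside the dosed range, and ``ambiguous`` when no start converges.

Group comparisons are two-sided nonparametric tests (exact Mann-Whitney for
small groups, Kruskal-Wallis for >2 groups); dichotomous associations use
Fisher's exact test or the chi-square test. The 2x2 therapeutic quadrant
crosses the DDR-deficiency call with the replication-stress stratum and maps
each cell to its predicted responsive drug classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ("sample_id", "compound", "dose", "well_role", "replicate", "raw_signal")
WELL_ROLES = ("treated", "vehicle", "media_blank", "actD_kill")

#: Pan-cancer screening sensitivity threshold for platinum EC50 (µmol/L).
PLATINUM_SENSITIVITY_THRESHOLD_UM = 10.0

#: Fitted span (top - bottom, percentage points) below which a curve is
#: reported as no_response.
MIN_RESPONSE_SPAN = 20.0

QUADRANTS = (
    "ddr_deficient_rs_high",
    "ddr_deficient_rs_low",
    "ddr_proficient_rs_high",
    "ddr_proficient_rs_low",
)
#: Predicted responsive drug classes per (ddr_deficient, rs_high) cell.
QUADRANT_RESPONSE: dict[tuple[bool, bool], tuple[str, ...]] = {
    (True, True): ("platinum_parp_inhibitor", "atr_wee1_inhibitor"),
    (True, False): ("platinum_parp_inhibitor",),
    (False, True): ("atr_wee1_inhibitor",),
    (False, False): (),
}


@dataclass(frozen=True)
class DoseResponseFit:
    """4PL fit result; parameters are None unless ``converged``."""

    ec50: float | None
    hill: float | None
    top: float | None
    bottom: float | None
    converged: bool
    status: str  # "ok" | "no_response" | "ambiguous"
    residual_sd: float | None


@dataclass(frozen=True)
class QuadrantCall:
    quadrant: str
    predicted_responsive: tuple[str, ...]


# ---------------------------------------------------------------------------
# Plate I/O and normalisation
# ---------------------------------------------------------------------------

def read_plate_csv(path: str | Path) -> pd.DataFrame:
    plate = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    return plate


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Normalise raw signals to percent viability per (sample, compound) group.

    Media-blank means are subtracted first; then
    v = 100 * (signal - mean(actD)) / (mean(vehicle) - mean(actD)).
    Raises on groups whose vehicle mean does not exceed the kill-control mean
    ("inverted controls"). Values outside [0, 100] are logged, never clipped.
    """
    rows = []
    for (sample, compound), group in plate.groupby(["sample_id", "compound"], sort=True):
        roles = group.groupby("well_role")["raw_signal"].mean()
        for role in ("media_blank", "vehicle", "actD_kill"):
            if role not in roles:
                raise ValueError(f"{sample}/{compound}: missing {role} control wells")
        blank = roles["media_blank"]
        vehicle = roles["vehicle"] - blank
        actd = roles["actD_kill"] - blank
        if vehicle <= actd:
            raise ValueError(f"{sample}/{compound}: inverted controls (vehicle <= actD)")
        treated = group[group["well_role"] == "treated"]
        v = 100.0 * ((treated["raw_signal"] - blank) - actd) / (vehicle - actd)
        n_outside = int(((v < 0) | (v > 100)).sum())
        if n_outside:
            logger.info("%s/%s: %d well(s) outside [0, 100]%% (kept)", sample, compound, n_outside)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "compound": compound,
                    "dose": treated["dose"].to_numpy(),
                    "replicate": treated["replicate"].to_numpy(),
                    "viability": v.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["sample_id", "compound", "dose", "replicate", "viability"]
    )


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

def _4pl(log10_c: np.ndarray, log10_ec50: float, hill: float, top: float, bottom: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_c - log10_ec50)))


def fit_4pl(doses: Sequence[float], viability: Sequence[float]) -> DoseResponseFit:
    """Fit the four-parameter logistic to (dose, viability%) observations.

    Requires >= 4 distinct positive doses. Initialisation is a fixed grid of
    log-dose quantiles for the EC50 and {0.5, 1, 2} for the hill slope; the
    best converged least-squares solution wins, so the fit is deterministic.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must align")
    if (doses <= 0).any():
        raise ValueError("doses must be positive (controls are handled upstream)")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")

    log_c = np.log10(doses)
    v_lo, v_hi = float(viability.min()), float(viability.max())
    span = v_hi - v_lo
    if span < 1e-9:
        # perfectly flat response: degenerate but well-defined
        return DoseResponseFit(
            ec50=None, hill=None, top=v_hi, bottom=v_lo,
            converged=True, status="no_response", residual_sd=0.0,
        )

    lo, hi = log_c.min(), log_c.max()
    bounds = (
        [lo - 4.0, 0.01, -np.inf, -np.inf],
        [hi + 4.0, 20.0, np.inf, np.inf],
    )
    best: tuple[float, np.ndarray] | None = None
    for ec50_start in np.quantile(log_c, [0.25, 0.5, 0.75]):
        for hill_start in (0.5, 1.0, 2.0):
            p0 = [ec50_start, hill_start, v_hi, v_lo]
            try:
                popt, _ = scipy.optimize.curve_fit(
                    _4pl, log_c, viability, p0=p0, bounds=bounds, maxfev=20000
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((_4pl(log_c, *popt) - viability) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt)

    if best is None:
        return DoseResponseFit(
            ec50=None, hill=None, top=None, bottom=None,
            converged=False, status="ambiguous", residual_sd=None,
        )

    ssr, (log_ec50, hill, top, bottom) = best
    if top < bottom:  # canonical orientation: hill keeps its meaning after swap
        top, bottom = bottom, top
    ec50 = 10.0 ** log_ec50
    dof = max(len(doses) - 4, 1)
    residual_sd = float(np.sqrt(ssr / dof))
    fitted_span = top - bottom
    outside = ec50 > 100.0 * doses.max() or ec50 < doses.min() / 100.0
    status = "no_response" if (fitted_span < MIN_RESPONSE_SPAN or outside) else "ok"
    return DoseResponseFit(
        ec50=float(ec50), hill=float(hill), top=float(top), bottom=float(bottom),
        converged=True, status=status, residual_sd=residual_sd,
    )


def fit_plate(normalized: pd.DataFrame) -> pd.DataFrame:
    """Fit one 4PL per (sample, compound) group of a normalised viability table."""
    rows = []
    for (sample, compound), group in normalized.groupby(["sample_id", "compound"], sort=True):
        fit = fit_4pl(group["dose"], group["viability"])
        rows.append(
            {
                "sample_id": sample,
                "compound": compound,
                "ec50": fit.ec50,
                "hill": fit.hill,
                "top": fit.top,
                "bottom": fit.bottom,
                "status": fit.status,
            }
        )
    return pd.DataFrame(rows)


def call_platinum_sensitivity(
    ec50: float, threshold: float = PLATINUM_SENSITIVITY_THRESHOLD_UM
) -> bool:
    """Sensitive iff EC50 is strictly below the threshold (default 10 µmol/L)."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    return ec50 < threshold


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def compare_groups(
    values: Sequence[float], labels: Sequence, test: str = "mann_whitney"
) -> tuple[float, float]:
    """Two-sided nonparametric comparison of values across label groups.

    mann_whitney requires exactly two groups; the exact null distribution is
    used when both groups have n <= 8 and the pooled data are tie-free,
    otherwise the normal approximation with tie correction. kruskal_wallis
    accepts two or more groups. Returns (statistic, p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == lab] for lab in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        x, y = groups
        exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(values)) == len(values)
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        res = scipy.stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def association_test(
    flags_a: Sequence[bool],
    flags_b: Sequence[bool],
    test: str = "fisher_exact",
    yates_correction: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Association between two dichotomous variables on a 2x2 table.

    Fisher's exact test is two-sided by hypergeometric enumeration (sum of
    table probabilities <= the observed one); chi-square is Pearson's without
    continuity correction unless ``yates_correction`` is set. Returns the
    contingency table and the p-value. Raises on an empty margin.
    """
    a = pd.Series(list(flags_a), dtype=bool)
    b = pd.Series(list(flags_b), dtype=bool)
    if len(a) != len(b):
        raise ValueError("flag vectors must align")
    table = np.zeros((2, 2), dtype=int)
    for ai, bi in zip(a, b):
        table[int(not ai), int(not bi)] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an empty margin")
    if test == "fisher_exact":
        _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    elif test == "chi_square":
        p = scipy.stats.chi2_contingency(table, correction=yates_correction).pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    frame = pd.DataFrame(table, index=["a_true", "a_false"], columns=["b_true", "b_false"])
    return frame, float(p)


def assign_quadrant(ddr_deficient: bool | None, rs_high: bool | None) -> QuadrantCall:
    """Cross the DDR call with the replication-stress stratum.

    DDR-deficient + high-RS samples are predicted responsive to both
    platinum/PARP-inhibitor and ATR/WEE1-inhibitor classes; single-positive
    cells to one class; double-negative to neither. An unknown flag makes the
    quadrant unassessable.
    """
    if ddr_deficient is None or rs_high is None:
        return QuadrantCall(quadrant="unassessable", predicted_responsive=())
    name = (
        f"ddr_{'deficient' if ddr_deficient else 'proficient'}"
        f"_rs_{'high' if rs_high else 'low'}"
    )
    return QuadrantCall(
        quadrant=name, predicted_responsive=QUADRANT_RESPONSE[(ddr_deficient, rs_high)]
    )
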