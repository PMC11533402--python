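"""Exposure-group contrasts: geometric mean ratios, Wald CIs, BH-FDR.

Outcomes (cell densities, on-nucleus intensities, SUVR) are analysed on the
natural-log scale.  Technical replicates are averaged per animal first (the
two-stage stand-in for an animal-level random intercept: with balanced
replicates it yields the same fixed-effect point estimate), then the exposed
vs vehicle contrast is a two-sample comparison of log-scale group means.  The
exponentiated difference is the geometric mean ratio (GMR); a 95% Wald CI
that excludes 1 indicates a group difference.  One outcome — the mean C3
intensity on GFAP nuclei — is shifted by +10 before the log transform.

Families of region x timepoint contrasts within one sex x outcome are
corrected by the Benjamini-Hochberg step-up FDR at alpha 0.05.  The step-up
rule is implemented directly,

    q_(i) = min_{j >= i} min(1, m * p_(j) / j),

so that its arithmetic matches the definition bit-for-bit.

Cohort inclusion for the exposure paradigm requires behaviour consistent with
status epilepticus: a mean modified-Racine score >= 2.5 over the first 40 min
post-exposure (closed bound).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05

COHORT_COLUMNS = ["animal_id", "sex", "exposure", "region", "dpe", "outcome_name", "value", "replicate_id"]


@dataclass(frozen=True)
class TransformSpec:
    """Log-transform policy for one outcome.

    ``shift`` is added before taking the natural log (10 for the C3
    mean-intensity outcome, 0 otherwise).  With ``shift == 0``,
    ``zero_policy`` decides how nonpositive values are handled: ``"error"``
    refuses them, ``"half_min"`` (default) replaces zeros by half the smallest
    positive value, logged loudly.
    """

    shift: float = 0.0
    zero_policy: str = "half_min"

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be nonnegative")
        if self.zero_policy not in ("error", "half_min"):
            raise ValueError("zero_policy must be 'error' or 'half_min'")


#: Per-outcome transform conventions; the +10 shift applies only to the C3
#: on-GFAP-nucleus intensity outcome.
def default_transform(outcome_name: str) -> TransformSpec:
    name = outcome_name.lower()
    if "c3" in name and "intensity" in name:
        return TransformSpec(shift=10.0)
    return TransformSpec()


def log_transform(values, spec: TransformSpec | None = None) -> np.ndarray:
    """Natural log of ``values + shift`` under the zero-handling policy."""
    spec = spec or TransformSpec()
    v = np.asarray(values, dtype=float)
    shifted = v + spec.shift
    bad = np.flatnonzero(shifted <= 0)
    if bad.size:
        if spec.zero_policy == "error" or np.any(v[bad] < 0) or not np.any(shifted > 0):
            raise ValueError(
                f"nonpositive values after shift {spec.shift} at positions {bad.tolist()}"
            )
        fill = 0.5 * shifted[shifted > 0].min()
        logger.warning(
            "log_transform: replacing %d zero value(s) at positions %s by half the "
            "minimum positive value (%.6g)", bad.size, bad.tolist(), fill,
        )
        shifted = shifted.copy()
        shifted[bad] = fill
    return np.log(shifted)


@dataclass(frozen=True)
class ContrastResult:
    """One exposure contrast for a sex x region x timepoint x outcome cell."""

    sex: str
    region: str
    dpe: object  # int, or "all" when collapsed over timepoints
    outcome_name: str
    gmr: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    log_gmr: float = math.nan
    se_log: float = math.nan
    p_raw: float = math.nan
    q_fdr: float = math.nan
    n_veh: int = 0
    n_dfp: int = 0
    significant_raw: bool = False
    significant_fdr: bool = False
    reason: str = ""

    @property
    def ok(self) -> bool:
        return math.isfinite(self.gmr)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _aggregate_animals(cell: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to one value per animal (raw scale)."""
    return cell.groupby(["animal_id", "exposure"], as_index=False)["value"].mean()


def estimate_gmr(
    table: pd.DataFrame,
    sex: str,
    region: str,
    dpe,
    outcome: str,
    spec: TransformSpec | None = None,
    alpha: float = ALPHA,
    use_t: bool = True,
) -> ContrastResult:
    """Geometric mean ratio (DFP / Veh) for one analysis cell.

    Replicates are averaged per animal, values are log-transformed, and the
    Wald contrast uses the pooled two-sample standard error.  ``use_t`` picks
    the Student-t critical value on n1+n2-2 df (default; exact coverage under
    log-normal outcomes at small n); ``use_t=False`` uses the normal 1.96
    convention.  ``dpe=None`` pools all timepoints into one cell.  A group
    with fewer than two animals yields a missing result with a reason rather
    than an estimate.
    """
    spec = spec or default_transform(outcome)
    sel = (
        (table["sex"] == sex)
        & (table["region"] == region)
        & (table["outcome_name"] == outcome)
    )
    if dpe is not None:
        sel &= table["dpe"] == dpe
    cell = table.loc[sel]
    meta = dict(sex=sex, region=region, dpe=dpe if dpe is not None else "all", outcome_name=outcome)
    if cell.empty:
        return ContrastResult(**meta, reason="no data")
    per_animal = _aggregate_animals(cell)
    groups = {}
    for grp in ("Veh", "DFP"):
        vals = per_animal.loc[per_animal["exposure"] == grp, "value"].to_numpy()
        groups[grp] = vals
    n_veh, n_dfp = len(groups["Veh"]), len(groups["DFP"])
    if n_veh < 2 or n_dfp < 2:
        return ContrastResult(**meta, n_veh=n_veh, n_dfp=n_dfp,
                              reason=f"fewer than 2 animals per group (Veh={n_veh}, DFP={n_dfp})")
    log_veh = log_transform(groups["Veh"], spec)
    log_dfp = log_transform(groups["DFP"], spec)
    diff = float(log_dfp.mean() - log_veh.mean())
    df = n_veh + n_dfp - 2
    sp2 = ((n_veh - 1) * log_veh.var(ddof=1) + (n_dfp - 1) * log_dfp.var(ddof=1)) / df
    se = float(math.sqrt(sp2 * (1.0 / n_veh + 1.0 / n_dfp)))
    dist = sps.t(df) if use_t else sps.norm()
    crit = float(dist.ppf(1 - alpha / 2))
    if se == 0.0:
        p = 0.0 if diff != 0 else 1.0
        lo = hi = math.exp(diff)
    else:
        p = float(2 * dist.sf(abs(diff) / se))
        lo, hi = math.exp(diff - crit * se), math.exp(diff + crit * se)
    return ContrastResult(
        **meta,
        gmr=math.exp(diff),
        ci_low=lo,
        ci_high=hi,
        log_gmr=diff,
        se_log=se,
        p_raw=p,
        n_veh=n_veh,
        n_dfp=n_dfp,
        significant_raw=p < alpha,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the ascending order
    statistics; ties are order-preserving (equal p get equal q).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


@dataclass(frozen=True)
class RacineSeries:
    """Time-stamped modified-Racine seizure scores (ordinal 0-5)."""

    times_min: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        s = np.asarray(self.scores, dtype=int)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and scores must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if s.min(initial=0) < 0 or s.max(initial=0) > 5:
            raise ValueError("scores must lie in {0..5}")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "scores", s)


def racine_include(series: RacineSeries, window_min: float = 40.0, cutoff: float = 2.5) -> bool:
    """Status-epilepticus inclusion filter.

    Include iff the arithmetic mean of scores observed in ``(0, window_min]``
    meets the cutoff (closed bound; the default 2.5 over 40 min).  A series
    that does not cover the window is an error.
    """
    t = series.times_min
    if t.size == 0 or t.max() < window_min:
        raise ValueError(f"series does not cover the {window_min}-min scoring window")
    in_window = (t > 0) & (t <= window_min)
    if not in_window.any():
        raise ValueError("no scores inside the scoring window")
    return float(series.scores[in_window].mean()) >= cutoff


def run_contrast_grid(
    table: pd.DataFrame,
    outcomes: list[str] | None = None,
    specs: dict[str, TransformSpec] | None = None,
    alpha: float = ALPHA,
    use_t: bool = True,
    collapse: str = "by_cell",
) -> pd.DataFrame:
    """All sex x region x dpe x outcome contrasts with per-family FDR.

    ``collapse="by_cell"`` estimates one contrast per region x timepoint;
    ``"by_region"`` pools timepoints and reports overall per-region contrasts
    (the display used when a timepoint interaction is absent).  FDR families
    are all cells within one sex x outcome; missing cells carry a reason and
    do not enter the correction.  Failures are confined to their own cell.
    """
    if collapse not in ("by_cell", "by_region"):
        raise ValueError("collapse must be 'by_cell' or 'by_region'")
    outcomes = outcomes or sorted(table["outcome_name"].unique())
    results: list[ContrastResult] = []
    for sex in sorted(table["sex"].unique()):
        for outcome in outcomes:
            spec = (specs or {}).get(outcome, default_transform(outcome))
            family: list[ContrastResult] = []
            sub = table[(table["sex"] == sex) & (table["outcome_name"] == outcome)]
            regions = sorted(sub["region"].unique())
            dpes = [None] if collapse == "by_region" else sorted(sub["dpe"].unique())
            for region in regions:
                for dpe in dpes:
                    try:
                        res = estimate_gmr(table, sex, region, dpe, outcome,
                                           spec=spec, alpha=alpha, use_t=use_t)
                    except Exception as exc:  # confined to the cell
                        res = ContrastResult(sex=sex, region=region,
                                             dpe=dpe if dpe is not None else "all",
                                             outcome_name=outcome, reason=str(exc))
                    family.append(res)
            valid = [i for i, r in enumerate(family) if r.ok]
            if valid:
                q = bh_fdr([family[i].p_raw for i in valid])
                for qi, i in zip(q, valid):
                    family[i] = replace(family[i], q_fdr=float(qi),
                                        significant_fdr=bool(qi < alpha))
            results.extend(family)
    return pd.DataFrame([r.to_dict() for r in results])
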