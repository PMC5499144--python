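"""Logistic growth-curve fitting and MDR × MDP fitness.

Quantitative fitness analysis (QFA) summarizes each spotted yeast culture by
fitting a logistic growth law to its timed intensity readings,

    G(t) = K * G0 * exp(r t) / (K + G0 * (exp(r t) - 1)),

with carrying capacity ``K`` (intensity units), growth rate ``r`` (1/day) and
inoculum density ``G0`` (intensity units), and converting the fit into two
interpretable quantities:

* MDP (maximum doubling potential) — the number of population doublings from
  inoculum to saturation, ``log2(K / G0)`` (doublings);
* MDR (maximum doubling rate) — the reciprocal of the time the culture takes
  to double from its inoculum, ``r / ln[2 (K - G0) / (K - 2 G0)]``
  (doublings/day), which tends to ``r / ln 2`` in the exponential-growth
  limit ``K >> G0``.

Fitness is their product, F = MDR × MDP, in doublings²/day.  Cultures that
never grow are assigned fitness 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    InconsistencyError,
    InsufficientDataError,
    InvalidParameterError,
)

LN2 = float(np.log(2.0))

#: A culture whose maximum intensity is below this multiple of its minimum
#: intensity is considered dead (never grew).
DEFAULT_DEAD_THRESHOLD = 1.75

#: Additive intensity floor guarding the log transform.
INTENSITY_FLOOR = 1e-6

#: Growth-rate search window, 1/day.
R_BOUNDS = (1e-3, 50.0)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    """One culture's timed intensity series plus plate and gene metadata.

    Times are in days, strictly increasing; intensities are positive, in
    arbitrary imaging units.  ``background`` is ``"control"`` or ``"query"``.
    """

    screen_id: str
    plate_barcode: str
    row: int
    column: int
    orf: str
    gene: str
    background: str
    treatment: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)

    def validate(self):
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise InvalidParameterError("times and intensities must be 1-D and equal length")
        if np.any(~np.isfinite(self.times)) or np.any(~np.isfinite(self.intensities)):
            raise InvalidParameterError("non-finite observation in curve")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise InvalidParameterError("times must be non-negative")
        if np.any(self.intensities <= 0):
            raise InvalidParameterError("intensities must be positive")

    @property
    def key(self) -> tuple:
        return (self.screen_id, self.plate_barcode, self.row, self.column)


@dataclass
class LogisticFit:
    """Fitted logistic parameters for one culture.

    ``status`` is ``"ok"`` (parameters valid), ``"dead"`` (culture never
    grew; fitness is 0 downstream) or ``"failed"`` (optimizer did not
    converge from any initialization).  ``rss`` is the residual sum of
    squares on log intensities.
    """

    K: float
    r: float
    G0: float
    rss: float
    n_obs: int
    status: str


@dataclass
class FitnessMeasure:
    """MDR (doublings/day), MDP (doublings) and F = MDR × MDP (doublings²/day).

    ``doubling_capped`` marks the degenerate regime K ≤ 2·G0, where a full
    doubling from the inoculum is impossible under the logistic ceiling and
    MDR falls back to the exponential-phase rate r / ln 2.
    """

    mdr: float
    mdp: float
    fitness: float
    doubling_capped: bool = False


@dataclass
class ScreenFitnessTable:
    """Per-ORF fitness summary for one screen × background.

    ``data`` has one row per ORF (sorted lexicographically) with columns
    ``orf, gene, n, fitness_mean, fitness_median, mdr_mean, mdp_mean,
    replicates`` where ``replicates`` is the list of per-culture fitness
    values (dead/failed cultures contribute 0).
    """

    screen_id: str
    background: str
    treatment: str
    data: pd.DataFrame = field(repr=False)

    @property
    def mean_by_orf(self) -> pd.Series:
        return self.data.set_index("orf")["fitness_mean"]

    @property
    def replicates_by_orf(self) -> pd.Series:
        return self.data.set_index("orf")["replicates"]


# ---------------------------------------------------------------------------
# logistic kernel
# ---------------------------------------------------------------------------

def logistic_growth(t, K: float, r: float, G0: float):
    """Evaluate the logistic growth law G(t).

    Parameters must satisfy K > 0, r >= 0, 0 < G0 <= K and t >= 0.
    Accepts scalar or array ``t``; returns the matching shape.
    """
    t_arr = np.asarray(t, dtype=float)
    for name, value in (("K", K), ("r", r), ("G0", G0)):
        if not np.isfinite(value):
            raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    if K <= 0:
        raise InvalidParameterError(f"K must be positive, got {K}")
    if r < 0:
        raise InvalidParameterError(f"r must be non-negative, got {r}")
    if not (0 < G0 <= K):
        raise InvalidParameterError(f"G0 must satisfy 0 < G0 <= K, got G0={G0}, K={K}")
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise InvalidParameterError("t must be finite and non-negative")

    out = _logistic(t_arr, K, r, G0)
    return out if np.ndim(t) else float(out)


def _logistic(t, K, r, G0):
    # Stable evaluation: G = K / (1 + (K/G0 - 1) * exp(-r t)).
    e = np.exp(-np.minimum(r * t, 700.0))
    return K / (1.0 + (K / G0 - 1.0) * e)


def doubling_time(K: float, r: float, G0: float) -> float:
    """Time for the culture to double from its inoculum, in days.

    Closed form: t_d = ln[2 (K - G0) / (K - 2 G0)] / r, defined for K > 2·G0
    and r > 0; returns ``inf`` when doubling is impossible (K <= 2 G0).
    """
    if r <= 0 or K <= 2.0 * G0:
        return float("inf")
    return float(np.log(2.0 * (K - G0) / (K - 2.0 * G0)) / r)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _log_model_and_jac(theta, t):
    """log G(t) and its jacobian wrt (log K, log r, log G0)."""
    K, r, G0 = np.exp(theta)
    rt = np.minimum(r * t, 700.0)
    ert = np.exp(rt)
    D = K + G0 * (ert - 1.0)
    logG = np.log(K) + np.log(G0) + rt - np.log(D)
    dK = 1.0 - K / D
    dG0 = 1.0 - G0 * (ert - 1.0) / D
    dr = rt * (1.0 - G0 * ert / D)
    return logG, np.column_stack([dK, dr, dG0])


def is_dead(intensities: np.ndarray, dead_threshold: float = DEFAULT_DEAD_THRESHOLD) -> bool:
    """Dead-culture rule: maximum intensity below ``dead_threshold`` × minimum."""
    y = np.asarray(intensities, dtype=float)
    return bool(y.max() < dead_threshold * y.min())


def _initial_rate(t, logy, ymax):
    """Slope of log-intensity vs time over the 10–90 % of max window."""
    y = np.exp(logy)
    mask = (y >= 0.1 * ymax) & (y <= 0.9 * ymax)
    if mask.sum() < 2:
        mask = np.ones_like(t, dtype=bool)
    slope = np.polyfit(t[mask], logy[mask], 1)[0]
    if not np.isfinite(slope) or slope <= 0:
        slope = 1.0
    return float(np.clip(slope, R_BOUNDS[0] * 1.01, R_BOUNDS[1] * 0.99))


def fit_logistic(curve: GrowthCurve,
                 dead_threshold: float = DEFAULT_DEAD_THRESHOLD) -> LogisticFit:
    """Least-squares logistic fit on log intensities for one culture.

    The objective is residuals of log observed vs log modelled intensity
    (matching multiplicative measurement noise), minimized over
    (log K, log r, log G0) with a trust-region reflective solver and an
    analytic jacobian.  Initialization uses K₀ = max intensity, G0₀ = min
    intensity and r₀ from the log-linear slope over the 10–90 % window; one
    retry from (2K₀, r₀/2, G0₀/2) precedes a ``failed`` verdict.
    """
    curve.validate()
    t = curve.times
    y = np.maximum(curve.intensities, INTENSITY_FLOOR)
    n = t.size
    if n < 4:
        raise InsufficientDataError(
            f"curve {curve.key} has {n} observations; at least 4 required")
    if is_dead(y, dead_threshold):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, n, "dead")

    logy = np.log(y)
    ymax, ymin = float(y.max()), float(y.min())
    k0, g00 = ymax, ymin
    r0 = _initial_rate(t, logy, ymax)

    lo = np.log([0.5 * ymax, R_BOUNDS[0], 0.1 * ymin])
    hi = np.log([10.0 * ymax, R_BOUNDS[1], ymax])

    def residuals(theta):
        return _log_model_and_jac(theta, t)[0] - logy

    def jac(theta):
        return _log_model_and_jac(theta, t)[1]

    # one retry from a perturbed start before declaring failure
    for K_init, r_init, G0_init in ((k0, r0, g00), (2.0 * k0, r0 / 2.0, g00 / 2.0)):
        x0 = np.clip(np.log([K_init, r_init, G0_init]), lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(residuals, x0, jac=jac, bounds=(lo, hi),
                                method="trf", x_scale="jac",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        K, r, G0 = np.exp(res.x)
        rss = float(2.0 * res.cost)
        if K > G0 > 0 and r > 0 and np.isfinite(rss):
            return LogisticFit(float(K), float(r), float(G0), rss, n, "ok")
    return LogisticFit(np.nan, np.nan, np.nan, np.nan, n, "failed")


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def compute_fitness(fit: LogisticFit) -> FitnessMeasure:
    """Convert a logistic fit into MDR, MDP and F = MDR × MDP.

    Dead or failed fits score (0, 0, 0).  MDP = log2(K/G0);
    MDR = r / ln[2(K − G0)/(K − 2G0)] when K > 2·G0, else the
    exponential-phase fallback r / ln 2 with ``doubling_capped`` set.
    """
    if fit.status != "ok":
        return FitnessMeasure(0.0, 0.0, 0.0)
    K, r, G0 = fit.K, fit.r, fit.G0
    mdp = float(np.log2(K / G0))
    if K > 2.0 * G0:
        mdr = float(r / np.log(2.0 * (K - G0) / (K - 2.0 * G0)))
        capped = False
    else:
        mdr = float(r / LN2)
        capped = True
    return FitnessMeasure(mdr, mdp, mdr * mdp, capped)


def fit_and_score(curve: GrowthCurve,
                  dead_threshold: float = DEFAULT_DEAD_THRESHOLD
                  ) -> tuple[LogisticFit, FitnessMeasure]:
    fit = fit_logistic(curve, dead_threshold)
    return fit, compute_fitness(fit)


def summarize_screen(curves: list[GrowthCurve],
                     dead_threshold: float = DEFAULT_DEAD_THRESHOLD
                     ) -> ScreenFitnessTable:
    """Fit every culture of one screen × background and aggregate per ORF.

    All curves must share ``screen_id`` and ``background``.  Dead and failed
    cultures contribute fitness 0 and are counted in ``n``.  ORFs are sorted
    lexicographically.
    """
    if not curves:
        raise InconsistencyError("no curves supplied")
    screen_ids = {c.screen_id for c in curves}
    backgrounds = {c.background for c in curves}
    if len(backgrounds) > 1:
        raise InconsistencyError(f"mixed backgrounds in screen input: {sorted(backgrounds)}")
    if len(screen_ids) > 1:
        raise InconsistencyError(f"mixed screen ids in screen input: {sorted(screen_ids)}")

    per_orf: dict[str, dict] = {}
    for curve in curves:
        _, fm = fit_and_score(curve, dead_threshold)
        rec = per_orf.setdefault(curve.orf, {"gene": curve.gene, "fitness": [],
                                             "mdr": [], "mdp": []})
        rec["fitness"].append(fm.fitness)
        rec["mdr"].append(fm.mdr)
        rec["mdp"].append(fm.mdp)

    rows = []
    for orf in sorted(per_orf):
        rec = per_orf[orf]
        reps = rec["fitness"]
        rows.append({
            "orf": orf,
            "gene": rec["gene"],
            "n": len(reps),
            "fitness_mean": float(np.mean(reps)),
            "fitness_median": float(np.median(reps)),
            "mdr_mean": float(np.mean(rec["mdr"])),
            "mdp_mean": float(np.mean(rec["mdp"])),
            "replicates": [float(v) for v in reps],
        })
    first = curves[0]
    return ScreenFitnessTable(first.screen_id, first.background, first.treatment,
                              pd.DataFrame(rows))
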