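"""Concentration-response analysis: activity calling and Hill AC50 estimation.

The analysis proceeds per chemical and endpoint axis:

1. A control band is set at the mean of the 0-concentration (vehicle)
   values ± 2 sample standard deviations. A series with every value inside
   the band has no effect; excursions only above give an upward trend, only
   below a downward trend, and excursions on both sides a U-shaped
   (nonmonotone) trend that yields no AC50.
2. Trending series are fit to a four-parameter Hill curve by nonlinear
   least squares with trend-specific anchoring: downward data keep the
   vehicle level as the top (1) with the bottom free in [0, 1]; upward data
   are shifted by -1 so the vehicle level is the bottom (0) with the top
   free (1 = a 100% increase).
3. The AC50 is the concentration on the fitted curve producing a 50% change
   from the control mean. Curves that never attain a 50% change yield an
   inactive call, which carries the matrix default of 1 M. Crossings beyond
   the top tested concentration are kept but flagged as extrapolated.

``HillCurveModel`` / ``HillCurveResults`` expose the fit itself;
``call_screen`` orchestrates the full calling over a processed screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .simulate import CELL_AXIS, DIFF_AXIS
from .icw import QC_OK

logger = logging.getLogger(__name__)

ENDPOINTS = ("cell_loss", "cell_gain", "diff_decrease", "diff_increase")

#: (axis, trend) -> endpoint called active on that trend
TREND_ENDPOINT = {
    (CELL_AXIS, "down"): "cell_loss",
    (CELL_AXIS, "up"): "cell_gain",
    (DIFF_AXIS, "down"): "diff_decrease",
    (DIFF_AXIS, "up"): "diff_increase",
}

INACTIVE_AC50_M = 1.0  # matrix default for no significant activity

CALL_COLUMNS = [
    "chemical", "endpoint", "active", "shape", "ac50_uM", "ac50_M",
    "hillslope", "top", "bottom", "extrapolated", "rss",
]


class InsufficientControlsError(ValueError):
    pass


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class ControlBand:
    """Vehicle-control variability band: mean ± 2 sample SD."""

    mean: float
    sd: float

    @property
    def low(self) -> float:
        return self.mean - 2.0 * self.sd

    @property
    def high(self) -> float:
        return self.mean + 2.0 * self.sd


def control_band(controls) -> ControlBand:
    values = np.asarray(controls, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise InsufficientControlsError("need >= 2 control values for the band")
    return ControlBand(float(values.mean()), float(values.std(ddof=1)))


@dataclass(frozen=True)
class ResponseSeries:
    """One chemical x axis concentration-response series.

    ``conc``/``value`` hold the treated points (individual replicate wells,
    positive concentrations); ``controls`` the 0-concentration values.
    """

    chemical: str
    endpoint_axis: str
    conc: np.ndarray
    value: np.ndarray
    controls: np.ndarray
    replicate_id: tuple = ()

    def __post_init__(self):
        if len(self.conc) == 0:
            raise DomainError("series needs at least one treated point")
        if np.any(np.asarray(self.conc) <= 0):
            raise DomainError("treated concentrations must be positive")

    @classmethod
    def from_responses(cls, responses: pd.DataFrame, chemical: str, axis: str):
        """Build a series from a processed-response table.

        Treated points are the chemical's own positive-concentration wells;
        controls are the 0-concentration records (vehicle wells of the
        chemical's plates, plus any 0-dose wells recorded under the
        chemical itself).
        """
        ok = responses[(responses["endpoint_axis"] == axis)
                       & (responses["qc_flag"] == QC_OK)]
        own = ok[ok["chemical"] == chemical]
        treated = own[own["conc_uM"] > 0]
        plates = set(own["plate_id"]) if "plate_id" in own.columns else None
        zero = ok[ok["conc_uM"] == 0]
        if plates is not None:
            zero = zero[zero["plate_id"].isin(plates)]
        controls = zero[
            (zero["chemical"] == chemical) | (zero["chemical"] == "VEHICLE")
        ]["value"].to_numpy(float)
        return cls(
            chemical, axis,
            treated["conc_uM"].to_numpy(float), treated["value"].to_numpy(float),
            controls, tuple(treated.get("replicate_id", ())),
        )


def classify_activity(series: ResponseSeries, band: ControlBand,
                      aggregate: str | None = "mean") -> str:
    """Classify the trend of a series against the control band.

    Values exactly on a band edge count as within the band. By default the
    rule is applied to per-concentration replicate means (``aggregate=None``
    tests every individual value), which keeps single spurious replicate
    excursions from turning a monotone series into a U-shape.
    """
    conc = np.asarray(series.conc, float)
    value = np.asarray(series.value, float)
    if aggregate == "mean":
        levels = np.unique(conc)
        value = np.array([value[conc == c].mean() for c in levels])
    above = bool(np.any(value > band.high))
    below = bool(np.any(value < band.low))
    if above and below:
        return "ushape"
    if above:
        return "up"
    if below:
        return "down"
    return "none"


# ---------------------------------------------------------------------------
# Hill model


def _hill_down(c, bottom, ac50, slope):
    return bottom + (1.0 - bottom) / (1.0 + (c / ac50) ** slope)


def _hill_up(c, top, ac50, slope):
    x = (c / ac50) ** slope
    return top * x / (1.0 + x)


@dataclass
class HillCurveResults:
    """Fitted four-parameter Hill curve (trend-specific anchoring).

    Parameters are on the vehicle-relative scale: for a downward fit the top
    is anchored at 1 and ``bottom`` is the residual plateau; for an upward
    fit the bottom is anchored at 0 on the shifted (value - 1) scale and
    ``top`` is the plateau increase (1 = a 100% increase over vehicle).
    """

    trend: str
    top: float
    bottom: float
    ac50_param: float  # Hill midpoint, concentration units of the input
    hillslope: float
    rss: float
    converged: bool
    n_obs: int = 0

    def predict(self, conc):
        """Fitted vehicle-relative response (original, unshifted scale)."""
        conc = np.asarray(conc, dtype=float)
        x = (conc / self.ac50_param) ** self.hillslope
        if self.trend == "down":
            return self.bottom + (self.top - self.bottom) / (1.0 + x)
        return 1.0 + self.bottom + (self.top - self.bottom) * x / (1.0 + x)

    def ac50_change(self) -> float | None:
        """Concentration producing a 50% change from control, if attained."""
        if not self.converged:
            return None
        if self.trend == "down":
            # response crosses 0.5 iff the curve spans it
            if not (self.bottom < 0.5 < self.top):
                return None
            x = (self.top - 0.5) / (0.5 - self.bottom)
        else:
            # shifted scale: change of 0.5 means adjusted response 0.5
            if not (self.bottom < 0.5 < self.top):
                return None
            x = (0.5 - self.bottom) / (self.top - 0.5)
        return float(self.ac50_param * x ** (1.0 / self.hillslope))

    def acf(self, F: float) -> float:
        """AC_F derived from the fitted AC50 and Hill slope."""
        ac50 = self.ac50_change()
        if ac50 is None:
            raise DomainError("curve does not attain a 50% change")
        return ac_f(ac50, self.hillslope, F)

    def summary(self) -> str:
        lines = [
            "Hill concentration-response fit",
            "=" * 39,
            f"{'trend':<22}{self.trend:>17}",
            f"{'n obs':<22}{self.n_obs:>17d}",
            f"{'converged':<22}{str(self.converged):>17}",
            f"{'top':<22}{self.top:>17.4g}",
            f"{'bottom':<22}{self.bottom:>17.4g}",
            f"{'AC50 (midpoint)':<22}{self.ac50_param:>17.4g}",
            f"{'Hill slope':<22}{self.hillslope:>17.4g}",
            f"{'RSS':<22}{self.rss:>17.4g}",
        ]
        ac50 = self.ac50_change()
        lines.append(f"{'AC50 (50% change)':<22}"
                     f"{(f'{ac50:.4g}' if ac50 is not None else 'not attained'):>17}")
        return "\n".join(lines)


class HillCurveModel:
    """Nonlinear least-squares Hill model for one trending series.

    Parameters
    ----------
    conc, response
        Treated concentrations (positive, any consistent unit) and
        vehicle-relative responses (vehicle = 1).
    trend
        "down" or "up"; selects the anchoring described in the module
        docstring.
    anchored
        With ``anchored=False`` all four parameters (top, bottom, midpoint,
        slope) are free — exposed for sensitivity analysis; the anchored
        variant is the default analysis path.
    """

    #: multi-start initial slopes; lowest-objective start wins
    SLOPE_STARTS = (0.5, 1.0, 4.0)
    #: Hill slopes steeper than ~8 are indistinguishable from a step at
    #: 4-concentration resolution and only destabilize the midpoint
    SLOPE_BOUNDS = (0.3, 8.0)
    #: prior SD (decades) of log10 slope for the empirical-Bayes shrinkage
    SLOPE_PRIOR_TAU = 0.2
    MAX_NFEV = 5000

    def __init__(self, conc, response, trend: str, anchored: bool = True):
        if trend not in ("down", "up"):
            raise DomainError(f"trend must be 'down' or 'up', got {trend!r}")
        self.conc = np.asarray(conc, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.conc.size < 4:
            raise DomainError("need >= 4 points for a four-parameter Hill fit")
        if np.any(self.conc <= 0):
            raise DomainError("concentrations must be positive")
        self.trend = trend
        self.anchored = anchored

    @classmethod
    def from_series(cls, series: ResponseSeries, trend: str, **kw):
        return cls(series.conc, series.value, trend, **kw)

    def fit(self) -> HillCurveResults:
        """Fit by penalized nonlinear least squares.

        Numerical choices, all aimed at the 4-concentration design:

        * the midpoint is optimized as log10(AC50) within ±3 decades of the
          tested range, initialized at the geometric-mean concentration;
        * downward fits minimize residuals on the log response scale (the
          intensity noise is multiplicative); upward fits stay on the
          shifted linear scale, where values may cross zero;
        * the log10 Hill slope carries an empirical-Bayes shrinkage toward
          1 (penalty weight s²/τ², with s² the residual variance of an
          unpenalized first pass and τ = ``SLOPE_PRIOR_TAU``), so sparse
          noisy designs cannot chase arbitrarily steep slopes while exact
          data are recovered exactly;
        * three slope starts, lowest objective wins.
        """
        c, y = self.conc, self.response
        lg = np.log10
        la_lo, la_hi = lg(c.min()) - 3.0, lg(c.max()) + 3.0
        la0 = float(np.clip(np.mean(lg(c)), la_lo, la_hi))
        s_lo, s_hi = self.SLOPE_BOUNDS

        if self.trend == "down":
            y_fit = y
            plateau0 = float(np.clip(min(y.mean(), y.min()), 0.0, 1.0))

            def predict(p):
                return _hill_down(c, p[0], 10.0 ** p[1], p[2])

            obs = np.log(np.clip(y_fit, 1e-6, None))

            def data_resid(p):
                return np.log(np.clip(predict(p), 1e-6, None)) - obs

            plateau_hi = 1.0
        else:
            y_fit = y - 1.0
            plateau0 = float(np.clip(y_fit.max(), 1e-3, 10.0))

            def predict(p):
                return _hill_up(c, p[0], 10.0 ** p[1], p[2])

            def data_resid(p):
                return predict(p) - y_fit

            plateau_hi = 10.0
        if not self.anchored:
            # fully-free four-parameter variant: see _fit_free
            return self._fit_free(y_fit, la_lo, la_hi, la0)

        bounds = ([0.0, la_lo, s_lo], [plateau_hi, la_hi, s_hi])

        def solve(weight):
            def resid(p):
                r = data_resid(p)
                if weight > 0:
                    r = np.concatenate([r, [np.sqrt(weight) * np.log10(p[2])]])
                return r

            best = None
            for s0 in self.SLOPE_STARTS:
                res = least_squares(
                    resid, x0=[plateau0, la0, s0], bounds=bounds,
                    method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                    max_nfev=self.MAX_NFEV,
                )
                if res.status == 0:
                    # budget exhausted: polish from the stall point at the
                    # default tolerances to obtain a clean termination status
                    res = least_squares(resid, x0=res.x, bounds=bounds,
                                        method="trf", max_nfev=1000)
                if not np.all(np.isfinite(res.x)):
                    continue
                obj = float(np.sum(res.fun**2))
                if best is None or obj < best[0]:
                    best = (obj, res)
            return best

        stage1 = solve(0.0)
        if stage1 is None:
            return HillCurveResults(self.trend, np.nan, np.nan, np.nan, np.nan,
                                    np.nan, False, c.size)
        s2 = float(np.sum(data_resid(stage1[1].x) ** 2)) / max(c.size - 3, 1)
        weight = s2 / self.SLOPE_PRIOR_TAU**2
        best = solve(weight) if weight > 1e-12 else stage1
        if best is None:  # pragma: no cover - stage 1 succeeded
            best = stage1
        _, res = best
        plateau, la, slope = res.x
        rss = float(np.sum((predict(res.x) - y_fit) ** 2))
        if self.trend == "down":
            top, bottom = 1.0, float(plateau)
        else:
            top, bottom = float(plateau), 0.0
        # a run that exhausts its evaluation budget but sits at a stationary
        # point (tiny projected gradient) is still a converged fit
        ok = bool(res.status > 0 or res.optimality < 1e-8)
        return HillCurveResults(self.trend, top, bottom, float(10.0 ** la),
                                float(slope), rss, ok, c.size)

    def _fit_free(self, y_fit, la_lo, la_hi, la0) -> HillCurveResults:
        """All four parameters free (sensitivity-analysis variant)."""
        c = self.conc
        s_lo, s_hi = self.SLOPE_BOUNDS

        def resid(p):
            top, bottom, la, slope = p
            x = (c / 10.0 ** la) ** slope
            return bottom + (top - bottom) * (x / (1 + x) if self.trend == "up"
                                              else 1 / (1 + x)) - y_fit

        lo = [-10.0, -10.0, la_lo, s_lo]
        hi = [10.0, 10.0, la_hi, s_hi]
        y0, y1 = float(np.median(y_fit[c <= np.median(c)])), float(
            np.median(y_fit[c > np.median(c)]))
        best = None
        for s0 in self.SLOPE_STARTS:
            res = least_squares(resid, x0=[max(y0, y1), min(y0, y1), la0, s0],
                                bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                max_nfev=self.MAX_NFEV)
            if not np.all(np.isfinite(res.x)):
                continue
            rss = float(np.sum(res.fun**2))
            if best is None or rss < best[0]:
                best = (rss, res)
        if best is None:
            return HillCurveResults(self.trend, np.nan, np.nan, np.nan, np.nan,
                                    np.nan, False, c.size)
        rss, res = best
        top, bottom, la, slope = res.x
        return HillCurveResults(self.trend, float(top), float(bottom),
                                float(10.0 ** la), float(slope), rss,
                                bool(res.status > 0), c.size)


def fit_hill(series: ResponseSeries, shape: str, **kw) -> HillCurveResults:
    """Fit the trend-specific Hill model to a series; never raises on failure."""
    try:
        return HillCurveModel.from_series(series, shape, **kw).fit()
    except DomainError:
        raise
    except Exception:  # pragma: no cover
        return HillCurveResults(shape, np.nan, np.nan, np.nan, np.nan, np.nan, False, 0)


def ac_f(ac50: float, hillslope: float, F: float) -> float:
    """Concentration producing an F-percent change from control.

    The Hill inversion AC_F = AC50 * (F / (100 - F))**(1 / |Hillslope|);
    monotone increasing in F with AC_50 as the fixed point at F = 50.
    """
    if not 0 < F < 100:
        raise DomainError("F must lie in (0, 100)")
    if not ac50 > 0:
        raise DomainError("ac50 must be positive")
    if hillslope == 0:
        raise DomainError("hillslope must be nonzero")
    return float(ac50 * (F / (100.0 - F)) ** (1.0 / abs(hillslope)))


# ---------------------------------------------------------------------------
# Activity calls


@dataclass(frozen=True)
class ActivityCall:
    """Final call for one chemical x endpoint; inactive carries 1 M."""

    chemical: str
    endpoint: str
    active: bool
    shape: str
    ac50_uM: float = np.nan
    hillslope: float = np.nan
    top: float = np.nan
    bottom: float = np.nan
    extrapolated: bool = False
    rss: float = np.nan

    @property
    def ac50_M(self) -> float:
        if not self.active:
            return INACTIVE_AC50_M
        return self.ac50_uM * 1e-6


def ac50_from_fit(fit: HillCurveResults, series: ResponseSeries, shape: str,
                  max_conc: float | None = None) -> ActivityCall:
    """Assign the AC50 from a fitted curve for the endpoint matching its trend.

    Inactive (1 M default) when the fit failed or the curve never attains a
    50% change from control; flagged ``extrapolated`` when the crossing lies
    above the top tested concentration.
    """
    endpoint = TREND_ENDPOINT[(series.endpoint_axis, shape)]
    if max_conc is None:
        max_conc = float(np.max(series.conc))
    ac50 = fit.ac50_change() if fit.converged else None
    if ac50 is None:
        return ActivityCall(series.chemical, endpoint, False, shape,
                            hillslope=fit.hillslope, top=fit.top,
                            bottom=fit.bottom, rss=fit.rss)
    return ActivityCall(
        series.chemical, endpoint, True, shape, ac50_uM=float(ac50),
        hillslope=fit.hillslope, top=fit.top, bottom=fit.bottom,
        extrapolated=bool(ac50 > max_conc), rss=fit.rss,
    )


def _axis_calls(series: ResponseSeries | None, axis: str, chemical: str,
                aggregate: str | None = "mean") -> list[ActivityCall]:
    down_ep = TREND_ENDPOINT[(axis, "down")]
    up_ep = TREND_ENDPOINT[(axis, "up")]
    if series is None or len(series.controls) < 2:
        logger.warning("missing %s data for %s", axis, chemical)
        return [ActivityCall(chemical, ep, False, "missing") for ep in (down_ep, up_ep)]
    band = control_band(series.controls)
    shape = classify_activity(series, band, aggregate=aggregate)
    if shape in ("none", "ushape"):
        return [ActivityCall(chemical, ep, False, shape) for ep in (down_ep, up_ep)]
    try:
        fit = fit_hill(series, shape)
    except DomainError:  # fewer than 4 points
        logger.warning("too few points to fit %s/%s", chemical, axis)
        return [ActivityCall(chemical, ep, False, "missing") for ep in (down_ep, up_ep)]
    call = ac50_from_fit(fit, series, shape)
    other_ep = up_ep if call.endpoint == down_ep else down_ep
    return [call, ActivityCall(chemical, other_ep, False, shape)]


def call_screen(responses: pd.DataFrame, aggregate: str | None = "mean") -> pd.DataFrame:
    """Activity calls for every chemical x four endpoints of a processed screen."""
    calls: list[ActivityCall] = []
    chemicals = sorted(c for c in responses["chemical"].unique() if c != "VEHICLE")
    for chemical in chemicals:
        for axis in (CELL_AXIS, DIFF_AXIS):
            try:
                series = ResponseSeries.from_responses(responses, chemical, axis)
            except DomainError:
                series = None
            calls.extend(_axis_calls(series, axis, chemical, aggregate=aggregate))
    rows = [
        (c.chemical, c.endpoint, c.active, c.shape, c.ac50_uM, c.ac50_M,
         c.hillslope, c.top, c.bottom, c.extrapolated, c.rss)
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    order = {ep: i for i, ep in enumerate(ENDPOINTS)}
    return df.sort_values(["chemical", "endpoint"],
                          key=lambda s: s.map(order) if s.name == "endpoint" else s,
                          ignore_index=True)


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(path)
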