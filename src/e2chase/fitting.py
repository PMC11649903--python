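"""Estimation of discharge rate constants from chase time courses.

The central object is :class:`DischargeModel`, a statsmodels-style model built
from a :class:`ChaseDesign` (one or more paired time courses at fixed
nucleophile concentrations).  ``DischargeModel.fit()`` performs a global
Levenberg-Marquardt least-squares fit of the mono-ubiquitin band signal

    y(t) = E2L0 * exp(-k_obs t) + (k3*E2L0/k_obs) * (1 - exp(-k_obs t)),
    k_obs = k1 + k2*[Nu] + k3,

with E2L0, k1, k2, k3 shared across courses and [Nu] fixed per course, and
returns a :class:`DischargeResults` carrying estimates, standard errors, the
parameter covariance and a ``summary()`` table.

Rate constants are fitted on a log scale, which enforces positivity without
explicit bounds and equalises step sizes across rates spanning orders of
magnitude; standard errors are mapped back to the natural scale by the delta
method.  Auxiliary fits (mono/double exponential, linear rate-vs-concentration,
pH dose-response) and the fold-change / solvent-isotope arithmetic used to
compare enzyme variants live here as plain functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, curve_fit

from .kinetics import KineticParams, TimeCourse

__all__ = [
    "ChaseDesign",
    "DischargeModel",
    "DischargeResults",
    "RateWithError",
    "DoubleExpFit",
    "LinearFit",
    "DoseResponseFit",
    "IsotopeRatioSummary",
    "fit_global_discharge",
    "fit_mono_exponential",
    "fit_double_exponential",
    "fit_linear_rate_vs_conc",
    "fit_ph_dose_response",
    "fold_change_with_error",
    "solvent_isotope_ratio",
    "average_rates",
]

_PARAM_ORDER = ("E2L0", "k1", "k2", "k3")
_LOG_FLOOR = 1e-12  # rate floor on the log-fit scale; estimates at the floor read as zero


@dataclass(frozen=True)
class RateWithError:
    """A rate constant (or ratio of rates) with its standard deviation."""

    value: float
    sd: float
    flagged: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass
class ChaseDesign:
    """A set of time courses fitted jointly with shared parameters.

    Each course carries its own fixed nucleophile concentration; the kinetic
    parameters listed in *shared* are common to all courses (the default
    shares all four, matching the paired nu=0 / nu>0 assay layout).
    """

    courses: list[TimeCourse]
    shared: tuple[str, ...] = _PARAM_ORDER

    def __post_init__(self) -> None:
        if not self.courses:
            raise ValueError("ChaseDesign requires at least one course")
        for c in self.courses:
            if c.nu < 0:
                raise ValueError("every course must have nu >= 0")
        unknown = set(self.shared) - set(_PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown shared parameters: {sorted(unknown)}")

    @property
    def n_points(self) -> int:
        return sum(len(c) for c in self.courses)


class DischargeModel:
    """Global shared-parameter model of paired E2~Ub chase time courses.

    Parameters
    ----------
    design : ChaseDesign or list of TimeCourse
        The courses to fit jointly.  All must use the ``mono_band``-type
        observable (a fraction decaying from E2L0).
    apparent : bool
        Set for RING-containing reactions: the recovered constants are then
        apparent values, valid only at that E3 concentration, because
        discharge proceeds from a mixture of RING-bound and free E2~Ub.
    """

    def __init__(self, design: ChaseDesign | list[TimeCourse], apparent: bool = False):
        if isinstance(design, list):
            design = ChaseDesign(courses=design)
        self.design = design
        self.apparent = apparent

    # -- model function -------------------------------------------------

    @staticmethod
    def _signal(t: np.ndarray, nu: float, E2L0: float, k1: float, k2: float,
                k3: float) -> np.ndarray:
        kobs = k1 + k2 * nu + k3
        if kobs <= 0:
            return np.full_like(t, E2L0)
        decay = np.exp(-kobs * t)
        return E2L0 * decay + (k3 * E2L0 / kobs) * (1.0 - decay)

    # -- initialisation -------------------------------------------------

    def _default_init(self, fix: dict[str, float]) -> KineticParams:
        """Deterministic starting values.

        k1 from a mono-exponential pre-fit of the lowest-nu course; k2 from
        (k_obs(nu) - k1)/nu of the highest-nu course; k3 from the late-time
        plateau of the lowest-nu course; E2L0 from its first sample.
        """
        courses = sorted(self.design.courses, key=lambda c: c.nu)
        low, high = courses[0], courses[-1]
        e2l0 = float(np.clip(low.signal[0], 0.05, 1.0))

        def _kobs(course: TimeCourse) -> float:
            try:
                r = fit_mono_exponential(course)
                return max(r.value, 0.0)
            except Exception:
                return 0.0

        k1 = fix.get("k1", max(_kobs(low), _LOG_FLOOR))
        if "k2" in fix:
            k2 = fix["k2"]
        elif high.nu > 0:
            k2 = max((_kobs(high) - k1) / high.nu, _LOG_FLOOR)
        else:
            k2 = _LOG_FLOOR
        if "k3" in fix:
            k3 = fix["k3"]
        else:
            plateau = float(np.clip(low.signal[-1] / max(e2l0, 1e-9), 0.0, 0.9))
            k3 = max(plateau * k1, _LOG_FLOOR)
        return KineticParams(k1=k1, k2=k2, k3=k3, E2L0=e2l0)

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        init: KineticParams | None = None,
        fix: dict[str, float] | None = None,
    ) -> "DischargeResults":
        """Global least-squares fit; returns a :class:`DischargeResults`.

        Parameters
        ----------
        init : KineticParams, optional
            Starting values; derived from the data if omitted.
        fix : dict, optional
            Parameters held constant, e.g. ``{"k2": 0.0, "k3": 0.0}`` for a
            hydrolysis-only fit.
        """
        fix = dict(fix or {})
        unknown = set(fix) - set(_PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
        if init is None:
            init = self._default_init(fix)
        free = [p for p in _PARAM_ORDER if p not in fix]
        init_map = {
            "E2L0": init.E2L0, "k1": init.k1, "k2": init.k2, "k3": init.k3,
        }
        init_map.update(fix)

        def to_theta(values: dict[str, float]) -> np.ndarray:
            out = []
            for p in free:
                v = values[p]
                out.append(v if p == "E2L0" else np.log(max(v, _LOG_FLOOR)))
            return np.array(out)

        def from_theta(theta: np.ndarray) -> dict[str, float]:
            values = dict(init_map)
            for p, th in zip(free, theta):
                values[p] = th if p == "E2L0" else float(np.exp(th))
            return values

        t_all = [c.times for c in self.design.courses]
        y_all = [c.signal for c in self.design.courses]
        nu_all = [c.nu for c in self.design.courses]

        def residuals(theta: np.ndarray) -> np.ndarray:
            v = from_theta(theta)
            res = [
                self._signal(t, nu, v["E2L0"], v["k1"], v["k2"], v["k3"]) - y
                for t, y, nu in zip(t_all, y_all, nu_all)
            ]
            return np.concatenate(res)

        theta0 = to_theta(init_map)
        sol = least_squares(residuals, theta0, method="lm", xtol=1e-14,
                            ftol=1e-14, gtol=1e-14, max_nfev=20000)
        values = from_theta(sol.x)
        n, p = self.design.n_points, len(free)
        dof = max(n - p, 1)
        s2 = 2.0 * sol.cost / dof

        # covariance on the transformed scale, then delta method back
        jtj = sol.jac.T @ sol.jac
        try:
            cov_theta = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov_theta = np.linalg.pinv(jtj) * s2
        deriv = np.array(
            [1.0 if pname == "E2L0" else values[pname] for pname in free]
        )
        cov_free = cov_theta * np.outer(deriv, deriv)
        cov_free = 0.5 * (cov_free + cov_free.T)

        stderr = {pname: 0.0 for pname in _PARAM_ORDER}
        for i, pname in enumerate(free):
            stderr[pname] = float(np.sqrt(max(cov_free[i, i], 0.0)))

        params = KineticParams(
            k1=values["k1"], k2=values["k2"], k3=values["k3"],
            E2L0=float(np.clip(values["E2L0"], 1e-9, 1.0)),
        )
        resid = residuals(sol.x)
        return DischargeResults(
            model=self,
            params=params,
            stderr=stderr,
            cov=cov_free,
            free_names=tuple(free),
            fixed=fix,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            converged=bool(sol.success),
            n_points=n,
            apparent=self.apparent,
        )


@dataclass
class DischargeResults:
    """Fit results: estimates, uncertainties and diagnostics.

    ``stderr`` maps parameter names to standard errors (0 for fixed
    parameters); ``cov`` is the covariance of the free parameters on the
    natural scale, ordered as ``free_names``.
    """

    model: DischargeModel
    params: KineticParams
    stderr: dict[str, float]
    cov: np.ndarray
    free_names: tuple[str, ...]
    fixed: dict[str, float]
    residual_rms: float
    converged: bool
    n_points: int
    apparent: bool = False

    def __getitem__(self, name: str) -> RateWithError:
        value = getattr(self.params, name)
        return RateWithError(value=float(value), sd=self.stderr[name], label=name)

    def half_life(self) -> float:
        """Hydrolysis half-life ln2/k1 in minutes."""
        from .kinetics import half_life_from_rate

        return half_life_from_rate(self.params.k1)

    def summary(self) -> str:
        units = {"E2L0": "-", "k1": "1/min", "k2": "1/(mM*min)", "k3": "1/min"}
        lines = [
            "Global E2~Ub discharge fit"
            + ("  [APPARENT rate constants: RING-containing reaction]" if self.apparent else ""),
            f"  courses: {len(self.model.design.courses)}   points: {self.n_points}"
            f"   residual RMS: {self.residual_rms:.4g}   converged: {self.converged}",
            f"  {'param':<6} {'estimate':>12} {'stderr':>12} {'unit':>12}  note",
        ]
        for name in _PARAM_ORDER:
            note = "fixed" if name in self.fixed else ""
            lines.append(
                f"  {name:<6} {getattr(self.params, name):>12.4g}"
                f" {self.stderr[name]:>12.4g} {units[name]:>12}  {note}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": {n: getattr(self.params, n) for n in _PARAM_ORDER},
            "stderr": dict(self.stderr),
            "covariance": self.cov.tolist(),
            "free": list(self.free_names),
            "fixed": dict(self.fixed),
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "n_points": self.n_points,
            "apparent": self.apparent,
        }


def fit_global_discharge(
    design: ChaseDesign | list[TimeCourse],
    init: KineticParams | None = None,
    fix: dict[str, float] | None = None,
    apparent: bool = False,
) -> DischargeResults:
    """Convenience wrapper: build a :class:`DischargeModel` and fit it."""
    return DischargeModel(design, apparent=apparent).fit(init=init, fix=fix)


def average_rates(results: list[DischargeResults], name: str) -> RateWithError:
    """Fit-then-average across replicate experiments.

    Mirrors the reporting convention for replicate assays: each experiment is
    fitted separately and the rate constants are averaged, with the spread of
    the per-fit estimates (SD) as the error.
    """
    if not results:
        raise ValueError("need at least one fit result")
    vals = np.array([getattr(r.params, name) for r in results])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return RateWithError(value=float(np.mean(vals)), sd=sd, label=name)


# ---------------------------------------------------------------------------
# auxiliary fits
# ---------------------------------------------------------------------------


def fit_mono_exponential(course: TimeCourse) -> RateWithError:
    """Fit A*exp(-k_obs*t) + C; returns k_obs with its standard error.

    Used for fluorescence anisotropy traces and single hydrolysis-only
    courses.  Non-decaying data yields a k_obs near zero with a large
    standard error, flagged.
    """
    t, y = course.times, course.signal
    if len(t) < 4:
        raise ValueError(f"need >= 4 points for a mono-exponential fit, got {len(t)}")
    c0 = float(np.min(y))
    a0 = float(y[0] - c0)
    span = float(t[-1] - t[0]) or 1.0
    # crude decay-rate guess from the time to reach halfway between ends
    k0 = 2.0 / span
    if a0 > 0:
        half = c0 + 0.5 * a0
        below = np.flatnonzero(y <= half)
        if below.size:
            t_half = float(t[below[0]]) - float(t[0])
            if t_half > 0:
                k0 = np.log(2.0) / t_half

    def f(t, a, k, c):
        return a * np.exp(-k * t) + c

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(f, t, y, p0=[a0 if a0 != 0 else 1.0, k0, c0],
                                   maxfev=20000)
        k = float(popt[1])
        ksd = float(np.sqrt(max(pcov[1, 1], 0.0)))
        if not np.isfinite(ksd):
            # singular covariance: an exact fit (zero residual) is fine,
            # anything else is unidentifiable
            resid_rms = float(np.sqrt(np.mean((f(t, *popt) - y) ** 2)))
            scale = max(float(np.ptp(y)), 1e-300)
            ksd = 0.0 if resid_rms <= 1e-10 * scale else np.inf
    except RuntimeError:
        k, ksd = 0.0, np.inf
    flagged = (k <= 0) or not np.isfinite(ksd) or (k > 0 and ksd >= abs(k) > 0 and ksd > 0)
    if flagged:
        # non-decaying / unidentifiable: report a rate near zero, large stderr
        ksd = max(ksd if np.isfinite(ksd) else 0.0, abs(k), 1.0)
        k = 0.0
    return RateWithError(value=k, sd=ksd, flagged=flagged, label="k_obs")


@dataclass(frozen=True)
class DoubleExpFit:
    """Parameters of A1*exp(-ka*t) + A2*exp(-kb*t) + C with ka >= kb."""

    A1: float
    ka: float
    A2: float
    kb: float
    C: float
    stderr: tuple[float, float, float, float, float]
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.ka, self.A2, self.kb, self.C])


def fit_double_exponential(course: TimeCourse) -> DoubleExpFit:
    """Fit a sum of two exponentials plus offset.

    The components are ordered so the faster rate is first (ka >= kb).  A fit
    in which the two rates collapse onto each other is flagged ``degenerate``
    (the data support only a mono-exponential).
    """
    t, y = course.times, course.signal
    if len(t) < 6:
        raise ValueError(f"need >= 6 points for a double-exponential fit, got {len(t)}")
    mono = fit_mono_exponential(course)
    k_mid = mono.value if mono.value > 0 else 1.0 / max(float(t[-1] - t[0]), 1.0)
    c0 = float(np.min(y)) if y[0] >= y[-1] else float(np.max(y))
    a_tot = float(y[0] - c0)

    def f(t, a1, ka, a2, kb, c):
        return a1 * np.exp(-ka * t) + a2 * np.exp(-kb * t) + c

    p0 = [a_tot / 2 or 0.5, 4.0 * k_mid, a_tot / 2 or 0.5, k_mid / 4.0, c0]
    popt, pcov = curve_fit(f, t, y, p0=p0, maxfev=50000)
    a1, ka, a2, kb, c = popt
    err = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    ka, kb = abs(ka), abs(kb)
    if ka < kb:
        a1, a2, ka, kb = a2, a1, kb, ka
        err = err[[2, 3, 0, 1, 4]]
    degenerate = ka > 0 and (ka - kb) < 1e-3 * ka
    return DoubleExpFit(A1=float(a1), ka=float(ka), A2=float(a2), kb=float(kb),
                        C=float(c), stderr=tuple(float(e) for e in err),
                        degenerate=degenerate)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    slope_sd: float
    intercept: float
    intercept_sd: float
    residual_rms: float


def fit_linear_rate_vs_conc(points: list[tuple[float, float]]) -> LinearFit:
    """Ordinary least-squares line through (concentration, k_obs) points.

    The intercept is the rate in the absence of the titrated species (for
    RING titrations, the E3-free rate).  Requires at least two distinct
    concentrations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, k_obs) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct concentrations")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (slope * x + intercept)
    s2 = float(np.sum(resid**2) / (n - 2)) if n > 2 else 0.0
    return LinearFit(
        slope=slope,
        slope_sd=float(np.sqrt(s2 / sxx)),
        intercept=intercept,
        intercept_sd=float(np.sqrt(s2 * (1.0 / n + xm**2 / sxx))),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass(frozen=True)
class DoseResponseFit:
    """4-parameter logistic in pH: floor + (ceiling-floor)/(1+10^(slope*(mid-pH)))."""

    floor: float
    ceiling: float
    midpoint: float
    slope: float
    midpoint_sd: float
    stderr: tuple[float, float, float, float]
    flagged: bool = False


def fit_ph_dose_response(points: list[tuple[float, float]]) -> DoseResponseFit:
    """Fit k_obs vs pH with a 4-parameter logistic; the midpoint is the apparent pKa.

    Flat data (ceiling ~ floor) leaves the midpoint unidentifiable; the result
    is flagged rather than rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need >= 5 (pH, k_obs) points")
    ph, y = pts[:, 0], pts[:, 1]

    def f(ph, lo, hi, mid, slope):
        return lo + (hi - lo) / (1.0 + 10.0 ** (slope * (mid - ph)))

    lo0, hi0 = float(np.min(y)), float(np.max(y))
    span = hi0 - lo0
    if span <= 1e-12 * max(abs(hi0), 1.0):
        return DoseResponseFit(floor=lo0, ceiling=hi0, midpoint=float(np.mean(ph)),
                               slope=0.0, midpoint_sd=np.inf,
                               stderr=(0.0, 0.0, np.inf, np.inf), flagged=True)
    mid0 = float(ph[np.argmin(np.abs(y - (lo0 + span / 2)))])
    try:
        popt, pcov = curve_fit(f, ph, y, p0=[lo0, hi0, mid0, 1.0], maxfev=50000)
    except RuntimeError:
        return DoseResponseFit(floor=lo0, ceiling=hi0, midpoint=mid0, slope=0.0,
                               midpoint_sd=np.inf,
                               stderr=(np.inf,) * 4, flagged=True)
    err = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    mid_sd = float(err[2])
    flagged = not np.isfinite(mid_sd)
    return DoseResponseFit(floor=float(popt[0]), ceiling=float(popt[1]),
                           midpoint=float(popt[2]), slope=float(popt[3]),
                           midpoint_sd=mid_sd,
                           stderr=tuple(float(e) for e in err), flagged=flagged)


def fold_change_with_error(wt: RateWithError, mut: RateWithError) -> RateWithError:
    """Fold difference k_WT/k_Mut with propagated error.

    error = ratio * sqrt((sd_WT/k_WT)^2 + (sd_Mut/k_Mut)^2)
    """
    if mut.value <= 0:
        raise ValueError("mutant rate must be > 0 (fold change undefined)")
    if wt.value <= 0:
        raise ValueError("wild-type rate must be > 0")
    ratio = wt.value / mut.value
    err = ratio * np.sqrt((wt.sd / wt.value) ** 2 + (mut.sd / mut.value) ** 2)
    return RateWithError(value=float(ratio), sd=float(err),
                         label=f"{wt.label or 'WT'}/{mut.label or 'Mut'}")


@dataclass(frozen=True)
class IsotopeRatioSummary:
    """Per-pair H2O/D2O rate ratios with mean and SD across paired experiments."""

    ratios: tuple[float, ...]
    mean: float
    sd: float


def solvent_isotope_ratio(k_h2o, k_d2o) -> IsotopeRatioSummary:
    """Kinetic solvent isotope effect from paired H2O / D2O experiments.

    Each pair comes from experiments performed in parallel; the KSIE is the
    per-pair ratio k(H2O)/k(D2O), summarised by mean and SD across pairs.
    A ratio well above 1 indicates rate-limiting proton transfer, the
    signature of general base catalysis.
    """
    k_h = np.asarray(k_h2o, dtype=float)
    k_d = np.asarray(k_d2o, dtype=float)
    if k_h.shape != k_d.shape or k_h.ndim != 1:
        raise ValueError("k_h2o and k_d2o must be 1-D sequences of equal length")
    if k_h.size == 0:
        raise ValueError("need at least one pair")
    if np.any(k_h <= 0) or np.any(k_d <= 0):
        raise ValueError("all rates must be > 0")
    ratios = k_h / k_d
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return IsotopeRatioSummary(ratios=tuple(float(r) for r in ratios),
                               mean=float(np.mean(ratios)), sd=sd)
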