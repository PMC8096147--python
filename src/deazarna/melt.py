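"""Two-state thermodynamic analysis of UV melting profiles.

An RNA strand is assumed to populate only a folded and an unfolded state,
so a single equilibrium constant K(T) governs the transition.  The link
between K, the folded fraction theta and total strand concentration c_T
depends on molecularity:

    hairpin (unimolecular)          K = theta / (1 - theta)
    self-complementary duplex       K = theta / (2 c_T (1 - theta)^2)
    non-self-complementary duplex   K = 2 theta / (c_T (1 - theta)^2)
        (both strands mixed 1:1, each at c_T / 2; theta is the fraction
         of strands in duplex)

with K(T) = exp(-(dH - T dS / 1000) * 1000 / (R T)), dH in kcal/mol and
dS in cal mol^-1 K^-1.  Absorbance is modelled as a theta-weighted mix of
two linear baselines (folded below, unfolded above: hypochromicity).

Two estimation routes are provided, mirroring common practice:

* :class:`TwoStateMeltModel` — nonlinear least squares of a single curve
  (van't Hoff analysis of the curve shape);
* :class:`TmConcentrationModel` — linear regression of 1/Tm against
  ln(c_T) (self-complementary) or ln(c_T / 4) (non-self), which is only
  informative for bimolecular systems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal, stats

from .constants import R_CAL, T_REF, ZERO_C, celsius_to_kelvin, kelvin_to_celsius
from .seqmod import Molecularity

__all__ = [
    "MeltingCurve",
    "BaselinePair",
    "ThermoParams",
    "TwoStateMeltModel",
    "MeltResults",
    "TmConcentrationModel",
    "NoTransitionError",
    "FitConvergenceError",
    "tm_first_derivative",
    "fit_baselines",
    "van_t_hoff_fit",
    "tm_concentration_fit",
    "delta_g",
    "compare_to_reference",
    "aggregate_replicates",
    "equilibrium_constant",
    "theta_two_state",
    "tm_from_params",
    "read_melting_csv",
]


class NoTransitionError(RuntimeError):
    """The derivative maximum sits at the edge: no transition in range."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed; carries the last iterate for diagnostics."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MeltingCurve:
    """A UV absorbance-versus-temperature trace for one sample.

    Parameters
    ----------
    temperature : array
        Temperatures in degrees Celsius, strictly increasing.
    absorbance : array
        Absorbance (AU), same length; increases on melting.
    c_t : float
        Total strand concentration in mol/L.  Required (positive) for
        bimolecular models.
    molecularity : Molecularity
        How the folded state forms; set explicitly by design.
    """

    temperature: np.ndarray
    absorbance: np.ndarray
    c_t: float = np.nan
    molecularity: Molecularity = Molecularity.UNIMOLECULAR_HAIRPIN
    wavelength_nm: float = 260.0
    path_length_mm: float = 10.0
    replicate_id: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.temperature.shape != self.absorbance.shape:
            raise ValueError("temperature and absorbance lengths differ")
        if self.temperature.size < 20:
            raise ValueError("melting curve needs at least 20 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.molecularity.bimolecular and not (self.c_t > 0):
            raise ValueError("bimolecular curve requires c_t > 0")

    @property
    def temperature_k(self) -> np.ndarray:
        return celsius_to_kelvin(self.temperature)


@dataclass
class BaselinePair:
    """Linear folded / unfolded absorbance baselines, A = slope * T_C + intercept."""

    folded_slope: float
    folded_intercept: float
    unfolded_slope: float
    unfolded_intercept: float

    def folded(self, t_c):
        return self.folded_slope * np.asarray(t_c) + self.folded_intercept

    def unfolded(self, t_c):
        return self.unfolded_slope * np.asarray(t_c) + self.unfolded_intercept


@dataclass
class ThermoParams:
    """Fitted two-state thermodynamic parameters.

    dh in kcal/mol, ds in cal mol^-1 K^-1, dg298 in kcal/mol at 298.15 K,
    tm in degrees Celsius.  ``error_kind`` says whether the ``*_err``
    fields are standard errors ("se") or 95 % confidence half-widths
    ("ci95").
    """

    dh: float
    ds: float
    tm: float
    dg298: Optional[float] = None
    dh_err: float = np.nan
    ds_err: float = np.nan
    tm_err: float = np.nan
    dg298_err: float = np.nan
    error_kind: Optional[str] = None
    molecularity: Optional[Molecularity] = None
    source: str = ""
    n: int = 1
    flags: tuple = ()

    def __post_init__(self):
        if self.dg298 is None:
            self.dg298 = delta_g(self.dh, self.ds)

    def as_dict(self) -> dict:
        return {
            "dH_kcal_mol": self.dh,
            "dS_cal_mol_K": self.ds,
            "dG298_kcal_mol": self.dg298,
            "Tm_C": self.tm,
            "dH_err": self.dh_err,
            "dS_err": self.ds_err,
            "dG298_err": self.dg298_err,
            "Tm_err": self.tm_err,
            "error_kind": self.error_kind,
            "molecularity": self.molecularity.value if self.molecularity else None,
            "source": self.source,
            "n": self.n,
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def equilibrium_constant(t_k, dh, ds):
    """K(T) from dH (kcal/mol) and dS (cal/mol/K); exponent clipped for safety."""
    t_k = np.asarray(t_k, dtype=float)
    expo = -(dh * 1000.0 - t_k * ds) / (R_CAL * t_k)
    return np.exp(np.clip(expo, -500.0, 500.0))


def _theta_quadratic(a):
    # smaller root of a*x^2 - (2a+1)*x + a = 0, in [0, 1]; stable for a -> 0
    a = np.asarray(a, dtype=float)
    return np.where(
        a > 0, 2.0 * a / ((2.0 * a + 1.0) + np.sqrt(4.0 * a + 1.0)), 0.0
    )


def theta_two_state(t_k, dh, ds, molecularity, c_t=np.nan):
    """Folded fraction theta(T) for the given molecularity."""
    k = equilibrium_constant(t_k, dh, ds)
    if molecularity is Molecularity.UNIMOLECULAR_HAIRPIN:
        return k / (1.0 + k)
    if not (c_t > 0):
        raise ValueError("bimolecular theta requires c_t > 0")
    if molecularity is Molecularity.BIMOLECULAR_SELF_COMPLEMENTARY:
        return _theta_quadratic(2.0 * c_t * k)
    return _theta_quadratic(0.5 * c_t * k)


def tm_from_params(dh, ds, molecularity, c_t=np.nan):
    """Closed-form temperature (K) at which theta = 1/2.

    Hairpin: Tm = 1000 dH / dS.  Bimolecular: 1/Tm is linear in ln(c_T)
    (self-complementary) or ln(c_T/4) (non-self-complementary).
    """
    if molecularity is Molecularity.UNIMOLECULAR_HAIRPIN:
        return 1000.0 * dh / ds
    if not (c_t > 0):
        raise ValueError("bimolecular Tm requires c_t > 0")
    if molecularity is Molecularity.BIMOLECULAR_SELF_COMPLEMENTARY:
        x = np.log(c_t)
    else:
        x = np.log(c_t / 4.0)
    return 1000.0 * dh / (R_CAL * x + ds)


def _ds_from_dh_tm(dh, tm_k, molecularity, c_t):
    # invert tm_from_params for the (dH, Tm) fit parameterisation
    if molecularity is Molecularity.UNIMOLECULAR_HAIRPIN:
        return 1000.0 * dh / tm_k
    if molecularity is Molecularity.BIMOLECULAR_SELF_COMPLEMENTARY:
        return 1000.0 * dh / tm_k - R_CAL * np.log(c_t)
    return 1000.0 * dh / tm_k - R_CAL * np.log(c_t / 4.0)


# ---------------------------------------------------------------------------
# derivative Tm
# ---------------------------------------------------------------------------

def tm_first_derivative(curve: MeltingCurve, window: int = 11, polyorder: int = 3,
                        theta: Optional[np.ndarray] = None) -> float:
    """Melting temperature from the maximum of the smoothed first derivative.

    The derivative of absorbance with respect to temperature is taken with
    a Savitzky-Golay local-polynomial filter (default window 11 points,
    order 3) on a uniform grid, and the maximum is refined by parabolic
    interpolation of the three points around it.  Pass ``theta`` to take
    the derivative of the folded fraction instead of raw absorbance (the
    maximum of -d(theta)/dT coincides with that of dA/dT for flat
    baselines).

    Returns the melting temperature in degrees Celsius.

    Raises
    ------
    NoTransitionError
        If the derivative maximum falls in the edge windows, i.e. the
        curve is featureless or the transition is truncated.
    """
    t = curve.temperature
    y = curve.absorbance if theta is None else -np.asarray(theta, dtype=float)
    n = t.size
    window = min(window if window % 2 == 1 else window + 1, n - (1 - n % 2))
    if polyorder >= window:
        polyorder = window - 1
    # resample to a uniform grid so the filter's delta is exact
    tu = np.linspace(t[0], t[-1], n)
    yu = np.interp(tu, t, y)
    dy = signal.savgol_filter(yu, window, polyorder, deriv=1,
                              delta=tu[1] - tu[0])
    guard = max(window // 2, 1)
    i = int(np.argmax(dy))
    if i < guard or i > n - 1 - guard:
        raise NoTransitionError(
            "derivative maximum at the edge of the temperature range; "
            "no melting transition detected"
        )
    # parabolic refinement around the grid maximum
    y0, y1, y2 = dy[i - 1], dy[i], dy[i + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(tu[i] + shift * (tu[1] - tu[0]))


# ---------------------------------------------------------------------------
# baselines and folded fraction
# ---------------------------------------------------------------------------

def fit_baselines(curve: MeltingCurve, low_frac: float = 0.15,
                  high_frac: float = 0.15,
                  windows: Optional[tuple] = None):
    """Fit linear folded / unfolded baselines and compute theta(T).

    By default the coolest and hottest 15 % of points define the folded
    and unfolded regions; ``windows`` may give explicit ((lo1, lo2),
    (hi1, hi2)) temperature bounds instead.

    Returns ``(BaselinePair, theta)`` with
    ``theta = (A_u - A) / (A_u - A_f)`` clipped to [0, 1].
    """
    t, a = curve.temperature, curve.absorbance
    if windows is not None:
        (lo1, lo2), (hi1, hi2) = windows
        lo = (t >= lo1) & (t <= lo2)
        hi = (t >= hi1) & (t <= hi2)
    else:
        n_lo = max(int(round(low_frac * t.size)), 3)
        n_hi = max(int(round(high_frac * t.size)), 3)
        lo = np.zeros(t.size, bool)
        hi = np.zeros(t.size, bool)
        lo[:n_lo] = True
        hi[-n_hi:] = True
    if lo.sum() < 2 or hi.sum() < 2:
        raise ValueError("baseline windows must contain at least 2 points")
    mf, bf = np.polyfit(t[lo], a[lo], 1)
    mu, bu = np.polyfit(t[hi], a[hi], 1)
    pair = BaselinePair(mf, bf, mu, bu)
    gap = pair.unfolded(t) - pair.folded(t)
    span = np.ptp(a)
    if span == 0 or np.max(np.abs(gap)) < 1e-3 * span:
        raise ValueError("degenerate baselines: folded and unfolded coincide")
    if np.any(gap <= 0):
        warnings.warn(
            "unfolded baseline dips below folded baseline inside the range; "
            "baseline windows may overlap the transition", stacklevel=2
        )
    theta = (pair.unfolded(t) - a) / gap
    return pair, np.clip(theta, 0.0, 1.0)


# ---------------------------------------------------------------------------
# single-curve van't Hoff fit (Model / Results)
# ---------------------------------------------------------------------------

class TwoStateMeltModel:
    """Nonlinear two-state fit of one melting curve.

    The model is ``A(T) = A_f(T) * theta + A_u(T) * (1 - theta)`` with
    linear baselines and theta from the molecularity-specific mass-action
    law.  Free parameters: dH, Tm, and the four baseline coefficients
    (dS is derived from dH and Tm through the closed-form Tm relation, a
    parameterisation that keeps the optimiser well conditioned).

    Examples
    --------
    >>> model = TwoStateMeltModel(curve)          # doctest: +SKIP
    >>> res = model.fit()                          # doctest: +SKIP
    >>> print(res.summary())                       # doctest: +SKIP
    """

    def __init__(self, curve: MeltingCurve,
                 molecularity: Optional[Molecularity] = None):
        self.curve = curve
        self.molecularity = molecularity or curve.molecularity
        if self.molecularity.bimolecular and not (curve.c_t > 0):
            raise ValueError("bimolecular fit requires curve.c_t > 0")

    # -- forward -----------------------------------------------------------
    def predict(self, params, t_c=None):
        dh, tm_k, mf, bf, mu, bu = params
        t_c = self.curve.temperature if t_c is None else np.asarray(t_c)
        ds = _ds_from_dh_tm(dh, tm_k, self.molecularity, self.curve.c_t)
        th = theta_two_state(celsius_to_kelvin(t_c), dh, ds,
                             self.molecularity, self.curve.c_t)
        return (mf * t_c + bf) * th + (mu * t_c + bu) * (1.0 - th)

    def _initial_guess(self):
        pair, _theta = fit_baselines(self.curve)
        try:
            tm0 = celsius_to_kelvin(tm_first_derivative(self.curve))
        except NoTransitionError:
            tm0 = celsius_to_kelvin(float(np.median(self.curve.temperature)))
        return np.array([-60.0, tm0, pair.folded_slope, pair.folded_intercept,
                         pair.unfolded_slope, pair.unfolded_intercept])

    def fit(self, start_params=None) -> "MeltResults":
        curve = self.curve
        p0 = np.asarray(start_params, float) if start_params is not None \
            else self._initial_guess()

        def resid(p):
            return self.predict(p) - curve.absorbance

        lo = [-400.0, celsius_to_kelvin(curve.temperature[0]) - 50.0,
              -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [-1.0, celsius_to_kelvin(curve.temperature[-1]) + 50.0,
              np.inf, np.inf, np.inf, np.inf]
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                     x_scale=[10.0, 5.0, 1e-3, 0.1, 1e-3, 0.1])
        if not sol.success:
            raise FitConvergenceError(
                f"melting fit did not converge: {sol.message}",
                last_params=sol.x,
            )
        return MeltResults(self, sol)


class MeltResults:
    """Estimates, uncertainties and diagnostics from a two-state melt fit."""

    def __init__(self, model: TwoStateMeltModel, sol):
        self.model = model
        curve = model.curve
        p = sol.x
        dof = max(curve.temperature.size - p.size, 1)
        rss = float(2.0 * sol.cost)
        self.scale = np.sqrt(rss / dof)
        # covariance from the Jacobian at the solution
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * self.scale ** 2
        except np.linalg.LinAlgError:
            cov = np.full((p.size, p.size), np.nan)
        self.cov_params = cov
        self.fittedvalues = model.predict(p)
        self.resid = curve.absorbance - self.fittedvalues

        dh, tm_k = p[0], p[1]
        ds = _ds_from_dh_tm(dh, tm_k, model.molecularity, curve.c_t)
        # delta-method propagation to dS and dG298
        g_ds = np.zeros(p.size)
        g_ds[0] = 1000.0 / tm_k
        g_ds[1] = -1000.0 * dh / tm_k ** 2
        ds_var = float(g_ds @ cov @ g_ds)
        g_dg = np.zeros(p.size)
        g_dg[0] = 1.0 - T_REF / 1000.0 * g_ds[0]   # d(dG)/d(dH)
        g_dg[1] = -T_REF / 1000.0 * g_ds[1]        # d(dG)/d(Tm) via dS
        dg_var = float(g_dg @ cov @ g_dg)

        self.baselines = BaselinePair(*p[2:])
        flags = ()
        if dh > -2.0:
            flags += ("boundary_dH",)
        self.params = ThermoParams(
            dh=float(dh), ds=float(ds), tm=float(kelvin_to_celsius(tm_k)),
            dg298=delta_g(float(dh), float(ds)),
            dh_err=float(np.sqrt(cov[0, 0])), ds_err=float(np.sqrt(ds_var)),
            tm_err=float(np.sqrt(cov[1, 1])), dg298_err=float(np.sqrt(dg_var)),
            error_kind="se", molecularity=model.molecularity,
            source="van_t_hoff", flags=flags,
        )

    @property
    def theta(self) -> np.ndarray:
        """Fitted folded fraction on the observed temperature grid."""
        p = self.params
        return theta_two_state(self.model.curve.temperature_k, p.dh, p.ds,
                               self.model.molecularity, self.model.curve.c_t)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Two-state van't Hoff melting fit",
            f"  molecularity : {p.molecularity.value}",
            f"  c_T          : {self.model.curve.c_t:.3g} M",
            f"  Tm           : {p.tm:8.2f} +/- {p.tm_err:.2f} degC",
            f"  dH           : {p.dh:8.1f} +/- {p.dh_err:.1f} kcal/mol",
            f"  dS           : {p.ds:8.1f} +/- {p.ds_err:.1f} cal/mol/K",
            f"  dG(298.15 K) : {p.dg298:8.2f} +/- {p.dg298_err:.2f} kcal/mol",
            f"  residual sd  : {self.scale:.2e} AU",
        ]
        if p.flags:
            lines.append(f"  flags        : {', '.join(p.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Data, fit and baselines on one axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        t = self.model.curve.temperature
        ax.plot(t, self.model.curve.absorbance, ".", ms=3, label="data")
        ax.plot(t, self.fittedvalues, "-", label="two-state fit")
        ax.plot(t, self.baselines.folded(t), "--", lw=0.8, label="folded")
        ax.plot(t, self.baselines.unfolded(t), "--", lw=0.8, label="unfolded")
        ax.set_xlabel("temperature (degC)")
        ax.set_ylabel("absorbance (AU)")
        ax.legend()
        return ax


def van_t_hoff_fit(curve: MeltingCurve,
                   molecularity: Optional[Molecularity] = None) -> ThermoParams:
    """Convenience wrapper: fit one curve, return :class:`ThermoParams`."""
    return TwoStateMeltModel(curve, molecularity).fit().params


# ---------------------------------------------------------------------------
# Tm versus concentration (Model / Results)
# ---------------------------------------------------------------------------

class TmConcentrationModel:
    """Concentration dependence of the duplex melting temperature.

    For bimolecular transitions 1/Tm is linear in ln(c_T)
    (self-complementary) or ln(c_T/4) (non-self-complementary), with
    slope R / (1000 dH) and intercept dS / (1000 dH).

    Parameters
    ----------
    tm_k : sequence of float
        Melting temperatures in Kelvin.
    c_t : sequence of float
        Total strand concentrations, mol/L.
    molecularity : Molecularity
        Must be bimolecular; a hairpin Tm carries no concentration
        information.
    weights : sequence, optional
        Regression weights for 1/Tm (e.g. inverse variances).
    """

    def __init__(self, tm_k: Sequence[float], c_t: Sequence[float],
                 molecularity: Molecularity, weights=None):
        self.tm_k = np.asarray(tm_k, float)
        self.c_t = np.asarray(c_t, float)
        if molecularity is Molecularity.UNIMOLECULAR_HAIRPIN:
            raise ValueError(
                "Tm is concentration-independent for a unimolecular hairpin"
            )
        self.molecularity = molecularity
        self.weights = None if weights is None else np.asarray(weights, float)
        if self.tm_k.size != self.c_t.size:
            raise ValueError("tm and c_t lengths differ")
        if self.tm_k.size < 3:
            raise ValueError("need at least 3 (Tm, c_T) points")
        if np.any(self.c_t <= 0):
            raise ValueError("concentrations must be positive")

    def fit(self) -> "TmConcentrationResults":
        if self.molecularity is Molecularity.BIMOLECULAR_SELF_COMPLEMENTARY:
            x = np.log(self.c_t)
        else:
            x = np.log(self.c_t / 4.0)
        y = 1.0 / self.tm_k
        if np.ptp(x) == 0:
            raise ValueError("rank-deficient regression: all concentrations equal")
        w = self.weights
        coef, cov = np.polyfit(x, y, 1, w=None if w is None else np.sqrt(w),
                               cov="unscaled" if self.tm_k.size == 3 else True)
        return TmConcentrationResults(self, x, y, coef, cov)


class TmConcentrationResults:
    """dH and dS from the 1/Tm-versus-ln(c) regression, with SEs."""

    def __init__(self, model: TmConcentrationModel, x, y, coef, cov):
        self.model = model
        self.x, self.y = x, y
        slope, intercept = coef
        self.slope, self.intercept = float(slope), float(intercept)
        self.cov_coef = cov
        flags = ()
        if slope >= 0:
            flags += ("non_two_state_positive_slope",)
            warnings.warn(
                "non-negative slope in 1/Tm vs ln(c): implies dH >= 0, "
                "inconsistent with two-state duplex melting", stacklevel=2
            )
        dh = R_CAL / (1000.0 * slope)
        ds = 1000.0 * dh * intercept            # = R * intercept / slope
        # delta method on (slope, intercept)
        g_dh = np.array([-R_CAL / (1000.0 * slope ** 2), 0.0])
        g_ds = np.array([-R_CAL * intercept / slope ** 2, R_CAL / slope])
        dh_var = float(g_dh @ cov @ g_dh)
        ds_var = float(g_ds @ cov @ g_ds)
        g_dg = g_dh - T_REF / 1000.0 * g_ds
        dg_var = float(g_dg @ cov @ g_dg)
        tm_ref = kelvin_to_celsius(
            tm_from_params(dh, ds, model.molecularity, np.max(model.c_t))
        )
        self.params = ThermoParams(
            dh=dh, ds=ds, tm=float(tm_ref), dg298=delta_g(dh, ds),
            dh_err=float(np.sqrt(dh_var)), ds_err=float(np.sqrt(ds_var)),
            dg298_err=float(np.sqrt(dg_var)), error_kind="se",
            molecularity=model.molecularity, source="tm_concentration",
            n=model.tm_k.size, flags=flags,
        )

    @property
    def fittedvalues(self):
        return self.slope * self.x + self.intercept

    @property
    def resid(self):
        return self.y - self.fittedvalues

    def summary(self) -> str:
        p = self.params
        return "\n".join([
            "1/Tm versus ln(concentration) regression",
            f"  molecularity : {p.molecularity.value}",
            f"  n points     : {p.n}",
            f"  slope        : {self.slope:.4e} 1/K",
            f"  dH           : {p.dh:8.1f} +/- {p.dh_err:.1f} kcal/mol",
            f"  dS           : {p.ds:8.1f} +/- {p.ds_err:.1f} cal/mol/K",
            f"  dG(298.15 K) : {p.dg298:8.2f} +/- {p.dg298_err:.2f} kcal/mol",
        ])


def tm_concentration_fit(points, molecularity: Molecularity,
                         weights=None) -> ThermoParams:
    """Fit from ``[(Tm_K, c_T), ...]`` pairs; see :class:`TmConcentrationModel`."""
    tm_k, c_t = zip(*points)
    return TmConcentrationModel(tm_k, c_t, molecularity, weights).fit().params


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def delta_g(dh, ds=None, t: float = T_REF) -> float:
    """Gibbs energy dG = dH - T dS / 1000 in kcal/mol.

    Accepts either ``delta_g(params)`` with a :class:`ThermoParams`, or
    ``delta_g(dh, ds)`` with dH in kcal/mol and dS in cal mol^-1 K^-1.
    ``t`` is in Kelvin (default 298.15).
    """
    if isinstance(dh, ThermoParams):
        params = dh
        return params.dh - t * params.ds / 1000.0
    if ds is None:
        raise TypeError("delta_g requires ThermoParams or (dh, ds)")
    return dh - t * ds / 1000.0


def compare_to_reference(mod: ThermoParams, ref: ThermoParams):
    """(dTm, ddG298) of a modified construct relative to its reference."""
    return mod.tm - ref.tm, mod.dg298 - ref.dg298


def aggregate_replicates(fits: Sequence[ThermoParams],
                         ci: str = "t-sem") -> ThermoParams:
    """Aggregate replicate fits to mean and 95 % confidence half-widths.

    ``ci="t-sem"`` (default) gives the standard t-interval of the mean,
    t(0.975, n-1) * sd / sqrt(n); ``ci="t-sd"`` scales the replicate sd
    itself by the t-multiplier; ``ci="sd"`` reports the plain sd.
    A single fit is returned unchanged with a warning (no CI possible).
    """
    fits = list(fits)
    if len(fits) == 0:
        raise ValueError("no fits to aggregate")
    if len(fits) == 1:
        warnings.warn("single replicate: no confidence interval", stacklevel=2)
        return replace(fits[0], source=fits[0].source + "+aggregate", n=1)
    n = len(fits)
    tmult = stats.t.ppf(0.975, n - 1)

    def agg(values):
        values = np.asarray(values, float)
        sd = values.std(ddof=1)
        if ci == "t-sem":
            half = tmult * sd / np.sqrt(n)
        elif ci == "t-sd":
            half = tmult * sd
        elif ci == "sd":
            half = sd
        else:
            raise ValueError(f"unknown ci rule {ci!r}")
        return float(values.mean()), float(half)

    dh, dh_e = agg([f.dh for f in fits])
    ds, ds_e = agg([f.ds for f in fits])
    tm, tm_e = agg([f.tm for f in fits])
    dg, dg_e = agg([f.dg298 for f in fits])
    return ThermoParams(
        dh=dh, ds=ds, tm=tm, dg298=dg,
        dh_err=dh_e, ds_err=ds_e, tm_err=tm_e, dg298_err=dg_e,
        error_kind="ci95" if ci.startswith("t") else "sd",
        molecularity=fits[0].molecularity, source="aggregate", n=n,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_melting_csv(path, molecularity: Molecularity,
                     wavelength_nm: float = 260.0) -> list:
    """Read melting curves from CSV.

    Accepts either one curve per file (columns ``temperature_C,
    absorbance``) or long format with additional ``replicate`` and
    ``concentration_M`` columns, one curve per (replicate,
    concentration) group.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"temperature_C", "absorbance"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: CSV must contain columns {sorted(required)}")
    group_cols = [c for c in ("replicate", "concentration_M") if c in df.columns]
    curves = []
    groups = df.groupby(group_cols, sort=False) if group_cols else [((), df)]
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(group_cols, key))
        sub = sub.sort_values("temperature_C")
        curves.append(MeltingCurve(
            temperature=sub["temperature_C"].to_numpy(),
            absorbance=sub["absorbance"].to_numpy(),
            c_t=float(meta.get("concentration_M", np.nan)),
            molecularity=molecularity,
            wavelength_nm=float(sub["wavelength_nm"].iloc[0])
            if "wavelength_nm" in sub.columns else wavelength_nm,
            replicate_id=str(meta.get("replicate", "")),
        ))
    return curves
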