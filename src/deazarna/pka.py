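"""Nucleobase pKa from NMR pH titrations, and base-pair pKa-gap analysis.

Protonation state shifts the 13C resonances of a nucleobase, so the
observed chemical shift along a pH series follows the single-site
Henderson-Hasselbalch form

    delta_obs(pH) = (delta_deprot * 10^(pH - pKa) + delta_prot)
                    / (1 + 10^(pH - pKa))

Fitting delta_obs against pH yields the pKa and the two end-point
shifts.  The module also carries a reference table of nucleobase pKa
values (Watson-Crick donor and acceptor sites of A, C, G, U and the
3-/7-deazapurine analogues) and computes the donor-acceptor pKa gap of
each base pair: gaps near 5.4-5.5, as in the natural A-U and G-C pairs,
mark efficient pairing; deazapurines shift the acceptor (3-deaza) or
donor (7-deaza) pKa and thereby the gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "PKA_VALUES",
    "BASE_PAIR_SITES",
    "TitrationSeries",
    "PkaFit",
    "BasePairGap",
    "TitrationModel",
    "TitrationResults",
    "titration_model",
    "fit_titration",
    "delta_pka_gap",
    "protonated_fraction",
    "base_pair_gaps",
    "read_titration_csv",
]

#: Reference pKa values of the Watson-Crick-relevant ionisation sites.
#: Keys: residue token -> (site label, pKa).  Protonated species are the
#: acceptor-side purine/cytosine cations (A.H+ etc.).
PKA_VALUES: Dict[str, tuple] = {
    "A": ("N1 (A.H+)", 3.7),
    "c3A": ("N1 (c3A.H+)", 6.8),
    "c7A": ("N1 (c7A.H+)", 5.3),
    "U": ("N3-H", 9.2),
    "G": ("N1-H", 9.5),
    "c3G": ("N1-H", 12.3),
    "c7G": ("N1-H", 10.3),
    "C": ("N3 (C.H+)", 4.1),
}

#: Watson-Crick pairs analysed: (donor residue, acceptor residue).
#: For A-type pairs the donor is the pyrimidine imino N3-H of U; for
#: G-type pairs the donor is the purine imino N1-H, the acceptor C N3.
BASE_PAIR_SITES = (
    ("U", "A"),
    ("U", "c7A"),
    ("U", "c3A"),
    ("G", "C"),
    ("c7G", "C"),
    ("c3G", "C"),
)


@dataclass
class TitrationSeries:
    """pH versus chemical shift for one reporter nucleus."""

    pH: np.ndarray
    shift: np.ndarray
    nucleus: str = ""

    def __post_init__(self):
        self.pH = np.asarray(self.pH, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if self.pH.shape != self.shift.shape:
            raise ValueError("pH and shift lengths differ")
        if self.pH.size < 5:
            raise ValueError("need at least 5 titration points")
        if np.any((self.pH < 0) | (self.pH > 14)):
            raise ValueError("pH values must lie in [0, 14]")


@dataclass
class PkaFit:
    """Fitted single-site titration parameters."""

    pKa: float
    delta_prot: float
    delta_deprot: float
    pKa_err: float = np.nan
    delta_prot_err: float = np.nan
    delta_deprot_err: float = np.nan
    nucleus: str = ""
    extrapolated: bool = False

    def as_dict(self) -> dict:
        return {
            "nucleus": self.nucleus,
            "pKa": self.pKa, "pKa_err": self.pKa_err,
            "delta_prot_ppm": self.delta_prot,
            "delta_prot_err": self.delta_prot_err,
            "delta_deprot_ppm": self.delta_deprot,
            "delta_deprot_err": self.delta_deprot_err,
            "extrapolated": self.extrapolated,
        }


@dataclass(frozen=True)
class BasePairGap:
    """Donor-acceptor pKa gap of one Watson-Crick pair."""

    donor: str
    donor_site: str
    acceptor: str
    acceptor_site: str
    pKa_donor: float
    pKa_acceptor: float

    @property
    def gap(self) -> float:
        return self.pKa_donor - self.pKa_acceptor

    @property
    def label(self) -> str:
        return f"{self.acceptor}-{self.donor}" if self.donor == "U" \
            else f"{self.donor}-{self.acceptor}"


# ---------------------------------------------------------------------------
# model and fit
# ---------------------------------------------------------------------------

def titration_model(pH, pKa, delta_prot, delta_deprot):
    """Single-site fast-exchange titration curve, shifts in ppm."""
    pH = np.asarray(pH, dtype=float)
    x = np.power(10.0, np.clip(pH - pKa, -300, 300))
    return (delta_deprot * x + delta_prot) / (1.0 + x)


class TitrationModel:
    """Least-squares fit of a single-site titration curve.

    Multi-site (biphasic) data are rejected: if the residuals of the
    best single-site fit retain strong systematic structure the fit
    still returns, but an unidentifiable (flat) series raises.
    """

    def __init__(self, series: TitrationSeries):
        self.series = series

    def predict(self, params, pH=None):
        pH = self.series.pH if pH is None else pH
        return titration_model(pH, *params)

    def _initial_guess(self):
        s = self.series
        order = np.argsort(s.pH)
        d_lo = float(np.mean(s.shift[order[:2]]))
        d_hi = float(np.mean(s.shift[order[-2:]]))
        mid = 0.5 * (d_lo + d_hi)
        pka0 = float(np.interp(mid, s.shift[order][::-1] if d_lo > d_hi
                               else s.shift[order],
                               s.pH[order][::-1] if d_lo > d_hi
                               else s.pH[order]))
        if not np.isfinite(pka0):
            pka0 = float(np.median(s.pH))
        return np.array([pka0, d_lo, d_hi])

    def fit(self, start_params=None) -> "TitrationResults":
        s = self.series
        if np.ptp(s.shift) < 1e-6:
            raise RuntimeError(
                "flat titration series: end-point shifts coincide, "
                "pKa is unidentifiable"
            )
        p0 = np.asarray(start_params, float) if start_params is not None \
            else self._initial_guess()
        sol = optimize.least_squares(
            lambda p: self.predict(p) - s.shift, p0,
            bounds=([-2.0, -np.inf, -np.inf], [16.0, np.inf, np.inf]),
        )
        if not sol.success:
            raise RuntimeError(f"titration fit did not converge: {sol.message}")
        return TitrationResults(self, sol)


class TitrationResults:
    """pKa fit with covariance-derived standard errors."""

    def __init__(self, model: TitrationModel, sol):
        self.model = model
        self.sol = sol
        s = model.series
        self.fittedvalues = model.predict(sol.x)
        self.resid = s.shift - self.fittedvalues
        dof = max(s.pH.size - 3, 1)
        self.scale = float(np.sqrt(np.sum(self.resid ** 2) / dof))
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * self.scale ** 2
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
            se = np.full(3, np.nan)
        self.cov_params = cov
        pka = float(sol.x[0])
        extrapolated = not (s.pH.min() - 1.0 <= pka <= s.pH.max() + 1.0)
        if extrapolated:
            warnings.warn(
                f"fitted pKa {pka:.2f} lies outside the sampled pH range "
                f"[{s.pH.min():.1f}, {s.pH.max():.1f}] +/- 1; extrapolated",
                stacklevel=3,
            )
        self.fit = PkaFit(
            pKa=pka, delta_prot=float(sol.x[1]), delta_deprot=float(sol.x[2]),
            pKa_err=float(se[0]), delta_prot_err=float(se[1]),
            delta_deprot_err=float(se[2]), nucleus=s.nucleus,
            extrapolated=extrapolated,
        )

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Single-site pH titration fit",
            f"  nucleus       : {f.nucleus or '(unlabelled)'}",
            f"  pKa           : {f.pKa:7.2f} +/- {f.pKa_err:.2f}"
            + ("   [extrapolated]" if f.extrapolated else ""),
            f"  delta(prot)   : {f.delta_prot:8.3f} +/- {f.delta_prot_err:.3f} ppm",
            f"  delta(deprot) : {f.delta_deprot:8.3f} +/- {f.delta_deprot_err:.3f} ppm",
            f"  residual sd   : {self.scale:.3f} ppm",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        s = self.model.series
        ax.plot(s.pH, s.shift, "o", label="data")
        grid = np.linspace(s.pH.min(), s.pH.max(), 200)
        ax.plot(grid, self.model.predict(self.sol.x, grid), "-", label="fit")
        ax.axvline(self.fit.pKa, ls="--", lw=0.8)
        ax.set_xlabel("pH")
        ax.set_ylabel("chemical shift (ppm)")
        ax.legend()
        return ax


def fit_titration(series: TitrationSeries) -> PkaFit:
    """Fit one titration series; see :class:`TitrationModel`."""
    return TitrationModel(series).fit().fit


def fit_titration_joint(series_list: Sequence[TitrationSeries]):
    """Joint fit of several nuclei sharing one pKa.

    Each series keeps its own end-point shifts; the pKa is common.
    Returns ``(pKa, pKa_err, [PkaFit, ...])``.
    """
    series_list = list(series_list)
    if len(series_list) < 1:
        raise ValueError("need at least one series")
    singles = [TitrationModel(s).fit() for s in series_list]
    p0 = [float(np.mean([r.fit.pKa for r in singles]))]
    for r in singles:
        p0 += [r.fit.delta_prot, r.fit.delta_deprot]

    def resid(p):
        pka = p[0]
        out = []
        for i, s in enumerate(series_list):
            dp, dd = p[1 + 2 * i], p[2 + 2 * i]
            out.append(titration_model(s.pH, pka, dp, dd) - s.shift)
        return np.concatenate(out)

    sol = optimize.least_squares(resid, p0)
    if not sol.success:
        raise RuntimeError(f"joint titration fit failed: {sol.message}")
    n_obs = sum(s.pH.size for s in series_list)
    dof = max(n_obs - len(p0), 1)
    scale2 = np.sum(sol.fun ** 2) / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * scale2
        pka_err = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        pka_err = np.nan
    fits = []
    for i, s in enumerate(series_list):
        fits.append(PkaFit(
            pKa=float(sol.x[0]), delta_prot=float(sol.x[1 + 2 * i]),
            delta_deprot=float(sol.x[2 + 2 * i]), pKa_err=pka_err,
            nucleus=s.nucleus,
        ))
    return float(sol.x[0]), pka_err, fits


# ---------------------------------------------------------------------------
# gap analysis
# ---------------------------------------------------------------------------

def delta_pka_gap(donor_pKa: float, acceptor_pKa: float) -> float:
    """pKa gap = pKa(H-bond donor site) - pKa(H-bond acceptor site)."""
    return donor_pKa - acceptor_pKa


def protonated_fraction(pKa: float, pH) -> float:
    """Fraction of the protonated species at the given pH, 1/(1+10^(pH-pKa))."""
    pH = np.asarray(pH, dtype=float)
    frac = 1.0 / (1.0 + np.power(10.0, np.clip(pH - pKa, -300, 300)))
    return float(frac) if frac.ndim == 0 else frac


def base_pair_gaps(pka_table: Optional[Dict[str, tuple]] = None) -> list:
    """Donor-acceptor pKa gaps for the six Watson-Crick pairs analysed.

    Uses the built-in reference table unless an override mapping
    ``token -> (site, pKa)`` is supplied.
    """
    table = pka_table or PKA_VALUES
    gaps = []
    for donor, acceptor in BASE_PAIR_SITES:
        dsite, dpka = table[donor]
        asite, apka = table[acceptor]
        gaps.append(BasePairGap(donor, dsite, acceptor, asite, dpka, apka))
    return gaps


def read_titration_csv(path) -> list:
    """Read titration series from CSV with columns pH, shift_ppm[, nucleus]."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"pH", "shift_ppm"}.issubset(df.columns):
        raise ValueError(f"{path}: CSV must contain columns pH, shift_ppm")
    out = []
    groups = df.groupby("nucleus", sort=False) if "nucleus" in df.columns \
        else [("", df)]
    for nucleus, sub in groups:
        out.append(TitrationSeries(sub["pH"].to_numpy(),
                                   sub["shift_ppm"].to_numpy(),
                                   nucleus=str(nucleus)))
    return out
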