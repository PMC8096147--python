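"""Synthetic raw data for every stage of the pipeline.

Each generator is the exact forward model of the corresponding fitting
module — melting curves from the two-state mass-action law with linear
baselines, CLEANEX build-ups from the two-site transfer equation,
titration curves from the single-site Henderson-Hasselbalch form, and
idealized planar base pairs with waters at requested distances.  At
zero noise, fit(generate(truth)) therefore recovers the truth to solver
tolerance, which is the package's central self-consistency check.

Noise is Gaussian and seeded: identical seeds give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cleanex import DEFAULT_MIXING_SCHEDULE, CleanexSeries, \
    SaturationRecoverySeries, buildup_model
from .melt import BaselinePair, MeltingCurve, theta_two_state
from .pka import TitrationSeries, titration_model
from .seqmod import Molecularity
from .structure import Atom, StructureModel
from .constants import celsius_to_kelvin

__all__ = [
    "NoiseSpec",
    "MeltScenario",
    "DEFAULT_BASELINES",
    "DEFAULT_CONCENTRATIONS",
    "gen_melting_curves",
    "gen_cleanex_series",
    "gen_saturation_recovery",
    "gen_titration",
    "gen_toy_base_pair",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian observation noise: sigma in the observable's units."""

    sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: Typical RNA UV-melt baselines: gentle positive drift on both sides,
#: 20 % hyperchromicity on melting (folded 1.00 AU, unfolded 1.20 AU at
#: 0 degC on a normalised scale).
DEFAULT_BASELINES = BaselinePair(
    folded_slope=0.0003, folded_intercept=1.00,
    unfolded_slope=0.0005, unfolded_intercept=1.20,
)

#: Five strand concentrations log-spaced over 1-100 uM.
DEFAULT_CONCENTRATIONS = tuple(np.geomspace(1e-6, 1e-4, 5))


@dataclass
class MeltScenario:
    """Ground truth for a family of simulated melting curves.

    dh (kcal/mol) and ds (cal/mol/K) are the generator truth; one curve
    is produced per concentration on the shared temperature grid.
    """

    dh: float
    ds: float
    molecularity: Molecularity
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS
    baselines: BaselinePair = field(
        default_factory=lambda: DEFAULT_BASELINES)
    t_start: float = 20.0
    t_stop: float = 90.0
    t_step: float = 0.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def grid(self) -> np.ndarray:
        n = int(round((self.t_stop - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)


def gen_melting_curves(scenario: MeltScenario) -> List[MeltingCurve]:
    """Simulate one melting curve per concentration in the scenario."""
    t_c = scenario.grid()
    t_k = celsius_to_kelvin(t_c)
    rng = scenario.noise.rng()
    curves = []
    for c_t in scenario.concentrations:
        theta = theta_two_state(t_k, scenario.dh, scenario.ds,
                                scenario.molecularity, c_t)
        a = scenario.baselines.folded(t_c) * theta \
            + scenario.baselines.unfolded(t_c) * (1.0 - theta)
        if scenario.noise.sigma > 0:
            a = a + rng.normal(0.0, scenario.noise.sigma, size=a.size)
        curves.append(MeltingCurve(
            temperature=t_c, absorbance=a, c_t=float(c_t),
            molecularity=scenario.molecularity,
            replicate_id=f"sim_c{c_t:.3g}",
        ))
    return curves


def gen_cleanex_series(k: float, r1a: float, r1_water: float,
                       schedule: Sequence[float] = DEFAULT_MIXING_SCHEDULE,
                       noise: NoiseSpec = NoiseSpec(),
                       residue_label: str = "sim") -> CleanexSeries:
    """Simulate a CLEANEX build-up on the given mixing-time schedule.

    Duplicated mixing times in the schedule are produced as listed and
    receive independent noise draws, exactly as repeat measurements do.
    """
    tau = np.asarray(schedule, dtype=float)
    y = buildup_model(tau, k, r1a, r1_water)
    if noise.sigma > 0:
        y = y + noise.rng().normal(0.0, noise.sigma, size=tau.size)
    return CleanexSeries(tau, y, residue_label=residue_label,
                         r1_water=r1_water)


def gen_saturation_recovery(t1: float, m0: float = 1.0,
                            delays: Optional[Sequence[float]] = None,
                            noise: NoiseSpec = NoiseSpec()
                            ) -> SaturationRecoverySeries:
    """Simulate water saturation recovery M(t) = M0 (1 - exp(-t/T1))."""
    if delays is None:
        delays = np.linspace(0.1, 4.0 * t1, 10)
    delays = np.asarray(delays, dtype=float)
    y = m0 * (1.0 - np.exp(-delays / t1))
    if noise.sigma > 0:
        y = y + noise.rng().normal(0.0, noise.sigma, size=delays.size)
    return SaturationRecoverySeries(delays, y)


def gen_titration(pka: float, delta_prot: float, delta_deprot: float,
                  ph_grid: Sequence[float],
                  noise: NoiseSpec = NoiseSpec(),
                  nucleus: str = "sim") -> TitrationSeries:
    """Simulate a pH titration curve on the given pH grid."""
    ph = np.asarray(ph_grid, dtype=float)
    if np.ptp(ph) < 2.0:
        raise ValueError("pH grid must span at least 2 pH units")
    y = titration_model(ph, pka, delta_prot, delta_deprot)
    if noise.sigma > 0:
        y = y + noise.rng().normal(0.0, noise.sigma, size=ph.size)
    return TitrationSeries(ph, y, nucleus=nucleus)


# ---------------------------------------------------------------------------
# toy base pairs (synthetic stand-ins for crystallographic fixtures)
# ---------------------------------------------------------------------------

# Idealized planar Watson-Crick pair in the z = 0 plane, bond lengths
# ~1.4 A, N1...N3 hydrogen bond 2.82 A.  Only the atoms the hydration
# analysis touches need faithful names; the rest sketch the rings.
# The minor-groove face is the -y side (N3/C3, O2, both O2').
_PURINE_TEMPLATE = {
    "N1": (1.390, 0.000), "C2": (0.695, -1.204), "N3": (-0.695, -1.204),
    "C4": (-1.390, 0.000), "C5": (-0.695, 1.204), "C6": (0.695, 1.204),
    "N7": (-1.500, 2.250), "C8": (-2.800, 1.950), "N9": (-3.050, 0.600),
    "C1'": (-4.250, -0.100), "O2'": (-4.700, -1.550),
}
_PYRIMIDINE_TEMPLATE = {
    "N3": (4.210, 0.000), "C2": (4.905, -1.204), "N1": (6.295, -1.204),
    "C6": (6.990, 0.000), "C5": (6.295, 1.204), "C4": (4.905, 1.204),
    "O2": (4.280, -2.330), "C1'": (7.000, -2.420), "O2'": (7.550, -3.700),
}
_EXOCYCLIC = {
    "AU": {"purine": {"N6": (1.390, 2.408)}, "pyrimidine": {"O4": (4.280, 2.330)}},
    "GC": {"purine": {"O6": (1.390, 2.408), "N2": (0.695, -2.600)},
           "pyrimidine": {"N4": (4.280, 2.330)}},
}
_ELEMENT_FROM_NAME = {"N": "N", "C": "C", "O": "O"}


def gen_toy_base_pair(preset: str = "AU",
                      water_placements: Sequence[Tuple[str, float, Sequence[float]]] = (),
                      deaza3: bool = False,
                      residue_numbers: Tuple[int, int] = (1, 2),
                      chain: str = "A") -> StructureModel:
    """Synthetic idealized planar base pair with optional placed waters.

    This is a constructed stand-in fixture, not crystallographic data:
    an AU or GC pair drawn flat in the z = 0 plane with field-standard
    atom names.  ``deaza3=True`` replaces the purine N3 by a carbon
    named C3 (the 3-deazapurine substitution).  Each water placement is
    ``(anchor, distance_A, direction_xyz)`` with ``anchor`` like
    ``"1:N3"`` (residue_index:atom_name, 1 = purine, 2 = pyrimidine);
    the water oxygen is put exactly ``distance`` along the normalised
    direction from the anchor.  Placements closer than 1.5 A to any
    existing atom raise.
    """
    preset = preset.upper()
    if preset not in ("AU", "GC"):
        raise ValueError("preset must be 'AU' or 'GC'")
    pur_num, pyr_num = residue_numbers
    pur_name = preset[0]
    pyr_name = preset[1]
    atoms: List[Atom] = []

    def add(name, xy, resname, resnum, z=0.0):
        atoms.append(Atom(
            element=_ELEMENT_FROM_NAME[name[0]], name=name,
            residue_name=resname, residue_number=resnum, chain=chain,
            xyz=(float(xy[0]), float(xy[1]), float(z)),
        ))

    pur_resname = f"C3{pur_name}" if deaza3 else pur_name
    for name, xy in _PURINE_TEMPLATE.items():
        if deaza3 and name == "N3":
            name = "C3"
        add(name, xy, pur_resname, pur_num)
    for name, xy in _EXOCYCLIC[preset]["purine"].items():
        add(name, xy, pur_resname, pur_num)
    for name, xy in _PYRIMIDINE_TEMPLATE.items():
        add(name, xy, pyr_name, pyr_num)
    for name, xy in _EXOCYCLIC[preset]["pyrimidine"].items():
        add(name, xy, pyr_name, pyr_num)

    by_anchor = {}
    for a in atoms:
        idx = 1 if a.residue_number == pur_num else 2
        by_anchor[f"{idx}:{a.name}"] = a
    solute_xyz = np.array([a.xyz for a in atoms])

    for i, (anchor, dist, direction) in enumerate(water_placements, start=1):
        if anchor not in by_anchor:
            raise KeyError(f"unknown water anchor {anchor!r}")
        d = np.asarray(direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("water direction must be non-zero")
        pos = np.asarray(by_anchor[anchor].xyz) + dist * d / norm
        gaps = np.linalg.norm(solute_xyz - pos, axis=1)
        if np.min(gaps) < 1.5:
            raise ValueError(
                f"water {i} at {pos.round(2)} clashes with a solute atom "
                f"({np.min(gaps):.2f} A)"
            )
        atoms.append(Atom(
            element="O", name="O", residue_name="HOH",
            residue_number=100 + i, chain="S", xyz=tuple(pos),
            is_water=True,
        ))
        solute_xyz = np.vstack([solute_xyz, pos])

    return StructureModel(atoms, source_id=f"synthetic_{preset}"
                          + ("_c3" if deaza3 else ""))
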