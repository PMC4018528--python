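"""Mass-action kinetic model of cap-dependent translation initiation.

The model tracks three translation factors — the cap-binding protein eIF4E,
its inhibitor 4E-BP and the scaffold eIF4G — together with the two mutually
exclusive complexes eIF4E:4E-BP and eIF4E:eIF4G, plus an accumulated-protein
read-out proportional to the active initiation complex:

    R1  eIF4E + 4E-BP  <->  eIF4E:4E-BP     (k_on1 / k_off1,  KD1 = k_off1/k_on1)
    R2  eIF4E + eIF4G  <->  eIF4E:eIF4G     (k_on2 / k_off2,  KD2 = k_off2/k_on2)
    R3  eIF4E:eIF4G    -->  Protein + eIF4E:eIF4G   (k_cat_protein)
    R4  eIF4E:eIF4G    -->  4E-BP + eIF4E:eIF4G     (k_cat_4ebp)
    R5  4E-BP          -->  0                        (k_lys_4ebp)

Internal units are micromolar and seconds; second-order rate constants given
in M^-1 s^-1 must be converted at the boundary (1 M^-1 s^-1 = 1e-6 uM^-1 s^-1).
Perturbations (fertilization, rapamycin) are expressed as per-parameter fold
changes applied as a linear ramp in time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateParameters",
    "Totals",
    "SpeciesState",
    "ParameterRamp",
    "TimeCourse",
    "Trajectory",
    "IntegrationError",
    "UNFERTILIZED_RATES",
    "TABLE1_TOTALS",
    "SPECIES",
    "rhs",
    "params_at_time",
    "simulate",
]

#: order of the state vector used throughout the package
SPECIES = (
    "eif4e_free",
    "fourebp_free",
    "eif4g_free",
    "complex_eb",
    "complex_eg",
    "protein",
)

MOLAR_TO_UM = 1e-6  # 1 M^-1 s^-1 expressed in uM^-1 s^-1


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces unphysical output."""


@dataclass(frozen=True)
class RateParameters:
    """The seven kinetic constants of the model.

    Second-order rates (``k_on1``, ``k_on2``) are in uM^-1 s^-1, all
    first-order rates in s^-1.  ``k_cat_protein`` sets the scale of the
    arbitrary-unit protein output and is otherwise unconstrained.
    """

    k_on1: float
    k_off1: float
    k_on2: float
    k_off2: float
    k_cat_4ebp: float
    k_lys_4ebp: float
    k_cat_protein: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    @property
    def kd1(self) -> float:
        """Dissociation constant of eIF4E:4E-BP in uM."""
        return self.k_off1 / self.k_on1

    @property
    def kd2(self) -> float:
        """Dissociation constant of eIF4E:eIF4G in uM."""
        return self.k_off2 / self.k_on2

    def replace(self, **kwargs: float) -> "RateParameters":
        return dataclasses.replace(self, **kwargs)

    def scaled(self, fold_changes: Mapping[str, float]) -> "RateParameters":
        """Return a copy with the named parameters multiplied by fold factors."""
        unknown = set(fold_changes) - set(self.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return self.replace(
            **{k: getattr(self, k) * f for k, f in fold_changes.items()}
        )

    @classmethod
    def from_molar(
        cls,
        k_on1_per_M_s: float,
        k_off1: float,
        k_on2_per_M_s: float,
        k_off2: float,
        k_cat_4ebp: float,
        k_lys_4ebp: float,
        k_cat_protein: float = 1.0,
    ) -> "RateParameters":
        """Build parameters with association rates given in M^-1 s^-1."""
        return cls(
            k_on1=k_on1_per_M_s * MOLAR_TO_UM,
            k_off1=k_off1,
            k_on2=k_on2_per_M_s * MOLAR_TO_UM,
            k_off2=k_off2,
            k_cat_4ebp=k_cat_4ebp,
            k_lys_4ebp=k_lys_4ebp,
            k_cat_protein=k_cat_protein,
        )


@dataclass(frozen=True)
class Totals:
    """Total concentration pools in uM."""

    total_4ebp: float
    total_eif4e: float
    total_eif4g: float

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"total {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations of the five molecular species (uM) plus protein (AU)."""

    eif4e_free: float
    fourebp_free: float
    eif4g_free: float
    complex_eb: float
    complex_eg: float
    protein: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "SpeciesState":
        return cls(*map(float, y))

    @property
    def total_4ebp(self) -> float:
        return self.fourebp_free + self.complex_eb

    @property
    def total_eif4e(self) -> float:
        return self.eif4e_free + self.complex_eb + self.complex_eg

    @property
    def total_eif4g(self) -> float:
        return self.eif4g_free + self.complex_eg


@dataclass(frozen=True)
class ParameterRamp:
    """A linear transition of selected rate constants.

    Each parameter named in ``fold_changes`` moves linearly (in value, not in
    log) from its initial value to initial*fold between ``t_start`` and
    ``t_start + duration`` (seconds); outside the window it is clamped.
    """

    initial: RateParameters
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    t_start: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("ramp duration must be >= 0")
        for k, f in self.fold_changes.items():
            if not (f > 0):
                raise ValueError(f"fold factor for {k} must be > 0, got {f}")
        # validate names eagerly
        self.initial.scaled(self.fold_changes)

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    @property
    def final(self) -> RateParameters:
        return self.initial.scaled(self.fold_changes)


def params_at_time(ramp: ParameterRamp, t: float) -> RateParameters:
    """Rate constants in effect at time ``t`` (seconds) under a linear ramp."""
    if t <= ramp.t_start or not ramp.fold_changes:
        return ramp.initial
    if ramp.duration == 0 or t >= ramp.t_end:
        return ramp.final
    frac = (t - ramp.t_start) / ramp.duration
    return ramp.initial.replace(
        **{
            k: getattr(ramp.initial, k) * (1.0 + (f - 1.0) * frac)
            for k, f in ramp.fold_changes.items()
        }
    )


def rhs(state: SpeciesState, params: RateParameters) -> np.ndarray:
    """Mass-action time derivatives, in the order of :data:`SPECIES`.

    Units: uM/s for the five species, AU/s for protein.
    """
    y = state.as_array()
    if np.any(y[:5] < 0):
        raise ValueError("species concentrations must be >= 0")
    return _rhs_raw(y, params)


def _rhs_raw(y: np.ndarray, p: RateParameters) -> np.ndarray:
    E, B, G, C1, C2 = y[0], y[1], y[2], y[3], y[4]
    a1 = p.k_on1 * E * B
    d1 = p.k_off1 * C1
    a2 = p.k_on2 * E * G
    d2 = p.k_off2 * C2
    return np.array(
        [
            d1 + d2 - a1 - a2,
            d1 + p.k_cat_4ebp * C2 - p.k_lys_4ebp * B - a1,
            d2 - a2,
            a1 - d1,
            a2 - d2,
            p.k_cat_protein * C2,
        ]
    )


def _jac_raw(y: np.ndarray, p: RateParameters) -> np.ndarray:
    E, B, G = y[0], y[1], y[2]
    kon1E, kon1B = p.k_on1 * E, p.k_on1 * B
    kon2E, kon2G = p.k_on2 * E, p.k_on2 * G
    return np.array(
        [
            [-kon1B - kon2G, -kon1E, -kon2E, p.k_off1, p.k_off2, 0.0],
            [-kon1B, -kon1E - p.k_lys_4ebp, 0.0, p.k_off1, p.k_cat_4ebp, 0.0],
            [-kon2G, 0.0, -kon2E, 0.0, p.k_off2, 0.0],
            [kon1B, kon1E, 0.0, -p.k_off1, 0.0, 0.0],
            [kon2G, 0.0, kon2E, 0.0, -p.k_off2, 0.0],
            [0.0, 0.0, 0.0, 0.0, p.k_cat_protein, 0.0],
        ]
    )


@dataclass
class Trajectory:
    """Integrated trajectory: times in seconds, states as an (n, 6) array."""

    t: np.ndarray
    y: np.ndarray
    ramp: ParameterRamp

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_array(self.y[i])

    @property
    def times_min(self) -> np.ndarray:
        return self.t / 60.0

    def species(self, name: str) -> np.ndarray:
        return self.y[:, SPECIES.index(name)]

    def total_4ebp(self) -> np.ndarray:
        return self.species("fourebp_free") + self.species("complex_eb")

    def total_4ebp_pct(self, reference: float | None = None) -> np.ndarray:
        """Total 4E-BP as percent of its value at the first time point."""
        tot = self.total_4ebp()
        ref = tot[0] if reference is None else reference
        return 100.0 * tot / ref

    def to_frame(self):
        import pandas as pd

        recs = []
        for j, name in enumerate(SPECIES):
            for i, ti in enumerate(self.t):
                recs.append((ti / 60.0, name, self.y[i, j]))
        return pd.DataFrame(recs, columns=["time_min", "species", "value_uM"])


def simulate(
    initial: SpeciesState,
    ramp: ParameterRamp,
    t_grid: Sequence[float],
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> Trajectory:
    """Integrate the model over ``t_grid`` (seconds, increasing, from t=0).

    Ramped parameters are handled by splitting the integration at the ramp
    boundaries so the solver never steps across a derivative discontinuity.
    A stiff-capable method (LSODA) with an analytic Jacobian is used.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) == 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a non-empty strictly increasing 1-D array")
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be > 0")

    t0, t_final = float(t_grid[0]), float(t_grid[-1])
    breaks = sorted(
        {t0, t_final}
        | {t for t in (ramp.t_start, ramp.t_end) if t0 < t < t_final}
    )

    def f(t, y):
        return _rhs_raw(y, params_at_time(ramp, t))

    def jac(t, y):
        return _jac_raw(y, params_at_time(ramp, t))

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y0 = initial.as_array()
    for a, b in zip(breaks[:-1], breaks[1:]):
        inside = t_grid[(t_grid > a) & (t_grid < b)]
        t_eval = np.concatenate(([a], inside, [b]))
        sol = solve_ivp(
            f,
            (a, b),
            y0,
            method="LSODA",
            jac=jac,
            rtol=rel_tol,
            atol=abs_tol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise IntegrationError(f"ODE solver failed on [{a}, {b}]: {sol.message}")
        y0 = sol.y[:, -1]
        ts.append(sol.t)
        ys.append(sol.y.T)

    t_all = np.concatenate(ts)
    y_all = np.vstack(ys)
    # keep only requested grid points (breaks may have added t_start/t_end)
    idx = np.searchsorted(t_all, t_grid)
    t_out = t_all[idx]
    y_out = y_all[idx]

    if np.any(y_out[:, :5] < -abs_tol * 100):
        raise IntegrationError("negative species concentration beyond tolerance")
    y_out = y_out.copy()
    y_out[:, :5] = np.clip(y_out[:, :5], 0.0, None)
    return Trajectory(t=t_out, y=y_out, ramp=ramp)


@dataclass
class TimeCourse:
    """Observed or simulated time series: minutes, percent (or AU), replicate.

    ``values`` are percent of each replicate's own t=0 observation for 4E-BP
    densitometry-style data, or arbitrary units for protein accumulation.
    """

    times_min: np.ndarray
    values: np.ndarray
    replicates: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.replicates = np.asarray(self.replicates)
        n = len(self.times_min)
        if not (len(self.values) == len(self.replicates) == n):
            raise ValueError("times, values, replicates must have equal length")
        if n == 0:
            raise ValueError("time course is empty")
        if not np.all(np.isfinite(self.times_min)) or not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("times and values must be finite")
        for rep in np.unique(self.replicates):
            t = self.times_min[self.replicates == rep]
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times not strictly increasing in replicate {rep!r}")

    def __len__(self) -> int:
        return len(self.times_min)

    @property
    def n_replicates(self) -> int:
        return len(np.unique(self.replicates))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "replicate_id": self.replicates,
                "time_min": self.times_min,
                "value_pct": self.values,
            }
        )

    @classmethod
    def from_frame(cls, df) -> "TimeCourse":
        return cls(
            times_min=df["time_min"].to_numpy(float),
            values=df["value_pct"].to_numpy(float),
            replicates=df["replicate_id"].to_numpy(),
        )


# Table 1 canonical parameters: SPR-measured eIF4E/4E-BP kinetics, literature
# eIF4E/eIF4G kinetics, emetine-fitted degradation and flux-balance synthesis.
UNFERTILIZED_RATES = RateParameters(
    k_on1=9.3e3 * MOLAR_TO_UM,   # 9.3e3 M^-1 s^-1
    k_off1=2.2e-4,
    k_on2=1.82e3 * MOLAR_TO_UM,  # 1.82e3 M^-1 s^-1
    k_off2=2.0e-4,
    k_cat_4ebp=3.2e-3,
    k_lys_4ebp=5.9e-4,
    k_cat_protein=1.0,
)

TABLE1_TOTALS = Totals(total_4ebp=3.67, total_eif4e=2.15, total_eif4g=2.15)
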