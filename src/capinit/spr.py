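"""1:1 Langmuir kinetics for surface-plasmon-resonance sensorgrams.

The eIF4E / 4E-BP association and dissociation rate constants are measured by
SPR: the binding partner is immobilized, the analyte is injected in a
dilution series, and the response R(t) (relative refractive index, uRIU)
follows pseudo-first-order 1:1 kinetics

    association:   R(t) = R_eq (1 - exp(-(k_on C + k_off) t)),
                   R_eq = R_max C / (KD + C)
    dissociation:  R(t) = R(t_assoc) exp(-k_off (t - t_assoc))

A *global* fit shares k_on, k_off and R_max across all concentrations of the
series, which is what makes both rate constants identifiable even when
individual curves are near saturation.  Mass-transport limitation and
baseline referencing are out of scope; synthetic curves are generated
pre-referenced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "Sensorgram",
    "BindingFit",
    "simulate_sensorgram",
    "sensorgram_response",
    "global_fit",
    "dissociation_koff",
    "equilibrium_kd",
    "dilution_series",
    "PAPER_DILUTION_M",
]

#: the measured eIF4E dilution series: 3-fold steps from 4.37 uM down to
#: 53.9 nM (concentrations in molar)
PAPER_DILUTION_M = tuple(4.37e-6 / 3.0 ** k for k in range(5))


@dataclass
class Sensorgram:
    """A single-analyte-concentration SPR trace.

    ``t_assoc`` and ``t_dissoc`` are the association and dissociation phase
    durations in seconds (boundaries set by the instrument, not inferred).
    Concentration is molar; response in uRIU.
    """

    times: np.ndarray
    response: np.ndarray
    analyte_concentration: float
    t_assoc: float
    t_dissoc: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if len(self.times) != len(self.response):
            raise ValueError("times and response must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.analyte_concentration < 0:
            raise ValueError("analyte concentration must be >= 0")


@dataclass
class BindingFit:
    """Globally fitted 1:1 binding constants with asymptotic standard errors."""

    k_on: float      # M^-1 s^-1
    k_off: float     # s^-1
    r_max: float     # uRIU
    k_on_err: float
    k_off_err: float
    r_max_err: float
    residual_norm: float

    @property
    def kd(self) -> float:
        """Dissociation constant k_off/k_on in M."""
        return self.k_off / self.k_on


def sensorgram_response(
    times: np.ndarray,
    k_on: float,
    k_off: float,
    r_max: float,
    concentration: float,
    t_assoc: float,
) -> np.ndarray:
    """Closed-form 1:1 response at ``times`` (association then dissociation)."""
    times = np.asarray(times, dtype=float)
    kobs = k_on * concentration + k_off
    kd = k_off / k_on if k_on > 0 else np.inf
    r_eq = r_max * concentration / (kd + concentration) if np.isfinite(kd) else 0.0
    assoc = r_eq * (1.0 - np.exp(-kobs * np.clip(times, 0.0, t_assoc)))
    r_end = r_eq * (1.0 - np.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-k_off * np.clip(times - t_assoc, 0.0, None))
    return np.where(times <= t_assoc, assoc, dissoc)


def simulate_sensorgram(
    k_on: float,
    k_off: float,
    r_max: float,
    concentration: float,
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Sensorgram:
    """Generate a (optionally noisy) synthetic 1:1 sensorgram.

    ``noise_sd`` is Gaussian noise in uRIU added i.i.d. to every sample;
    with a fixed ``seed`` the output is reproducible bit for bit.
    """
    for name, v in [("k_on", k_on), ("k_off", k_off), ("r_max", r_max),
                    ("concentration", concentration)]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    times = np.arange(0.0, t_assoc + t_dissoc + 0.5 * dt, dt)
    resp = sensorgram_response(times, k_on, k_off, r_max, concentration, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=len(resp))
    return Sensorgram(
        times=times,
        response=resp,
        analyte_concentration=concentration,
        t_assoc=t_assoc,
        t_dissoc=t_dissoc,
    )


def dissociation_koff(sg: Sensorgram) -> float:
    """k_off from a log-linear fit of the dissociation phase of one curve."""
    mask = (sg.times > sg.t_assoc) & (sg.response > 0)
    if mask.sum() < 2:
        raise ValueError("not enough positive dissociation-phase points")
    t = sg.times[mask] - sg.t_assoc
    slope = np.polyfit(t, np.log(sg.response[mask]), 1)[0]
    return float(-slope)


def global_fit(
    sensorgrams: Sequence[Sensorgram],
    p0: Sequence[float] | None = None,
) -> BindingFit:
    """Global nonlinear least-squares 1:1 fit across a dilution series.

    k_on, k_off and R_max are shared by all curves; the fit runs in log
    space to enforce positivity.  Standard errors are the asymptotic values
    from the Jacobian at the optimum.
    """
    if len(sensorgrams) < 2:
        raise ValueError("global fit needs at least two analyte concentrations")

    if p0 is None:
        r0 = 1.5 * max(sg.response.max() for sg in sensorgrams)
        top = max(sensorgrams, key=lambda s: s.analyte_concentration)
        try:
            koff0 = max(dissociation_koff(top), 1e-6)
        except ValueError:
            koff0 = 1e-3
        kon0 = 1e4
        p0 = (kon0, koff0, r0)

    def residuals(logp: np.ndarray) -> np.ndarray:
        k_on, k_off, r_max = np.exp(logp)
        res = [
            sensorgram_response(
                sg.times, k_on, k_off, r_max, sg.analyte_concentration, sg.t_assoc
            )
            - sg.response
            for sg in sensorgrams
        ]
        return np.concatenate(res)

    sol = least_squares(residuals, np.log(np.asarray(p0, dtype=float)), method="lm")
    if not sol.success:
        raise RuntimeError(f"global 1:1 fit failed: {sol.message}")
    k_on, k_off, r_max = np.exp(sol.x)

    # asymptotic covariance in log space -> delta-method SEs in linear space
    n_pts = len(sol.fun)
    dof = max(n_pts - 3, 1)
    s2 = float(np.sum(sol.fun ** 2)) / dof
    jtj = sol.jac.T @ sol.jac
    cond = np.linalg.cond(jtj)
    if not np.isfinite(cond) or cond > 1e14:
        raise RuntimeError("ill-conditioned global fit (parameters not identifiable)")
    cov_log = s2 * np.linalg.inv(jtj)
    se_log = np.sqrt(np.diag(cov_log))
    return BindingFit(
        k_on=float(k_on),
        k_off=float(k_off),
        r_max=float(r_max),
        k_on_err=float(k_on * se_log[0]),
        k_off_err=float(k_off * se_log[1]),
        r_max_err=float(r_max * se_log[2]),
        residual_norm=float(np.sqrt(np.sum(sol.fun ** 2))),
    )


def equilibrium_kd(concentrations: Sequence[float], r_eq: Sequence[float]) -> float:
    """KD (M) from a saturation fit R_eq = R_max C / (KD + C)."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(r_eq, dtype=float)

    def model(cc, r_max, kd):
        return r_max * cc / (kd + cc)

    popt, _ = curve_fit(model, c, r, p0=(r.max() * 1.2, np.median(c)))
    return float(popt[1])


def dilution_series(top: float, n: int = 6, factor: float = 3.0) -> np.ndarray:
    """Analyte concentrations for an ``n``-point ``factor``-fold dilution series."""
    return top / factor ** np.arange(n)
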