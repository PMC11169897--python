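"""Extracellular stimulation of a retinal axon by the cathode plate.

Two stages replace the proprietary tissue/neuron engine, at property-level
fidelity:

1. Plate field: the 100 x 100 um^2 electrode is an equipotential plate in a
   uniformly conductive medium (0.027 S/m).  A method-of-moments solve on a
   square patch grid yields the plate current distribution (edge-peaked, as
   expected for an equipotential conductor) and, from it, the extracellular
   potential and current density along the axon line at the 5 um standoff.

2. Axon: an unmyelinated fibre as a cable of classical Hodgkin-Huxley
   compartments driven by the extracellular potential (activating-function
   coupling).  Crank-Nicolson on the cable term with Rush-Larsen gate
   updates keeps the fixed-step integration stable and deterministic.

The membrane model is a qualitative substitute: thresholds have the right
existence, order of magnitude and monotonicities (strength-duration,
standoff), but exact equality with any particular proprietary channel set is
not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_banded

UM_TO_M = 1e-6


@dataclass(frozen=True)
class ElectrodeSpec:
    side_um: float = 100.0
    thickness_nm: float = 50.0
    standoff_um: float = 5.0
    conductivity_s_per_m: float = 0.027
    rel_permittivity: float = 4.06e7  # tissue at 10 Hz; unused in the
    # resistive quasi-static solve but kept as part of the tissue record

    def __post_init__(self) -> None:
        for name in ("side_um", "thickness_nm", "standoff_um",
                     "conductivity_s_per_m", "rel_permittivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AxonSpec:
    diameter_um: float = 1.0
    length_um: float = 400.0
    compartment_um: float = 5.0
    membrane_model: str = "hodgkin_huxley"
    axial_resistivity_ohm_cm: float = 35.4

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.length_um <= 0:
            raise ValueError("diameter and length must be positive")
        if not (0 < self.compartment_um <= 5.0):
            raise ValueError("compartment length must lie in (0, 5] um "
                             "(spatial convergence requirement)")

    def positions_um(self) -> np.ndarray:
        n = int(round(self.length_um / self.compartment_um))
        return (np.arange(n) - (n - 1) / 2.0) * self.compartment_um


@dataclass(frozen=True)
class StimulusPulse:
    amplitude_v: float
    duration_ms: float = 1.0
    period_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass(frozen=True)
class MembraneTrace:
    times_ms: np.ndarray
    x_um: np.ndarray
    v_mv: np.ndarray  # (time, compartment), membrane potential

    @property
    def peak_mv(self) -> float:
        return float(np.max(self.v_mv))

    def spiked(self, threshold_mv: float = -10.0) -> bool:
        return self.peak_mv >= threshold_mv


# ---------------------------------------------------------------------------
# Method-of-moments plate solve
# ---------------------------------------------------------------------------

MIN_PATCHES_PER_SIDE = 20


@lru_cache(maxsize=16)
def _plate_solution(side_um: float, conductivity_s_per_m: float,
                    n_patches: int):
    """Patch centres (m) and per-patch currents (A) for a 1 V plate."""
    if n_patches < MIN_PATCHES_PER_SIDE:
        raise ValueError(
            f"patch grid too coarse to resolve the plate edges: need >= "
            f"{MIN_PATCHES_PER_SIDE} patches per side, got {n_patches}"
        )
    side_m = side_um * UM_TO_M
    a = side_m / n_patches
    centres_1d = (np.arange(n_patches) + 0.5) * a - side_m / 2.0
    xx, yy = np.meshgrid(centres_1d, centres_1d, indexing="ij")
    x = xx.ravel()
    y = yy.ravel()
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    dist = np.hypot(dx, dy)
    sigma = conductivity_s_per_m
    with np.errstate(divide="ignore"):
        resist = 1.0 / (4.0 * np.pi * sigma * dist)
    # self term: centre potential of a uniform square current patch
    self_resist = 4.0 * np.log(1.0 + np.sqrt(2.0)) / (4.0 * np.pi * sigma * a)
    np.fill_diagonal(resist, self_resist)
    currents = np.linalg.solve(resist, np.ones(len(x)))
    return x, y, currents, a


def plate_current_profile(e: ElectrodeSpec, voltage_v: float,
                          line_standoff_um: float | None = None,
                          x_positions_um: np.ndarray | None = None,
                          n_patches: int = 30):
    """Normal current density (A/m^2) along the axon line at the standoff.

    Returns ``(x_um, j_a_m2)``.  The profile is linear in the applied
    voltage and carries its sign.
    """
    standoff = (e.standoff_um if line_standoff_um is None
                else line_standoff_um)
    if x_positions_um is None:
        x_positions_um = np.linspace(-1.5 * e.side_um, 1.5 * e.side_um, 301)
    x_positions_um = np.asarray(x_positions_um, dtype=float)
    px, py, currents, _ = _plate_solution(e.side_um, e.conductivity_s_per_m,
                                          n_patches)
    z = standoff * UM_TO_M
    xs = x_positions_um[:, None] * UM_TO_M
    r2 = (xs - px[None, :]) ** 2 + py[None, :] ** 2 + z**2
    # J_z = sum I_j z / (4 pi r^3) for unit plate voltage
    jz_unit = np.sum(currents[None, :] * z / (4.0 * np.pi * r2**1.5), axis=1)
    return x_positions_um, voltage_v * jz_unit


def extracellular_potential(e: ElectrodeSpec, voltage_v: float,
                            x_positions_um: np.ndarray,
                            line_standoff_um: float | None = None,
                            n_patches: int = 30) -> np.ndarray:
    """Extracellular potential (V) along the axon line at the standoff."""
    standoff = (e.standoff_um if line_standoff_um is None
                else line_standoff_um)
    px, py, currents, _ = _plate_solution(e.side_um, e.conductivity_s_per_m,
                                          n_patches)
    z = standoff * UM_TO_M
    xs = np.asarray(x_positions_um, dtype=float)[:, None] * UM_TO_M
    r = np.sqrt((xs - px[None, :]) ** 2 + py[None, :] ** 2 + z**2)
    phi_unit = np.sum(currents[None, :] / (4.0 * np.pi
                                           * e.conductivity_s_per_m * r),
                      axis=1)
    return voltage_v * phi_unit


def plate_surface_current(e: ElectrodeSpec, voltage_v: float,
                          n_patches: int = 30):
    """Per-patch current density on the plate itself (edge-peaked)."""
    px, py, currents, a = _plate_solution(e.side_um, e.conductivity_s_per_m,
                                          n_patches)
    return px / UM_TO_M, py / UM_TO_M, voltage_v * currents / a**2


# ---------------------------------------------------------------------------
# Hodgkin-Huxley cable
# ---------------------------------------------------------------------------

# classical squid-axon membrane at 6.3 C
_C_M = 1.0          # uF/cm^2
_G_NA, _E_NA = 120.0, 50.0     # mS/cm^2, mV
_G_K, _E_K = 36.0, -77.0
_G_L, _E_L = 0.3, -54.387
_V_REST = -65.0


def _safe_exp_ratio(x):
    """x / (exp(x) - 1), stable at x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-7, 1.0 - x / 2.0, x / np.expm1(x))
    return out


def _gate_rates(v):
    # alpha_m = 0.1 (v+40) / (1 - exp(-(v+40)/10)) == ratio(-(v+40)/10)
    am = _safe_exp_ratio(-(v + 40.0) / 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    # alpha_n = 0.01 (v+55) / (1 - exp(-(v+55)/10)) == 0.1 * ratio(-(v+55)/10)
    an = 0.1 * _safe_exp_ratio(-(v + 55.0) / 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def _steady_gates(v):
    am, bm, ah, bh, an, bn = _gate_rates(v)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def simulate_membrane(a: AxonSpec, ve_profile_mv: np.ndarray,
                      pulse: StimulusPulse, t_total_ms: float = 5.0,
                      dt_ms: float = 0.005) -> MembraneTrace:
    """Cable + Hodgkin-Huxley response to an extracellular potential pulse.

    ``ve_profile_mv`` is the extracellular potential (mV) at each
    compartment for the pulse amplitude; it is switched on for
    ``pulse.duration_ms`` and off afterwards (monophasic rectangular pulse).
    Crank-Nicolson handles the stiff cable coupling; an explicit step with
    Rush-Larsen gates handles the membrane.  Raises if the time step is too
    coarse for the membrane dynamics.
    """
    x = a.positions_um()
    n = len(x)
    ve = np.asarray(ve_profile_mv, dtype=float)
    if ve.shape != (n,):
        raise ValueError(
            f"field profile must be sampled at every compartment "
            f"({n} expected, got {ve.shape})"
        )
    if dt_ms > 0.025:
        raise ValueError("integration unstable: dt must be <= 0.025 ms for "
                         "the explicit membrane update")

    dx_cm = a.compartment_um * 1e-4
    d_cm = a.diameter_um * 1e-4
    r_kohm_cm = a.axial_resistivity_ohm_cm / 1000.0
    g_ax = d_cm / (4.0 * r_kohm_cm * dx_cm**2)  # mS/cm^2

    # tridiagonal Laplacian with sealed (Neumann) ends
    main = -2.0 * np.ones(n)
    main[0] = main[-1] = -1.0
    upper = np.ones(n - 1)

    lam = dt_ms * g_ax / (2.0 * _C_M)
    ab = np.zeros((3, n))
    ab[0, 1:] = -lam * upper
    ab[1, :] = 1.0 - lam * main
    ab[2, :-1] = -lam * upper

    def laplacian(vec):
        out = np.empty_like(vec)
        out[1:-1] = vec[:-2] - 2.0 * vec[1:-1] + vec[2:]
        out[0] = vec[1] - vec[0]
        out[-1] = vec[-2] - vec[-1]
        return out

    n_steps = int(round(t_total_ms / dt_ms))
    v = np.full(n, _V_REST)
    m, h, ng = _steady_gates(v)
    times = np.arange(n_steps + 1) * dt_ms
    trace = np.empty((n_steps + 1, n))
    trace[0] = v

    lap_ve = laplacian(ve)
    for step in range(n_steps):
        t = step * dt_ms
        on_now = float((t % pulse.period_ms) < pulse.duration_ms)
        on_next = float(((t + dt_ms) % pulse.period_ms) < pulse.duration_ms)

        i_ion = (_G_NA * m**3 * h * (v - _E_NA)
                 + _G_K * ng**4 * (v - _E_K)
                 + _G_L * (v - _E_L))
        rhs = (v + lam * laplacian(v)
               + dt_ms * g_ax / (2.0 * _C_M) * (on_now + on_next) * lap_ve
               - dt_ms / _C_M * i_ion)
        v = solve_banded((1, 1), ab, rhs)
        # during a strong pulse the local membrane potential legitimately
        # approaches the extracellular amplitude; guard only true blow-up
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > 50.0e3:
            raise RuntimeError(
                "integration diverged: reduce dt or compartment length"
            )

        am, bm, ah, bh, an, bn = _gate_rates(v)
        for gate, alpha, beta in ((0, am, bm), (1, ah, bh), (2, an, bn)):
            tau = 1.0 / (alpha + beta)
            inf = alpha * tau
            if gate == 0:
                m = inf + (m - inf) * np.exp(-dt_ms / tau)
            elif gate == 1:
                h = inf + (h - inf) * np.exp(-dt_ms / tau)
            else:
                ng = inf + (ng - inf) * np.exp(-dt_ms / tau)
        trace[step + 1] = v

    return MembraneTrace(times, x, trace)


def axon_field_profile(e: ElectrodeSpec, a: AxonSpec, amplitude_v: float,
                       n_patches: int = 30) -> np.ndarray:
    """Extracellular potential (mV) at each axon compartment."""
    phi_v = extracellular_potential(e, amplitude_v, a.positions_um(),
                                    n_patches=n_patches)
    return phi_v * 1000.0


def threshold_search(e: ElectrodeSpec, a: AxonSpec,
                     pulse_duration_ms: float = 1.0,
                     amplitude_cap_v: float = 2.0,
                     resolution_v: float = 1e-3,
                     n_patches: int = 30,
                     t_total_ms: float = 5.0,
                     dt_ms: float = 0.005) -> float:
    """Smallest cathodic |V| on the plate that elicits an action potential.

    Bisection to the requested voltage resolution; deterministic.
    """
    unit_profile = axon_field_profile(e, a, -1.0, n_patches=n_patches)

    def spikes(amplitude: float) -> bool:
        pulse = StimulusPulse(amplitude_v=-amplitude,
                              duration_ms=pulse_duration_ms)
        trace = simulate_membrane(a, amplitude * unit_profile, pulse,
                                  t_total_ms=t_total_ms, dt_ms=dt_ms)
        return trace.spiked()

    if not spikes(amplitude_cap_v):
        raise ValueError(
            f"no action potential up to the {amplitude_cap_v} V amplitude cap"
        )
    lo, hi = 0.0, amplitude_cap_v
    while hi - lo > resolution_v:
        mid = 0.5 * (lo + hi)
        if spikes(mid):
            hi = mid
        else:
            lo = mid
    return hi
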