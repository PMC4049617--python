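"""Transient integration, the glucose-pulse protocol and response times.

The ODE system is stiff (chain enzymes relax within seconds while F26BP
turns over on the hour scale), so integration uses an implicit-capable
adaptive solver at tight tolerances.  A 500 h horizon is the default for
settling runs.  The pulse protocol reproduces the transient discrimination
experiment: a brief glucose excursion from the bistable window commits the
system to the high-flux branch only if the F26BP pool, whose relaxation
rate is proportional to the PFKFB expression level, responds quickly
enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .catalog import ModelConfig
from .errors import NumericalError, ProtocolError
from .model import fluxes, rhs_raw
from .state import MetaboliteState
from .steady_state import find_steady_states

#: Default settling horizon (h).
T_SETTLE = 500.0


@dataclass
class Trajectory:
    """Time-stamped metabolite and flux series from a transient run."""

    t: np.ndarray
    y: np.ndarray                        # shape (n_times, 12)
    config: ModelConfig = field(repr=False)
    glucose: np.ndarray | None = None    # input profile sampled on t

    def state_at(self, index: int) -> MetaboliteState:
        return MetaboliteState.from_array(np.maximum(self.y[index], 0.0))

    @property
    def terminal_state(self) -> MetaboliteState:
        return self.state_at(-1)

    def flux_series(self, which: str = "PFK") -> np.ndarray:
        """Instantaneous flux (mM/h) of one reaction along the trajectory."""
        out = np.empty(len(self.t))
        for i, ti in enumerate(self.t):
            cfg = self.config
            if self.glucose is not None:
                cfg = cfg.with_env(GLC_EXT=float(self.glucose[i]))
            out[i] = fluxes(self.state_at(i), cfg.env, cfg)[which]
        return out

    def to_frame(self):
        import pandas as pd

        from .state import SPECIES
        frame = pd.DataFrame(self.y, columns=list(SPECIES))
        frame.insert(0, "t", self.t)
        if self.glucose is not None:
            frame["glucose_input"] = self.glucose
        return frame


def _segment(config: ModelConfig, y0: np.ndarray, t0: float, t1: float,
             rtol: float, atol: float, out_step: float) -> tuple[np.ndarray, np.ndarray]:
    env = config.env
    t_eval = np.arange(t0, t1, out_step)
    if len(t_eval) == 0 or t_eval[-1] < t1:
        t_eval = np.append(t_eval, t1)
    sol = solve_ivp(lambda t, y: rhs_raw(y, env, config), (t0, t1), y0,
                    method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise NumericalError(f"integration failed at t = {sol.t[-1]:.3f} h: "
                             f"{sol.message}")
    return sol.t, sol.y.T


def integrate(config: ModelConfig,
              glucose_profile: float | Callable[[float], float] | list,
              init: MetaboliteState, t_end: float = T_SETTLE,
              rtol: float = 1e-8, atol: float = 1e-10,
              out_step: float = 0.1) -> Trajectory:
    """Integrate the model under a constant or piecewise-constant glucose input.

    ``glucose_profile`` is a constant (mM), a callable t -> mM evaluated as
    a step function on the output grid, or a list of ``(t_start, value)``
    breakpoints.  Piecewise-constant profiles are integrated segment by
    segment so the discontinuities are exact.
    """
    if callable(glucose_profile):
        ts = np.arange(0.0, t_end + 0.5 * out_step, out_step)
        values = np.array([float(glucose_profile(t)) for t in ts])
        jumps = np.nonzero(np.diff(values) != 0)[0]
        breaks = [(0.0, values[0])] + [(float(ts[i + 1]), float(values[i + 1]))
                                       for i in jumps]
    elif isinstance(glucose_profile, (int, float)):
        breaks = [(0.0, float(glucose_profile))]
    else:
        breaks = [(float(t), float(v)) for t, v in glucose_profile]
    if breaks[0][0] != 0.0:
        raise ProtocolError("glucose profile must start at t = 0")

    t_all = [np.array([0.0])]
    y_all = [init.as_array()[None, :]]
    g_all = [np.array([breaks[0][1]])]
    y0 = init.as_array()
    for k, (t_start, value) in enumerate(breaks):
        t_stop = breaks[k + 1][0] if k + 1 < len(breaks) else t_end
        if t_stop <= t_start:
            continue
        cfg = config.with_env(GLC_EXT=value)
        t, y = _segment(cfg, y0, t_start, t_stop, rtol, atol, out_step)
        y0 = y[-1]
        t_all.append(t[1:])
        y_all.append(y[1:])
        g_all.append(np.full(len(t) - 1, value))
    t = np.concatenate(t_all)
    y = np.maximum(np.concatenate(y_all), 0.0)
    return Trajectory(t=t, y=y, config=config, glucose=np.concatenate(g_all))


@dataclass(frozen=True)
class PulseOutcome:
    """Result of one glucose-pulse experiment."""

    switched: bool
    settle_time: float | None    # h; response time to 90% of the flux gap
    final_flux: float            # mM/h at the end of the run
    low_flux: float              # stable branch fluxes at base glucose
    high_flux: float
    pulse_glucose: float
    trajectory: Trajectory = field(repr=False)


def pulse_protocol(config: ModelConfig, pfkfb_level: float = 1.0,
                   base_glucose: float = 5.0,
                   pulse_glucose: float | None = 25.0,
                   t0: float = 50.0, duration: float = 1.5,
                   t_end: float | None = None, seed: int = 0) -> PulseOutcome:
    """Glucose pulse from the low-flux branch of a bistable operating point.

    The system is initialized on the algebraic low-flux root at
    ``base_glucose``, glucose is stepped to ``pulse_glucose`` (default
    25 mM, the high-glucose culture concentration; pass None to use
    switch-up + 2 mM) at ``t0`` for ``duration`` hours, and the run
    continues at base glucose until ``t_end`` to decide which branch the
    system settled on.
    """
    cfg = config.with_levels(PFKFB=pfkfb_level)
    sols = find_steady_states(base_glucose, cfg, n_starts=40, seed=seed,
                              method="reduction")
    stable = [s for s in sols if s.stable]
    if len(stable) < 2:
        raise ProtocolError(
            f"base glucose {base_glucose} mM is not in a bistable window "
            f"({len(stable)} stable state(s) found)")
    low, high = stable[0], stable[-1]
    if pulse_glucose is None:
        from .bifurcation import switch_points
        grid = np.arange(max(base_glucose - 4, 0.25), base_glucose + 10, 0.5)
        up, _ = switch_points(cfg, "glucose", grid, seed=seed)
        pulse_glucose = (up if up is not None else base_glucose) + 2.0
    if t_end is None:
        t_end = t0 + duration + T_SETTLE
    profile = [(0.0, base_glucose), (t0, float(pulse_glucose)),
               (t0 + duration, base_glucose)]
    traj = integrate(cfg, profile, low.state, t_end=t_end)
    flux = traj.flux_series("PFK")
    final = float(flux[-1])
    switched = abs(final - high.flux) < abs(final - low.flux)
    settle = response_time(traj, target_flux=high.flux) if switched else None
    return PulseOutcome(switched=switched, settle_time=settle,
                        final_flux=final, low_flux=low.flux,
                        high_flux=high.flux,
                        pulse_glucose=float(pulse_glucose), trajectory=traj)


def response_time(trajectory: Trajectory, target_flux: float,
                  fraction: float = 0.9, which: str = "PFK") -> float | None:
    """First time the flux crosses ``fraction`` of the gap to ``target_flux``.

    Returns None when the threshold is never crossed (e.g. a constant
    trajectory).
    """
    flux = trajectory.flux_series(which)
    start = flux[0]
    threshold = start + fraction * (target_flux - start)
    if target_flux >= start:
        hit = np.nonzero(flux >= threshold)[0]
    else:
        hit = np.nonzero(flux <= threshold)[0]
    if len(hit) == 0:
        return None
    return float(trajectory.t[hit[0]])
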