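"""Quasi-static scans of steady states against a control parameter.

A scan enumerates the complete steady-state set at every grid value of the
control parameter (glucose, PFKFB K/P, an enzyme level, or one of the fixed
environment concentrations), classifies stability, and detects the
switch-up / switch-down values bounding any multistable window by bisection
on the coexisting-state count.  Branches are labelled by flux ordering
(low / intermediate / high).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import ModelConfig
from .errors import ConfigurationError
from .steady_state import SteadyStateSolution, find_steady_states

#: Control parameters scan() understands besides "level:<ENZYME>".
SCAN_PARAMETERS = ("glucose", "KP", "NAD_NADH", "LAC", "ALA")


def apply_parameter(config: ModelConfig, parameter: str, value: float
                    ) -> tuple[ModelConfig, float]:
    """Return (modified config, glucose to solve at) for one scan value."""
    glucose = config.env.GLC_EXT
    if parameter == "glucose":
        return config.with_env(GLC_EXT=value), value
    if parameter == "KP":
        return config.with_kp_ratio(value), glucose
    if parameter == "NAD_NADH":
        # vary the ratio at fixed NADH, mirroring a redox-state perturbation
        return config.with_env(NAD=value * config.env.NADH), glucose
    if parameter == "LAC":
        return config.with_env(LAC=value), glucose
    if parameter == "ALA":
        return config.with_env(ALA=value), glucose
    if parameter.startswith("level:"):
        enzyme = parameter.split(":", 1)[1]
        return config.with_levels(**{enzyme: value}), glucose
    raise ConfigurationError(
        f"unknown scan parameter {parameter!r}; valid: {SCAN_PARAMETERS} "
        "or 'level:<ENZYME>'")


@dataclass
class BifurcationDiagram:
    """Branch-resolved steady states along a control-parameter grid."""

    parameter: str
    grid: np.ndarray
    points: list[list[SteadyStateSolution]]
    switch_up: float | None = None
    switch_down: float | None = None
    branch_labels: list[list[str]] = field(default_factory=list)
    config: ModelConfig | None = field(default=None, repr=False)

    def n_states(self) -> np.ndarray:
        return np.array([len(p) for p in self.points])

    def n_stable(self) -> np.ndarray:
        return np.array([sum(s.stable for s in p) for p in self.points])

    def n_unstable(self) -> np.ndarray:
        return np.array([sum(not s.stable for s in p) for p in self.points])

    def max_coexisting(self) -> int:
        return int(self.n_states().max(initial=0))

    def is_bistable(self) -> bool:
        return bool((self.n_stable() >= 2).any())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (parameter value, steady state)."""
        rows = []
        for value, sols, labels in zip(
                self.grid, self.points,
                self.branch_labels or [[""] * len(p) for p in self.points]):
            for sol, lab in zip(sols, labels):
                row = {self.parameter: value, "flux": sol.flux,
                       "stability": sol.stability, "branch": lab,
                       "max_eig_real": sol.max_real_eigenvalue,
                       "residual": sol.residual_norm}
                row.update({k: v for k, v in zip(
                    sol.state.__dataclass_fields__, sol.state.as_array())})
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False, float_format="%.12g")
        return buf.getvalue()


def _label_branches(points: list[list[SteadyStateSolution]]) -> list[list[str]]:
    names = {1: ["only"], 2: ["low", "high"], 3: ["low", "intermediate", "high"]}
    out = []
    for sols in points:
        n = len(sols)
        if n in names:
            out.append(list(names[n]))
        else:
            out.append([f"branch{i}" for i in range(n)])
    return out


def scan(config: ModelConfig, parameter: str, grid, seed: int = 0,
         method: str = "reduction", n_starts: int = 60,
         detect_switches: bool = True) -> BifurcationDiagram:
    """Steady-state enumeration along a sorted control-parameter grid.

    Per-point seeds are derived from the master seed so points are
    reproducible independently.  With the default method the scalar flux
    reduction enumerates states exhaustively; "multistart" or "hybrid"
    follow the pseudorandom-initial-guess route instead.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    points = []
    for i, value in enumerate(grid):
        cfg, glucose = apply_parameter(config, parameter, float(value))
        sols = find_steady_states(glucose, cfg, n_starts=n_starts,
                                  seed=(seed * 100003 + i) % (2**31 - 1),
                                  method=method)
        points.append(sols)
    diagram = BifurcationDiagram(parameter=parameter, grid=grid, points=points,
                                 config=config)
    diagram.branch_labels = _label_branches(points)
    if detect_switches and len(grid) >= 2:
        up, down = switch_points(config, parameter, grid, diagram=diagram,
                                 seed=seed, method=method, n_starts=n_starts)
        diagram.switch_up, diagram.switch_down = up, down
    return diagram


def _count(config: ModelConfig, parameter: str, value: float, seed: int,
           method: str, n_starts: int) -> int:
    cfg, glucose = apply_parameter(config, parameter, value)
    return len(find_steady_states(glucose, cfg, n_starts=n_starts, seed=seed,
                                  method=method))


def switch_points(config: ModelConfig, parameter: str, grid,
                  diagram: BifurcationDiagram | None = None,
                  refine_to: float | None = None, seed: int = 0,
                  method: str = "reduction", n_starts: int = 60,
                  ) -> tuple[float | None, float | None]:
    """(switch_up, switch_down) of the multistable window, refined by bisection.

    switch_up is where the low branch ceases to exist (upper edge of the
    window); switch_down where the high branch appears (lower edge).  Both
    are None for a monostable diagram.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    if refine_to is None:
        span = grid[-1] - grid[0]
        refine_to = max(span / 2000.0, 1e-6)
    if diagram is not None and np.array_equal(diagram.grid, grid):
        counts = diagram.n_states()
    else:
        counts = np.array([_count(config, parameter, v, seed, method, n_starts)
                           for v in grid])
    multi = counts >= 3
    if not multi.any():
        return None, None

    def count(v: float) -> int:
        return _count(config, parameter, float(v), seed, method, n_starts)

    idx = np.nonzero(multi)[0]
    i_lo, i_hi = int(idx[0]), int(idx[-1])
    # upper edge
    if i_hi == len(grid) - 1:
        switch_up = float(grid[-1])
    else:
        lo, hi = grid[i_hi], grid[i_hi + 1]
        while hi - lo > refine_to:
            mid = 0.5 * (lo + hi)
            if count(mid) >= 3:
                lo = mid
            else:
                hi = mid
        switch_up = float(0.5 * (lo + hi))
    # lower edge
    if i_lo == 0:
        switch_down = float(grid[0])
    else:
        lo, hi = grid[i_lo - 1], grid[i_lo]
        while hi - lo > refine_to:
            mid = 0.5 * (lo + hi)
            if count(mid) >= 3:
                hi = mid
            else:
                lo = mid
        switch_down = float(0.5 * (lo + hi))
    return switch_up, switch_down


def bistability_region(config: ModelConfig, parameter: str,
                       bounds: tuple[float, float], n_coarse: int = 41,
                       **kwargs) -> tuple[float, float] | None:
    """[switch_down, switch_up] interval of the multistable window, or None."""
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ConfigurationError("bistability_region bounds must be finite")
    grid = np.linspace(lo, hi, n_coarse)
    up, down = switch_points(config, parameter, grid, **kwargs)
    if up is None:
        return None
    return (down, up)


def hysteresis_paths(config: ModelConfig, glucose_grid,
                     seed: int = 0) -> pd.DataFrame:
    """Quasi-static up-scan and down-scan fluxes along a glucose grid.

    The up-scan starts on the lowest-flux state and tracks its branch by
    nearest-neighbour continuation in concentration space, jumping only when
    the branch loses existence; the down-scan does the same from the top.
    Inside a bistable window the two paths occupy different branches.
    """
    grid = np.asarray(sorted(glucose_grid), dtype=float)
    per_point = []
    for i, g in enumerate(grid):
        sols = find_steady_states(float(g), config, n_starts=40,
                                  seed=(seed * 99991 + i) % (2**31 - 1),
                                  method="reduction")
        per_point.append([s for s in sols if s.stable] or sols)

    def follow(order):
        path = []
        current = None
        for i in order:
            sols = per_point[i]
            if current is None:
                current = sols[0 if order[0] == 0 else -1]
            else:
                ref = np.log10(current.state.as_array() + 1e-12)
                current = min(sols, key=lambda s: np.max(np.abs(
                    np.log10(s.state.as_array() + 1e-12) - ref)))
            path.append(current)
        return path

    up = follow(list(range(len(grid))))
    down = follow(list(range(len(grid) - 1, -1, -1)))[::-1]
    return pd.DataFrame({
        "glucose": grid,
        "flux_up_scan": [s.flux for s in up],
        "flux_down_scan": [s.flux for s in down],
    })


def enzyme_sensitivity(config: ModelConfig, enzyme_id: str,
                       fold_range: float = 100.0, n_levels: int = 9,
                       glucose_grid=None, seed: int = 0) -> pd.DataFrame:
    """Range of one enzyme's level over which glycolysis stays multistable.

    The level is varied over ``fold_range`` (two orders of magnitude by
    default, centred on the reference level) while everything else is held
    fixed; each level is scored by whether a multistable glucose window
    survives, and by its switch points (drift).
    """
    if glucose_grid is None:
        glucose_grid = np.concatenate([np.arange(0.5, 6.0, 0.5),
                                       np.arange(6.0, 26.0, 2.0)])
    half = np.sqrt(fold_range)
    levels = np.geomspace(1.0 / half, half, n_levels) if fold_range > 1 \
        else np.array([1.0])
    rows = []
    for level in levels:
        cfg = config.with_levels(**{enzyme_id: float(level)})
        up, down = switch_points(cfg, "glucose", glucose_grid, seed=seed)
        rows.append({"enzyme": enzyme_id, "level": float(level),
                     "bistable": up is not None,
                     "switch_up": up, "switch_down": down})
    return pd.DataFrame(rows)


def environment_sensitivity(config: ModelConfig, which: str, grid,
                            glucose_grid=None, seed: int = 0) -> pd.DataFrame:
    """Steady-state multiplicity versus one fixed-environment concentration.

    ``which`` is one of NAD_NADH, LAC, ALA.  Mitochondrial pyruvate is held
    at 0.1 mM for the lactate and alanine scans.  Each row reports the
    maximum number of coexisting states over glucose and the glucose switch
    points at that environment value.
    """
    if which not in ("NAD_NADH", "LAC", "ALA"):
        raise ConfigurationError(f"unknown environment axis {which!r}")
    if glucose_grid is None:
        glucose_grid = np.concatenate([np.arange(0.5, 6.0, 0.5),
                                       np.arange(6.0, 26.0, 2.0)])
    if which in ("LAC", "ALA"):
        config = config.with_env(PYR_M=0.1)
    rows = []
    for value in grid:
        cfg, _ = apply_parameter(config, which, float(value))
        counts = []
        for g in glucose_grid:
            counts.append(len(find_steady_states(float(g), cfg, n_starts=40,
                                                 seed=seed, method="reduction")))
        up, down = switch_points(cfg, "glucose", glucose_grid, seed=seed)
        rows.append({which: float(value),
                     "max_coexisting": int(max(counts)),
                     "switch_up": up, "switch_down": down})
    return pd.DataFrame(rows)
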