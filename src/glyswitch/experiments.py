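"""Scripted reproductions of the figure-level analyses.

Each experiment id maps to a function that runs the corresponding analysis
end-to-end from a configuration and returns an :class:`ExperimentResult`
holding the underlying data tables and a machine-readable summary
(switch points, state counts, pulse outcomes, flux ratios).  The in-silico
analogue of the cultured-cell hysteresis protocol lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bifurcation import scan, switch_points
from .catalog import ModelConfig, build_config
from .dynamics import integrate, pulse_protocol
from .errors import ConfigurationError, ProtocolError
from .model import fluxes
from .reduction import node_steady_states, node_switch_points
from .steady_state import find_steady_states

#: Cytosolic volume used to convert intracellular fluxes (mM/h) to
#: cell-specific rates (mmol per 1e9 cells per h): litres per 1e9 cells.
CELL_VOLUME_L_PER_1E9 = 3.66e-3


def flux_to_specific(flux_mm_per_h: float) -> float:
    """mM/h -> mmol/1e9 cells/h via the default cell volume."""
    return flux_mm_per_h * CELL_VOLUME_L_PER_1E9


def hela_like_config() -> ModelConfig:
    """The default HeLa-like configuration (both loops; reduced transport).

    PFKL with PKM2 at K/P = 10; the glucose transporter level is set to the
    transport-limited regime of cultured cells so that the bistable glucose
    window brackets the intermediate assay concentrations (switch-down just
    above 0.6 mM, switch-up just below 10 mM).
    """
    return build_config("PFKL", "PKM2", 10.0).with_levels(GLUT=0.12)


@dataclass
class ExperimentResult:
    """Tables and summary statistics of one scripted experiment."""

    experiment_id: str
    config_digest: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        import json
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables.items():
            frame.to_csv(out / f"{self.experiment_id}_{name}.csv",
                         index=False, float_format="%.12g")
        payload = {"experiment_id": self.experiment_id,
                   "config_digest": self.config_digest,
                   "summary": _jsonable(self.summary)}
        (out / f"{self.experiment_id}_summary.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# node experiments
# ---------------------------------------------------------------------------

def _node_diagram(config: ModelConfig, with_pfkfb: bool,
                  f6p_grid) -> pd.DataFrame:
    rows = []
    for f6p in f6p_grid:
        for st in node_steady_states(float(f6p), config, with_pfkfb):
            rows.append({"F6P": st.f6p, "F16BP": st.f16bp, "flux": st.flux,
                         "stable": st.stable})
    return pd.DataFrame(rows)


def _fig1b(config: ModelConfig | None, **kw) -> ExperimentResult:
    cfg = config or build_config("PFKL", "PKM1", 10.0)
    grid = np.arange(0.01, 0.51, 0.01)
    table = _node_diagram(cfg, with_pfkfb=False, f6p_grid=grid)
    up, down = node_switch_points(cfg, with_pfkfb=False)
    return ExperimentResult("fig1b", cfg.digest(), {"diagram": table},
                            {"switch_up_f6p_mm": up, "switch_down_f6p_mm": down})


def _fig1d(config: ModelConfig | None, kp_values=(0.5, 1, 2, 5, 10, 20, 50),
           **kw) -> ExperimentResult:
    cfg = config or build_config("PFKL", "PKM1", 10.0)
    rows = []
    for kp in kp_values:
        up, down = node_switch_points(cfg.with_kp_ratio(float(kp)))
        rows.append({"KP": float(kp), "bistable": up is not None,
                     "switch_up_f6p_mm": up, "switch_down_f6p_mm": down})
    table = pd.DataFrame(rows)
    return ExperimentResult("fig1d", cfg.digest(), {"kp_scan": table},
                            {"bistable_kp": table[table.bistable].KP.tolist(),
                             "monostable_kp": table[~table.bistable].KP.tolist()})


def _figS1(config: ModelConfig | None, kp_values=(0.5, 1, 2, 5, 10, 20, 50),
           **kw) -> ExperimentResult:
    cfg = config or build_config("PFKP", "PKM1", 10.0)
    rows = []
    for kp in kp_values:
        c = cfg.with_kp_ratio(float(kp))
        counts = [len(node_steady_states(float(f), c))
                  for f in np.arange(0.02, 0.62, 0.02)]
        rows.append({"KP": float(kp), "max_states": int(max(counts))})
    table = pd.DataFrame(rows)
    return ExperimentResult("figS1", cfg.digest(), {"kp_scan": table},
                            {"always_monostable":
                             bool((table.max_states == 1).all())})


# ---------------------------------------------------------------------------
# full-model glucose scans
# ---------------------------------------------------------------------------

_FIG2_SETS = {
    "fig2a": ("PFKP", "PKM1"),
    "fig2b": ("PFKL", "PKM1"),
    "fig2c": ("PFKP", "PKM2"),
    "fig2d": ("PFKL", "PKM2"),
}

#: Default glucose grid for full-model scans (mM): dense at low glucose.
GLUCOSE_GRID = np.concatenate([np.arange(0.25, 6.0, 0.25),
                               np.arange(6.0, 26.0, 1.0)])


def _fig2(which: str, config: ModelConfig | None, glucose_grid=None,
          seed: int = 0, **kw) -> ExperimentResult:
    pfk, pk = _FIG2_SETS[which]
    cfg = config or build_config(pfk, pk, 10.0)
    grid = GLUCOSE_GRID if glucose_grid is None else np.asarray(glucose_grid)
    diagram = scan(cfg, "glucose", grid, seed=seed)
    summary = {
        "max_coexisting": diagram.max_coexisting(),
        "max_stable": int(diagram.n_stable().max(initial=0)),
        "bistable": diagram.is_bistable(),
        "switch_up_glucose_mm": diagram.switch_up,
        "switch_down_glucose_mm": diagram.switch_down,
        "flux_at_max_glucose": float(diagram.points[-1][-1].flux)
        if diagram.points[-1] else None,
    }
    return ExperimentResult(which, cfg.digest(),
                            {"diagram": diagram.to_frame()}, summary)


def _fig2e(config: ModelConfig | None, kp_values=(2, 5, 10, 20, 50),
           glucose_grid=None, seed: int = 0, **kw) -> ExperimentResult:
    cfg = config or build_config("PFKL", "PKM2", 10.0)
    grid = GLUCOSE_GRID if glucose_grid is None else np.asarray(glucose_grid)
    rows = []
    for kp in kp_values:
        c = cfg.with_kp_ratio(float(kp))
        up, down = switch_points(c, "glucose", grid, seed=seed)
        rows.append({"KP": float(kp), "bistable": up is not None,
                     "switch_up_glucose_mm": up,
                     "switch_down_glucose_mm": down})
    table = pd.DataFrame(rows)
    return ExperimentResult("fig2e", cfg.digest(), {"kp_scan": table},
                            {"rows": table.to_dict("records")})


def _figS2(config: ModelConfig | None, kp_values=(5, 10, 20, 50, 100),
           seed: int = 0, **kw) -> ExperimentResult:
    cfg = config or build_config("PFKP", "PKM1", 10.0)
    grid = np.arange(0.5, 25.5, 1.0)
    rows = []
    for kp in kp_values:
        c = cfg.with_kp_ratio(float(kp))
        counts = [len(find_steady_states(float(g), c, n_starts=40, seed=seed,
                                         method="reduction")) for g in grid]
        rows.append({"KP": float(kp), "max_states": int(max(counts))})
    table = pd.DataFrame(rows)
    return ExperimentResult("figS2", cfg.digest(), {"kp_scan": table},
                            {"always_monostable":
                             bool((table.max_states == 1).all())})


def _figS3(config: ModelConfig | None,
           enzymes=("HK", "PFK", "PK", "GLUT", "LDH"), seed: int = 0,
           **kw) -> ExperimentResult:
    from .bifurcation import enzyme_sensitivity
    cfg = config or build_config("PFKL", "PKM2", 10.0)
    frames = [enzyme_sensitivity(cfg, e, seed=seed) for e in enzymes]
    table = pd.concat(frames, ignore_index=True)
    widths = {}
    for e in enzymes:
        sub = table[(table.enzyme == e) & table.bistable]
        widths[e] = (float(np.log10(sub.level.max() / sub.level.min()))
                     if len(sub) >= 2 else 0.0)
    return ExperimentResult("figS3", cfg.digest(), {"sensitivity": table},
                            {"bistable_decades": widths})


def _figS4(config: ModelConfig | None, seed: int = 0, **kw) -> ExperimentResult:
    from .bifurcation import environment_sensitivity
    cfg = config or build_config("PFKL", "PKM2", 10.0)
    nad = environment_sensitivity(cfg, "NAD_NADH",
                                  (0.5, 1.0, 9.0, 10.0, 100.0, 700.0),
                                  seed=seed)
    lac = environment_sensitivity(cfg, "LAC", (0.5, 1.8, 5.0, 20.0, 40.0),
                                  seed=seed)
    ala = environment_sensitivity(cfg, "ALA", (0.1, 0.5, 2.0, 8.0, 20.0),
                                  seed=seed)
    return ExperimentResult(
        "figS4", cfg.digest(),
        {"nad_nadh": nad, "lactate": lac, "alanine": ala},
        {"nad_nadh": nad.to_dict("records"),
         "lactate_invariant": bool(lac.switch_up.nunique() <= 1),
         "alanine_switch_up": ala.switch_up.tolist()})


def _figS5(config: ModelConfig | None, seed: int = 0, **kw) -> ExperimentResult:
    res = isozyme_mixture_scan(seed=seed)
    return res


def _fig4(config: ModelConfig | None, levels=(1.0, 0.5, 0.2, 0.1),
          base_glucose: float = 5.0, seed: int = 0, **kw) -> ExperimentResult:
    cfg = config or build_config("PFKL", "PKM2", 10.0)
    # steady-state superposition across PFKFB levels
    sup_rows = []
    for level in levels:
        c = cfg.with_levels(PFKFB=level)
        for s in find_steady_states(base_glucose, c, n_starts=40, seed=seed,
                                    method="reduction"):
            sup_rows.append({"pfkfb_level": level, "flux": s.flux,
                             "stability": s.stability})
    pulse_rows = []
    for level in levels:
        out = pulse_protocol(cfg, pfkfb_level=level, base_glucose=base_glucose,
                             seed=seed)
        pulse_rows.append({"pfkfb_level": level, "switched": out.switched,
                           "settle_time_h": out.settle_time,
                           "final_flux": out.final_flux,
                           "pulse_glucose": out.pulse_glucose})
    sup = pd.DataFrame(sup_rows)
    pulse = pd.DataFrame(pulse_rows)
    return ExperimentResult(
        "fig4", cfg.digest(), {"steady_states": sup, "pulse": pulse},
        {"switched_levels": pulse[pulse.switched].pfkfb_level.tolist(),
         "returned_levels": pulse[~pulse.switched].pfkfb_level.tolist()})


def _figS7(config: ModelConfig | None, seed: int = 0, **kw) -> ExperimentResult:
    cfg = config or hela_like_config()
    grid = np.concatenate([np.arange(0.25, 6.0, 0.25),
                           np.arange(6.0, 26.0, 1.0)])
    diagram = scan(cfg, "glucose", grid, seed=seed, detect_switches=False)
    table = delta_L_over_delta_G(diagram)
    stable = table[table.stability == "stable"]
    lo = stable[stable.branch == "low"].ratio.mean()
    hi = stable[stable.branch == "high"].ratio.mean()
    return ExperimentResult("figS7", cfg.digest(), {"ratio": table},
                            {"mean_ratio_low_branch": None if np.isnan(lo) else float(lo),
                             "mean_ratio_high_branch": None if np.isnan(hi) else float(hi)})


def _fig3(config: ModelConfig | None, seed: int = 0, **kw) -> ExperimentResult:
    cfg = config or hela_like_config()
    table = hela_hysteresis_insilico(cfg)
    piv = table.pivot(index="test_glucose", columns="history",
                      values="glucose_uptake_specific")
    dependent = {float(g): bool(abs(piv.loc[g, "HG"] - piv.loc[g, "LG"])
                                > 0.2 * max(piv.loc[g, "HG"], piv.loc[g, "LG"]))
                 for g in piv.index}
    return ExperimentResult("fig3", cfg.digest(), {"fluxes": table},
                            {"history_dependent": dependent})


_REGISTRY = {
    "fig1b": _fig1b, "fig1d": _fig1d, "figS1": _figS1,
    "fig2a": lambda config=None, **kw: _fig2("fig2a", config, **kw),
    "fig2b": lambda config=None, **kw: _fig2("fig2b", config, **kw),
    "fig2c": lambda config=None, **kw: _fig2("fig2c", config, **kw),
    "fig2d": lambda config=None, **kw: _fig2("fig2d", config, **kw),
    "fig2e": _fig2e, "figS2": _figS2, "figS3": _figS3, "figS4": _figS4,
    "figS5": _figS5, "fig4": _fig4, "fig3": _fig3, "figS7": _figS7,
}


def experiment_ids() -> list[str]:
    return sorted(_REGISTRY)


def reproduce(experiment_id: str, config: ModelConfig | None = None,
              **overrides) -> ExperimentResult:
    """Run one registered figure-level analysis end-to-end."""
    if experiment_id not in _REGISTRY:
        raise ConfigurationError(
            f"unknown experiment {experiment_id!r}; valid: {experiment_ids()}")
    return _REGISTRY[experiment_id](config=config, **overrides)


# ---------------------------------------------------------------------------
# cultured-cell hysteresis protocol and derived quantities
# ---------------------------------------------------------------------------

def hela_hysteresis_insilico(config: ModelConfig | None = None,
                             preconditioning: dict | None = None,
                             test_glucose=(0.6, 2.0, 3.0, 4.5, 25.0),
                             precondition_h: float = 12.0,
                             assay_h: float = 6.0,
                             seed: int = 0) -> pd.DataFrame:
    """History-dependence protocol: precondition at low/high glucose, then
    assay glucose-uptake and lactate fluxes at test concentrations.

    Cells start from the high-glucose steady state (the culture they came
    from), are held ``precondition_h`` hours at the LG or HG glucose, then
    ``assay_h`` hours at each test concentration; the reported rates are the
    quasi-steady fluxes at the end of the assay window, converted to
    mmol/1e9 cells/h.
    """
    cfg = config or hela_like_config()
    pre = {"LG": 0.6, "HG": 25.0}
    if preconditioning:
        pre.update(preconditioning)
    sols_hg = find_steady_states(pre["HG"], cfg, n_starts=40, seed=seed,
                                 method="reduction")
    stable_hg = [s for s in sols_hg if s.stable]
    if not stable_hg:
        raise ProtocolError("no stable state at the HG preconditioning glucose")
    origin = stable_hg[-1].state

    # verify the window brackets the intermediate test concentrations
    mids = [g for g in test_glucose if pre["LG"] < g < pre["HG"]]
    for g in mids:
        stable = [s for s in find_steady_states(float(g), cfg, n_starts=40,
                                                seed=seed, method="reduction")
                  if s.stable]
        if len(stable) < 2:
            raise ProtocolError(
                f"HeLa-like config is not bistable at {g} mM glucose; "
                "the protocol requires switch_down < 2 and switch_up > 4.5")

    rows = []
    for history, pre_glc in pre.items():
        settled = integrate(cfg, float(pre_glc), origin,
                            t_end=precondition_h).terminal_state
        for g in test_glucose:
            traj = integrate(cfg, float(g), settled, t_end=assay_h)
            end_cfg = cfg.with_env(GLC_EXT=float(g))
            v = fluxes(traj.terminal_state, end_cfg.env, end_cfg)
            rows.append({
                "history": history, "test_glucose": float(g),
                "glucose_uptake_mm_h": v["GLUT"],
                "lactate_flux_mm_h": v["LDH"],
                "glucose_uptake_specific": flux_to_specific(v["GLUT"]),
                "lactate_specific": flux_to_specific(v["LDH"]),
            })
    return pd.DataFrame(rows)


def isozyme_mixture_scan(pfk_fraction_grids=None, pk: str = "PKM2",
                         kp_ratio: float = 10.0, seed: int = 0
                         ) -> ExperimentResult:
    """Bistability of PFK isoform mixtures (fractions on a simplex grid)."""
    if pfk_fraction_grids is None:
        pfk_fraction_grids = [
            {"PFKM": 1.0}, {"PFKL": 1.0}, {"PFKP": 1.0},
            {"PFKM": 0.7, "PFKP": 0.3}, {"PFKL": 0.7, "PFKP": 0.3},
            {"PFKM": 0.5, "PFKL": 0.5}, {"PFKL": 0.3, "PFKP": 0.7},
        ]
    grid = np.concatenate([np.arange(0.5, 6.0, 0.5), np.arange(6.0, 26.0, 2.0)])
    rows = []
    digest = None
    for fractions in pfk_fraction_grids:
        cfg = build_config(dict(fractions), pk, kp_ratio)
        digest = digest or cfg.digest()
        up, down = switch_points(cfg, "glucose", grid, seed=seed)
        rows.append({"fractions": str(sorted(fractions.items())),
                     "bistable": up is not None,
                     "switch_up_glucose_mm": up,
                     "switch_down_glucose_mm": down})
    table = pd.DataFrame(rows)
    return ExperimentResult("figS5", digest or "", {"mixtures": table},
                            {"rows": table.to_dict("records")})


def delta_L_over_delta_G(diagram) -> pd.DataFrame:
    """Lactate-production to glucose-uptake flux ratio per steady state.

    Bounded by 2 (two lactate per glucose); the high-flux branch diverts a
    larger share of pyruvate to lactate than the low-flux branch.
    """
    from .bifurcation import apply_parameter
    base = diagram.config or hela_like_config()
    rows = []
    for value, sols, labels in zip(diagram.grid, diagram.points,
                                   diagram.branch_labels):
        cfg, _ = apply_parameter(base, diagram.parameter, float(value))
        for sol, lab in zip(sols, labels):
            v = fluxes(sol.state, cfg.env, cfg)
            ratio = v["LDH"] / v["GLUT"] if v["GLUT"] > 0 else np.nan
            rows.append({diagram.parameter: value, "flux": sol.flux,
                         "stability": sol.stability, "branch": lab,
                         "lactate_flux": v["LDH"], "glucose_flux": v["GLUT"],
                         "ratio": ratio})
    return pd.DataFrame(rows)
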