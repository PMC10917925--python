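"""Numerical integration of stimulus protocols and observable extraction.

``simulate`` runs a stiff implicit integration (BDF with an analytic
Jacobian sparsity pattern) of a model under a :class:`StimulusProtocol`:
an optional normoxic pre-equilibration, the t = 0 stimulus (VEGF boluses,
O₂ step, DAPT scaling of γ-secretase cleavage), and any mid-run set-value
events.  Results come back as a :class:`TrajectorySet` with time in hours,
the full state matrix, and the named observables; ``ecpi_timecourse`` turns
a trajectory into per-cell ECPI series and an explicit tip/stalk/
undifferentiated pattern call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ecmodel import ECPI_COMPONENTS
from .network import CompiledNetwork, ModelDefinition, assemble_rhs
from .protocols import StimulusProtocol, dapt_scale

HOUR_S = 3600.0

#: Default solver settings: stiff method, tight tolerances for the fast
#: Ca²⁺ transients living alongside multi-hour HIF dynamics.
DEFAULT_SOLVER = {"method": "BDF", "rtol": 1e-8, "atol": 1e-12}

#: Pattern call: final quartile of the window, 5% relative separation.
PATTERN_WINDOW_FRACTION = 0.25
PATTERN_THRESHOLD = 0.05


class IntegrationFailure(RuntimeError):
    """The stiff solver failed; carries the most extreme state for diagnosis."""


class DegenerateNormalizationError(ValueError):
    """Max-normalization of an all-zero (or empty) series."""


@dataclass
class TrajectorySet:
    """Solved time courses: states (µM) and derived observables vs hours."""

    time_h: np.ndarray
    states: pd.DataFrame
    observables: pd.DataFrame
    solver_stats: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        if name in self.observables.columns:
            return self.observables[name].to_numpy()
        return self.states[name].to_numpy()


def default_time_grid(duration_h: float) -> np.ndarray:
    """1-minute resolution up to 2 h protocols, 5-minute beyond."""
    step_h = (1.0 if duration_h <= 2.0 else 5.0) / 60.0
    n = int(round(duration_h / step_h))
    return np.linspace(0.0, duration_h, n + 1)


def _eval_observables(model: ModelDefinition, states: pd.DataFrame) -> pd.DataFrame:
    ns = {c: states[c].to_numpy() for c in states.columns}
    ns.update({"exp": np.exp, "log": np.log, "sqrt": np.sqrt, "abs": np.abs,
               "minimum": np.minimum, "maximum": np.maximum, "where": np.where})
    out = {}
    for name, expr in model.observables.items():
        out[name] = eval(expr, {"__builtins__": {}}, ns)  # noqa: S307 - validated exprs
    return pd.DataFrame(out, index=states.index)


def _integrate(rhs: CompiledNetwork, y0, p, t_span_s, t_eval_s, options) -> tuple:
    opts = dict(DEFAULT_SOLVER)
    opts.update(options or {})
    method = opts.pop("method")
    kwargs = {}
    if method in ("BDF", "Radau", "LSODA"):
        kwargs["jac_sparsity"] = rhs.jac_sparsity
    if method == "LSODA":
        kwargs.pop("jac_sparsity")
    sol = solve_ivp(rhs, t_span_s, y0, t_eval=t_eval_s, args=(p,),
                    method=method, dense_output=False, **opts, **kwargs)
    if not sol.success:
        names = [s.name for s in rhs.model.species]
        y_last = sol.y[:, -1] if sol.y.size else y0
        worst = names[int(np.argmax(np.abs(y_last)))]
        raise IntegrationFailure(
            f"integration failed at t={sol.t[-1] if sol.t.size else t_span_s[0]:.1f}s: "
            f"{sol.message}; largest-magnitude species: {worst}")
    return sol.y, {"nfev": sol.nfev, "njev": sol.njev, "nlu": sol.nlu}


def simulate(model: ModelDefinition, protocol: StimulusProtocol,
             t_grid: np.ndarray | None = None,
             solver_options: dict | None = None,
             rhs: CompiledNetwork | None = None,
             parameter_overrides: dict[str, float] | None = None,
             initial_species_overrides: dict[str, float] | None = None) -> TrajectorySet:
    """Integrate ``model`` under ``protocol`` and return all time courses.

    ``t_grid`` is in hours within [0, protocol.duration]; defaults to the
    resolution rule in :func:`default_time_grid`.  A prebuilt compiled RHS
    can be passed to amortise compilation across many runs (sensitivity,
    fitting); ``parameter_overrides`` apply on top of the registry without
    touching the model.
    """
    if t_grid is None:
        t_grid = default_time_grid(protocol.duration)
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if t_grid[0] < 0 or t_grid[-1] > protocol.duration + 1e-9:
        raise ValueError("t_grid must lie within [0, protocol.duration]")

    rhs = rhs or assemble_rhs(model)
    overrides = dict(parameter_overrides or {})
    sidx = model.species_index()
    stats_total = {"nfev": 0, "njev": 0, "nlu": 0}

    def has(name: str) -> bool:
        return name in model.parameters

    # --- pre-equilibration: normoxia, no exogenous VEGF --------------------
    eq_over = dict(overrides)
    if has("Vext1"):
        eq_over["Vext1"] = 0.0
        eq_over["Vext2"] = 0.0
    p_eq = model.parameter_vector(eq_over)
    y0 = model.initial_state(eq_over, species_overrides=initial_species_overrides)
    if protocol.pre_equilibrate_h > 0:
        T = protocol.pre_equilibrate_h * HOUR_S
        y_eq, st = _integrate(rhs, y0, p_eq, (0.0, T), np.array([0.0, T]),
                              solver_options)
        y0 = y_eq[:, -1]
        for k in stats_total:
            stats_total[k] += st[k]

    # --- stimulus onset ----------------------------------------------------
    stim_over = dict(overrides)
    if has("Vext1"):
        stim_over.setdefault("Vext1", protocol.vegf_cell1)
        stim_over.setdefault("Vext2", protocol.vegf_cell2)
    if has("O2"):
        stim_over.setdefault("O2", protocol.o2)
    if protocol.dapt > 0 and has("kcleave"):
        base = stim_over.get("kcleave", model.parameters["kcleave"].value)
        stim_over["kcleave"] = base * dapt_scale(protocol.dapt,
                                                 model.parameters["Ki_DAPT"].value)
    p = model.parameter_vector(stim_over)
    # constant environment species follow their bound parameters
    for i, sp in enumerate(model.species):
        if sp.initial_from_param is not None:
            y0 = y0.copy()
            y0[i] = p[model.parameter_index()[sp.initial_from_param]]

    # --- piecewise integration across events -------------------------------
    events = sorted(protocol.events, key=lambda e: e[0])
    breakpoints = [0.0] + [t for t, _, _ in events] + [protocol.duration]
    ys = []
    y = y0
    ei = 0
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        if b > a:
            mask = (t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)
            t_eval = np.unique(np.concatenate([[a], t_grid[mask], [b]])) * HOUR_S
            Y, st = _integrate(rhs, y, p, (a * HOUR_S, b * HOUR_S), t_eval,
                               solver_options)
            for k in stats_total:
                stats_total[k] += st[k]
            sel = np.isin(np.round(t_eval / HOUR_S, 10), np.round(t_grid[mask], 10))
            ys.append((t_grid[mask], Y[:, sel]))
            y = Y[:, -1].copy()
        while ei < len(events) and abs(events[ei][0] - b) < 1e-12:
            _, sp_name, val = events[ei]
            y = y.copy()
            y[sidx[sp_name]] = val
            ei += 1

    t_all = np.concatenate([t for t, _ in ys])
    Y_all = np.concatenate([Y for _, Y in ys], axis=1)
    # at event times keep the post-event row (last occurrence)
    t_rounded = np.round(t_all, 10)
    t_out, rev_idx = np.unique(t_rounded[::-1], return_index=True)
    keep = len(t_rounded) - 1 - rev_idx
    states = pd.DataFrame(Y_all[:, keep].T, index=t_out,
                          columns=[s.name for s in model.species])
    obs = _eval_observables(model, states)
    stats_total["n_negative_clamped"] = rhs.n_negative_clamped
    return TrajectorySet(time_h=t_out, states=states, observables=obs,
                         solver_stats=stats_total)


def normalize_to_max(series) -> np.ndarray:
    """Divide a series by its maximum over the window (max maps to 1)."""
    x = np.asarray(series, float)
    if x.size == 0:
        raise DegenerateNormalizationError("empty series")
    m = np.max(x)
    if m <= 0:
        raise DegenerateNormalizationError("series maximum is not positive")
    return x / m


@dataclass
class EcpiReport:
    """Per-cell ECPI series, window means, and the pattern call."""

    time_h: np.ndarray
    ecpi_c1: np.ndarray
    ecpi_c2: np.ndarray
    mean_c1: float
    mean_c2: float
    separation: float  # relative |mean_c1 - mean_c2| / mean of means
    calls: dict[str, str]


def ecpi_timecourse(traj: TrajectorySet,
                    window_fraction: float = PATTERN_WINDOW_FRACTION,
                    threshold: float = PATTERN_THRESHOLD) -> EcpiReport:
    """ECPI series per cell plus the tip/stalk/undifferentiated call.

    The call averages each cell's ECPI over the final ``window_fraction`` of
    the simulation: the lower cell is "tip", the higher "stalk", and both
    are "undifferentiated" when they differ by less than ``threshold``
    (relative).  A zero Dll4·VEGFR2 anywhere in the window raises
    :class:`~tipstalk.ecmodel.UndefinedIndexError`.
    """
    from .ecmodel import UndefinedIndexError

    t = traj.time_h
    series = {}
    for cell, comp in ECPI_COMPONENTS.items():
        num = traj.series(comp["hes1"]) * traj.series(comp["vegfr1"])
        den = traj.series(comp["dll4"]) * traj.series(comp["vegfr2"])
        series[cell] = (num, den)
    t_lo = t[-1] - window_fraction * (t[-1] - t[0])
    win = t >= t_lo - 1e-12
    means = {}
    full = {}
    for cell, (num, den) in series.items():
        if np.any(den[win] <= 0):
            raise UndefinedIndexError(
                f"ECPI undefined for {cell}: Dll4*VEGFR2 vanishes in the call window")
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        full[cell] = e
        means[cell] = float(np.mean(e[win]))
    m1, m2 = means["c1"], means["c2"]
    sep = abs(m1 - m2) / (0.5 * (m1 + m2))
    if sep < threshold:
        calls = {"c1": "undifferentiated", "c2": "undifferentiated"}
    elif m1 < m2:
        calls = {"c1": "tip", "c2": "stalk"}
    else:
        calls = {"c1": "stalk", "c2": "tip"}
    return EcpiReport(time_h=t, ecpi_c1=full["c1"], ecpi_c2=full["c2"],
                      mean_c1=m1, mean_c2=m2, separation=sep, calls=calls)


def dll4_titration_experiment(model: ModelDefinition,
                              dll4_levels_cell2=(0.0, 2.0, 20.0),
                              vegf: float = 0.0012,
                              duration_h: float = 2.0,
                              solver_options: dict | None = None,
                              rhs: CompiledNetwork | None = None) -> dict[float, TrajectorySet]:
    """Equal VEGF on both cells; titrate the second cell's initial Dll4.

    Raising Dll4 in cell 2 activates Notch in cell 1 (stalk shift), limiting
    its free VEGFR2 and hence its downstream Ca²⁺/NO response.
    """
    out = {}
    rhs = rhs or assemble_rhs(model)
    sidx = model.species_index()
    for level in dll4_levels_cell2:
        if level < 0:
            raise ValueError("Dll4 level must be non-negative")
        proto = StimulusProtocol(vegf_cell1=vegf, vegf_cell2=vegf,
                                 duration=duration_h,
                                 events=[(0.0, "Dll4_c2", float(level))])
        out[float(level)] = simulate(model, proto, solver_options=solver_options,
                                     rhs=rhs)
    return out
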