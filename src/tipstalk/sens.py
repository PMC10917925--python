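"""Global (PRCC over Latin-hypercube samples) and local sensitivity analysis,
plus the practical-identifiability screens.

PRCC — the partial rank correlation coefficient — is the correlation between
the residuals of rank-transformed input x_j and rank-transformed output y
after each has been regressed on all other ranked inputs; significance comes
from the usual t-approximation.  The global analysis varies parameters
within a factor-1.5 band around their nominal values and scores the ECPI of
each cell at 1 h and 12 h under normoxia/hypoxia stimulation conditions.

The identifiability screens implement the pragmatic pre-fit reduction:
parameters with negligible influence (|PRCC| ≤ 0.2 and p ≥ 0.05 everywhere)
are set aside, and antagonistic parameter pairs acting on a single process
(forward/reverse of one binding, phosphorylation/dephosphorylation of one
target) are collapsed to the forward member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .ecmodel import ECPI_COMPONENTS
from .network import ModelDefinition, assemble_rhs
from .protocols import StimulusProtocol
from .sim import simulate

PRCC_CUT = 0.2
P_CUT = 0.05
GSA_FACTOR = 1.5

#: Stimulation conditions for the ECPI sensitivity analysis.
GSA_CONDITIONS = {
    "normoxia-equal": dict(vegf_cell1=0.0012, vegf_cell2=0.0012, o2=209.0),
    "normoxia-differential": dict(vegf_cell1=0.0012, vegf_cell2=0.0006, o2=209.0),
    "hypoxia-differential": dict(vegf_cell1=0.0012, vegf_cell2=0.0006, o2=9.95),
}


class DegenerateSamplingError(ValueError):
    """LHS bounds with lower >= upper, or too few samples."""


class SimulationFailureRate(RuntimeError):
    """More than the tolerated fraction of GSA samples failed to integrate."""


@dataclass
class SensitivityResult:
    """PRCC and p per (parameter, output, timepoint, condition)."""

    table: pd.DataFrame  # columns: parameter, output, timepoint, condition, prcc, p
    n: int
    seed: int | None
    factor: float = GSA_FACTOR
    dropped: int = 0
    meta: dict = field(default_factory=dict)

    def parameters(self) -> list[str]:
        return list(dict.fromkeys(self.table["parameter"]))

    def max_abs_prcc(self, parameter: str) -> float:
        sub = self.table[self.table["parameter"] == parameter]
        return float(np.nanmax(np.abs(sub["prcc"].to_numpy()))) if len(sub) else np.nan


def lhs_sample(bounds, n: int, seed: int | None = None) -> np.ndarray:
    """n × k Latin-hypercube sample: one point per equal-probability stratum
    and dimension, reproducible for a given seed."""
    b = np.atleast_2d(np.asarray(bounds, float))
    if n < 2:
        raise DegenerateSamplingError("need at least 2 samples")
    if np.any(b[:, 0] >= b[:, 1]):
        raise DegenerateSamplingError("each dimension needs lower < upper")
    sampler = qmc.LatinHypercube(d=b.shape[0], seed=seed)
    return qmc.scale(sampler.random(n), b[:, 0], b[:, 1])


def prcc(X, y, return_frame: bool = False):
    """Partial rank correlation of each input column against the output.

    Returns ``(coefficients, p_values)`` arrays aligned with the columns of
    ``X``.  A column that is (rank-)collinear with the others — e.g. a
    duplicated input — gets NaN rather than a silently wrong number, as does
    a constant output.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, k = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on the number of samples")
    if n < k + 3:
        raise ValueError("need at least k + 3 samples for PRCC")
    coeffs = np.full(k, np.nan)
    pvals = np.full(k, np.nan)
    if np.ptp(y) == 0:
        return (coeffs, pvals)
    rX = np.column_stack([stats.rankdata(X[:, j]) for j in range(k)])
    ry = stats.rankdata(y)
    df = n - k - 1  # residual dof after controlling the k-1 other inputs
    for j in range(k):
        others = np.delete(rX, j, axis=1)
        Z = np.column_stack([np.ones(n), others])
        bx, *_ = np.linalg.lstsq(Z, rX[:, j], rcond=None)
        by, *_ = np.linalg.lstsq(Z, ry, rcond=None)
        ex = rX[:, j] - Z @ bx
        ey = ry - Z @ by
        # duplicated/collinear column: no residual variance left to correlate
        if np.std(ex) < 1e-10 * max(np.std(rX[:, j]), 1.0) or np.std(ey) == 0:
            continue
        r = float(np.corrcoef(ex, ey)[0, 1])
        r = max(-1.0, min(1.0, r))
        coeffs[j] = r
        if abs(r) >= 1.0:
            pvals[j] = 0.0
        else:
            t = r * math.sqrt(df / (1.0 - r * r))
            pvals[j] = 2.0 * stats.t.sf(abs(t), df)
    return (coeffs, pvals)


def _ecpi_at(traj, cell: str, t_h: float) -> float:
    i = int(np.argmin(np.abs(traj.time_h - t_h)))
    comp = ECPI_COMPONENTS[cell]
    num = traj.series(comp["hes1"])[i] * traj.series(comp["vegfr1"])[i]
    den = traj.series(comp["dll4"])[i] * traj.series(comp["vegfr2"])[i]
    return num / den if den > 0 else np.nan


def gsa_ecpi(model: ModelDefinition,
             conditions=("normoxia-differential",),
             parameters: list[str] | None = None,
             timepoints=(1.0, 12.0),
             factor: float = GSA_FACTOR,
             n: int = 500,
             seed: int | None = None,
             solver_options: dict | None = None,
             pre_equilibrate_h: float = 24.0,
             max_failure_fraction: float = 0.1) -> SensitivityResult:
    """PRCC of each cell's ECPI at the given timepoints to parameter variation.

    Bounds are value/factor .. value·factor around the registry values
    (factor 1.5 by default).  Samples whose integration fails are dropped;
    more than ``max_failure_fraction`` failures aborts the analysis.
    """
    for c in conditions:
        if c not in GSA_CONDITIONS:
            raise ValueError(f"unknown condition {c!r}; valid: {sorted(GSA_CONDITIONS)}")
    if parameters is None:
        parameters = [p.name for p in model.parameters.values() if p.status == "fittable"]
    base = {p: model.parameters[p].value for p in parameters}
    bounds = np.array([[v / factor, v * factor] for v in base.values()])
    X = lhs_sample(bounds, n, seed)
    rhs = assemble_rhs(model)
    duration = max(timepoints)
    t_grid = np.unique(np.concatenate([[0.0], np.asarray(timepoints, float),
                                       np.linspace(0, duration, 25)]))
    rows = []
    dropped = 0
    for cond in conditions:
        proto = StimulusProtocol(duration=duration,
                                 pre_equilibrate_h=pre_equilibrate_h,
                                 **GSA_CONDITIONS[cond])
        outputs: dict[tuple, list] = {(c, t): [] for c in ("c1", "c2") for t in timepoints}
        ok_rows = []
        for i in range(n):
            overrides = dict(zip(base, X[i]))
            try:
                traj = simulate(model, proto, t_grid=t_grid, rhs=rhs,
                                solver_options=solver_options,
                                parameter_overrides=overrides)
            except Exception:
                dropped += 1
                continue
            ok_rows.append(i)
            for cell in ("c1", "c2"):
                for t in timepoints:
                    outputs[(cell, t)].append(_ecpi_at(traj, cell, t))
        if n - len(ok_rows) > max_failure_fraction * n:
            raise SimulationFailureRate(
                f"{n - len(ok_rows)}/{n} samples failed under {cond!r}")
        Xok = X[ok_rows]
        for (cell, t), ys in outputs.items():
            co, pv = prcc(Xok, np.asarray(ys))
            for j, pname in enumerate(base):
                rows.append((pname, f"ECPI_{cell}", t, cond, co[j], pv[j]))
    table = pd.DataFrame(rows, columns=["parameter", "output", "timepoint",
                                        "condition", "prcc", "p"])
    return SensitivityResult(table=table, n=n, seed=seed, factor=factor,
                             dropped=dropped,
                             meta={"parameters": parameters, "conditions": list(conditions)})


def local_sensitivity(model: ModelDefinition,
                      targets=("Hes1_c1", "Hes1_c2"),
                      inputs=("R2", "R1"),
                      horizons=(2.0, 48.0),
                      conditions=("normoxia-differential",),
                      fraction: float = 0.01,
                      solver_options: dict | None = None) -> pd.DataFrame:
    """Normalised central-difference sensitivities d ln(target)/d ln(input₀).

    ``inputs`` are per-cell species base names whose *initial* values are
    perturbed (both suffixed copies, one cell at a time); the simulations
    start from the assigned initial state without pre-equilibration, since
    the receptor initials are the quantity under study.
    """
    if fraction <= 0:
        raise ValueError("perturbation fraction must be positive")
    if max(horizons) <= 0:
        raise ValueError("horizons must be positive")
    rhs = assemble_rhs(model)
    duration = float(max(horizons))
    rows = []
    sidx = model.species_index()
    y_base = {s.name: s.initial_value for s in model.species}
    for cond in conditions:
        if cond not in GSA_CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        proto = StimulusProtocol(duration=duration, pre_equilibrate_h=0.0,
                                 **GSA_CONDITIONS[cond])
        t_grid = np.unique(np.concatenate([[0.0], np.asarray(horizons, float),
                                           np.linspace(0, duration, 25)]))
        for base in inputs:
            for cell in ("c1", "c2"):
                sp = f"{base}_{cell}"
                if sp not in sidx:
                    raise KeyError(f"unknown input species {sp!r}")
                v0 = y_base[sp]
                vals = {}
                for sign in (+1, -1):
                    traj = simulate(model, proto, t_grid=t_grid, rhs=rhs,
                                    solver_options=solver_options,
                                    initial_species_overrides={sp: v0 * (1 + sign * fraction)})
                    vals[sign] = traj
                for tgt in targets:
                    for h in horizons:
                        i = int(np.argmin(np.abs(vals[1].time_h - h)))
                        up = vals[1].series(tgt)[i]
                        dn = vals[-1].series(tgt)[i]
                        mid = 0.5 * (up + dn)
                        sens = ((up - dn) / (2 * fraction * mid)) if mid > 0 else np.nan
                        rows.append((cond, sp, tgt, h, sens))
    return pd.DataFrame(rows, columns=["condition", "input", "target",
                                       "horizon_h", "sensitivity"])


def influence_screen(result: SensitivityResult,
                     prcc_cut: float = PRCC_CUT,
                     p_cut: float = P_CUT) -> list[str]:
    """Parameters influential on at least one output: |PRCC| > cut or p < cut."""
    keep = []
    for pname in result.parameters():
        sub = result.table[result.table["parameter"] == pname]
        pr = np.abs(sub["prcc"].to_numpy(float))
        pv = sub["p"].to_numpy(float)
        if np.any((pr > prcc_cut) & ~np.isnan(pr)) or np.any((pv < p_cut) & ~np.isnan(pv)):
            keep.append(pname)
    return keep


def _rate_parameter(reaction) -> str | None:
    return reaction.law_params.get("k") or reaction.law_params.get("vmax")


def collinearity_screen(model: ModelDefinition, params: list[str],
                        fraction: float = 0.01) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop the reverse member of antagonistic parameter pairs.

    A pair is antagonistic when two reactions are exact reverses of each
    other (reactants(r1) == products(r2) and vice versa — reversible
    bindings, phosphorylation/dephosphorylation cycles) and the two rate
    parameters have opposite-signed finite-difference effects on the pair's
    net flux.  The forward (first-registered) member is retained.
    """
    model.validate()
    rhs = assemble_rhs(model)
    y0 = model.initial_state()
    # positive reference state: zero initials get a nominal small concentration
    y_ref = np.where(y0 > 0, y0, 1e-2)
    p0 = model.parameter_vector()
    pidx = model.parameter_index()

    def key(pairs):
        return tuple(sorted(pairs))

    removed: list[tuple[str, str]] = []
    removed_names: set[str] = set()
    seen: set[int] = set()
    for i, r1 in enumerate(model.reactions):
        for j in range(i + 1, len(model.reactions)):
            r2 = model.reactions[j]
            if j in seen or i in seen:
                continue
            if key(r1.reactants) == key(r2.products) and key(r1.products) == key(r2.reactants) \
                    and r1.reactants and r1.products:
                pf, pr = _rate_parameter(r1), _rate_parameter(r2)
                if pf is None or pr is None or pf not in params or pr not in params:
                    continue
                # numeric confirmation: opposite-signed effect on the net flux
                def net(pvec):
                    f = rhs.flux(0.0, y_ref, pvec)
                    return f[i] - f[j]
                d = {}
                for pn in (pf, pr):
                    up, dn = p0.copy(), p0.copy()
                    up[pidx[pn]] *= 1 + fraction
                    dn[pidx[pn]] *= 1 - fraction
                    d[pn] = net(up) - net(dn)
                if d[pf] * d[pr] < 0:
                    removed.append((pf, pr))
                    removed_names.add(pr)
                    seen.update((i, j))
    kept = [p for p in params if p not in removed_names]
    return kept, removed


def classify_parameter_groups(model: ModelDefinition,
                              sens_vegf: SensitivityResult,
                              sens_hypoxia: SensitivityResult,
                              parameters: list[str] | None = None) -> dict[str, list[str]]:
    """Partition fittable parameters into the VEGF-stage and hypoxia-stage
    groups by which condition's observables they influence most (max |PRCC|);
    ties go to the VEGF group, which is fitted first."""
    if parameters is None:
        parameters = [p.name for p in model.parameters.values() if p.status == "fittable"]
    groups: dict[str, list[str]] = {"vegf": [], "hypoxia": []}
    pv = set(sens_vegf.parameters())
    ph = set(sens_hypoxia.parameters())
    for pname in parameters:
        if pname not in pv and pname not in ph:
            raise KeyError(f"parameter {pname!r} absent from both sensitivity results")
        a = sens_vegf.max_abs_prcc(pname) if pname in pv else np.nan
        b = sens_hypoxia.max_abs_prcc(pname) if pname in ph else np.nan
        a = -np.inf if np.isnan(a) else a
        b = -np.inf if np.isnan(b) else b
        groups["hypoxia" if b > a else "vegf"].append(pname)
    return groups
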