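"""Staged particle-swarm calibration against max-normalized time courses,
runs-test goodness of fit, and bootstrap uncertainty quantification.

Calibration data are semi-quantitative (Western-blot style) time courses,
so both data and simulations are normalized to their maximum over the
shared window before residuals are formed.  Fitting proceeds in two stages:
the VEGF-stimulation parameter group is fitted first against the
VEGF/normoxia datasets, the hypoxia group second against the hypoxia
datasets with stage-1 results frozen — the staging that makes a large model
affordable to fit.  Goodness of fit uses the Wald-Wolfowitz runs test on
time-ordered residuals per observable; uncertainty comes from
case-resampling bootstrap with percentile prediction bands.

All optimisation routines work on an abstract predictor::

    predictor(params: dict, observable: str, condition: str, times_h) -> values

so toy analytic models, fixture networks, and the full two-cell model all
share one calibration path (``make_model_predictor`` adapts an ODE model).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .network import ModelDefinition, assemble_rhs
from .protocols import StimulusProtocol
from .sim import normalize_to_max, simulate

logger = logging.getLogger(__name__)

PENALTY = 1e6  # objective value for failed simulations; finite to keep PSO alive

DATASET_COLUMNS = ("time_h", "observable", "value", "condition", "source", "weight")


class DatasetError(ValueError):
    """Malformed experimental dataset."""


class DegenerateResidualError(ValueError):
    """Runs test on residuals that never change sign about their mean."""


@dataclass
class ExperimentalDataset:
    """Max-normalized time-course records.

    Columns: time_h, observable, value (in [0, 1]), condition, source,
    weight.  Each (observable, condition, source) group is one digitized
    experiment; the default weighting gives every such group equal total
    weight regardless of how many points it contributes.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise DatasetError(f"dataset missing columns {sorted(missing)}")
        if len(df) == 0:
            raise DatasetError("empty dataset")
        if (df["time_h"] < 0).any():
            raise DatasetError("negative times")
        if ((df["value"] < 0) | (df["value"] > 1 + 1e-12)).any():
            raise DatasetError("values must be max-normalized into [0, 1]")
        if (df["weight"] < 0).any():
            raise DatasetError("negative weights")

    @classmethod
    def from_records(cls, rows, equal_group_weights: bool = True) -> "ExperimentalDataset":
        df = pd.DataFrame(rows, columns=list(DATASET_COLUMNS[:5]))
        df["weight"] = 1.0
        ds = cls(records=df)
        if equal_group_weights:
            ds.reweight_equal_groups()
        return ds

    def reweight_equal_groups(self) -> None:
        """weight = 1 / (points in the group): each experiment counts once."""
        sizes = self.records.groupby(["observable", "condition", "source"])["value"].transform("size")
        self.records["weight"] = 1.0 / sizes

    def groups(self):
        return self.records.groupby(["observable", "condition", "source"], sort=False)

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.records["condition"]))

    def subset(self, condition_filter) -> "ExperimentalDataset":
        mask = self.records["condition"].map(condition_filter)
        if not mask.any():
            raise DatasetError("condition filter selects no records")
        return ExperimentalDataset(self.records[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ExperimentalDataset":
        return cls(pd.read_csv(path))


def make_model_predictor(model: ModelDefinition,
                         protocols: dict[str, StimulusProtocol],
                         solver_options: dict | None = None,
                         condition_overrides: dict[str, dict] | None = None):
    """Adapt an ODE model + per-condition protocols to the predictor interface.

    One simulation per (params, condition) is cached within a single
    objective evaluation sweep; observables are interpolated at the
    requested times.  The default solver here is LSODA — markedly faster
    than BDF for the small fixture networks this path is exercised with —
    at the same tight tolerances; pass ``solver_options`` to override.
    """
    rhs = assemble_rhs(model)
    if solver_options is None:
        solver_options = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-12}
    cache: dict = {}

    def predictor(params: dict, observable: str, condition: str, times_h) -> np.ndarray:
        if condition not in protocols:
            raise DatasetError(f"no protocol registered for condition {condition!r}")
        key = (tuple(sorted(params.items())), condition)
        if key not in cache:
            if len(cache) > 32:
                cache.clear()
            proto = protocols[condition]
            overrides = dict(params)
            if condition_overrides and condition in condition_overrides:
                overrides.update(condition_overrides[condition])
            traj = simulate(model, proto, rhs=rhs, solver_options=solver_options,
                            parameter_overrides=overrides)
            cache[key] = traj
        traj = cache[key]
        return np.interp(np.asarray(times_h, float), traj.time_h, traj.series(observable))

    return predictor


def weighted_ssr(predictor, params: dict, datasets) -> float:
    """Σ weight · (normalized simulation − normalized data)².

    The simulation is max-normalized over the same time window as each data
    group.  A failed simulation yields a large-but-finite penalty so the
    optimizer can continue.
    """
    if isinstance(datasets, ExperimentalDataset):
        datasets = [datasets]
    total = 0.0
    for ds in datasets:
        for (obs, cond, _src), g in ds.groups():
            w = g["weight"].to_numpy(float)
            if not w.any():
                continue
            t = g["time_h"].to_numpy(float)
            v = g["value"].to_numpy(float)
            try:
                sim = np.asarray(predictor(params, obs, cond, t), float)
                sim = normalize_to_max(sim) if np.max(sim) > 0 else sim
            except Exception as exc:  # noqa: BLE001 - penalty path by contract
                logger.warning("simulation failure during SSR (%s/%s): %s", obs, cond, exc)
                return PENALTY
            total += float(np.sum(w * (sim - v) ** 2))
    return total


# ---------------------------------------------------------------------------
# particle swarm optimization
# ---------------------------------------------------------------------------

@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    trace: np.ndarray  # best-so-far objective per iteration
    nfev: int


def pso(objective, bounds, swarm_size: int = 30, iterations: int = 300,
        seed: int | None = None, inertia: float = 0.729,
        cognitive: float = 1.49445, social: float = 1.49445,
        x0: np.ndarray | None = None) -> PSOResult:
    """Canonical global-best particle swarm minimisation.

    Every particle tracks its personal best; the swarm tracks the global
    best; velocities combine inertia, cognitive and social pulls; positions
    are clamped to the (finite) bounds.  Reproducible for a given seed.
    """
    b = np.atleast_2d(np.asarray(bounds, float))
    lo, hi = b[:, 0], b[:, 1]
    if not np.all(np.isfinite(b)):
        raise ValueError("pso requires finite bounds")
    if np.any(lo >= hi):
        raise ValueError("each dimension needs lower < upper")
    if swarm_size < 2:
        raise ValueError("swarm_size must be >= 2")
    rng = np.random.default_rng(seed)
    d = len(lo)
    X = lo + rng.random((swarm_size, d)) * (hi - lo)
    if x0 is not None:
        X[0] = np.clip(np.asarray(x0, float), lo, hi)
    V = (rng.random((swarm_size, d)) - 0.5) * (hi - lo) * 0.1
    F = np.array([objective(x) for x in X])
    nfev = swarm_size
    P, Pf = X.copy(), F.copy()
    g = int(np.argmin(Pf))
    gx, gf = P[g].copy(), float(Pf[g])
    trace = np.empty(iterations)
    for it in range(iterations):
        r1 = rng.random((swarm_size, d))
        r2 = rng.random((swarm_size, d))
        V = inertia * V + cognitive * r1 * (P - X) + social * r2 * (gx - X)
        X = np.clip(X + V, lo, hi)
        F = np.array([objective(x) for x in X])
        nfev += swarm_size
        better = F < Pf
        P[better], Pf[better] = X[better], F[better]
        g = int(np.argmin(Pf))
        if Pf[g] < gf:
            gx, gf = P[g].copy(), float(Pf[g])
        trace[it] = gf
    return PSOResult(x=gx, fun=gf, trace=trace, nfev=nfev)


# ---------------------------------------------------------------------------
# staged fitting
# ---------------------------------------------------------------------------

def default_condition_filters() -> dict:
    """Stage → predicate on the condition label: 'hypoxia...' labels feed the
    hypoxia stage, everything else (normoxia + VEGF doses) the VEGF stage."""
    return {
        "vegf": lambda c: not str(c).startswith("hypoxia"),
        "hypoxia": lambda c: str(c).startswith("hypoxia"),
    }


@dataclass
class FitResult:
    values: dict[str, float]
    objective: float
    objective_trace: np.ndarray
    bounds: dict[str, tuple[float, float]]
    residuals: pd.DataFrame  # time_h, observable, condition, source, residual
    runs_tests: pd.DataFrame  # condition, observable, h, p
    stages: list[dict] = field(default_factory=list)
    seed: int | None = None


def _residual_table(predictor, params, datasets) -> pd.DataFrame:
    if isinstance(datasets, ExperimentalDataset):
        datasets = [datasets]
    rows = []
    for ds in datasets:
        for (obs, cond, src), g in ds.groups():
            t = g["time_h"].to_numpy(float)
            v = g["value"].to_numpy(float)
            sim = np.asarray(predictor(params, obs, cond, t), float)
            if np.max(sim) > 0:
                sim = normalize_to_max(sim)
            order = np.argsort(t)
            for i in order:
                rows.append((t[i], obs, cond, src, sim[i] - v[i]))
    return pd.DataFrame(rows, columns=["time_h", "observable", "condition",
                                       "source", "residual"])


def staged_fit(predictor, datasets, groups: dict[str, list[str]],
               baseline: dict[str, float],
               bounds_decades: float = 1.0,
               seed: int | None = None,
               swarm_size: int = 30, iterations: int = 300,
               polish: bool = True,
               condition_filters: dict | None = None,
               stage_order=("vegf", "hypoxia")) -> FitResult:
    """Two-stage grouped PSO fit.

    Stage 1 fits ``groups['vegf']`` against the VEGF/normoxia-labelled
    datasets with the hypoxia group frozen at baseline; stage 2 freezes the
    stage-1 estimates and fits ``groups['hypoxia']`` against the hypoxia
    datasets.  Per-parameter bounds span ``bounds_decades`` orders of
    magnitude above and below baseline.  An optional local polish
    (Nelder-Mead on the PSO optimum) tightens each stage's endpoint.
    """
    if isinstance(datasets, ExperimentalDataset):
        datasets = [datasets]
    filters = condition_filters or default_condition_filters()
    fitted = set().union(*groups.values())
    unknown = fitted - set(baseline)
    if unknown:
        raise KeyError(f"groups reference parameters without baseline values: {sorted(unknown)}")
    current = dict(baseline)
    bounds_all = {p: (baseline[p] / 10 ** bounds_decades, baseline[p] * 10 ** bounds_decades)
                  for p in fitted}
    traces = []
    stages = []
    rng = np.random.default_rng(seed)
    for stage in stage_order:
        names = list(groups.get(stage, []))
        if not names:
            logger.warning("stage %r has no parameters; skipped", stage)
            continue
        stage_data = []
        for d in datasets:
            try:
                stage_data.append(d.subset(filters[stage]))
            except DatasetError:
                continue
        if not stage_data:
            logger.warning("stage %r has no matching datasets; skipped", stage)
            continue
        lo = np.array([bounds_all[p][0] for p in names])
        hi = np.array([bounds_all[p][1] for p in names])
        # optimise in log-space: the bounds are multiplicative
        def obj(z, _names=names, _data=stage_data):
            trial = dict(current)
            trial.update(zip(_names, np.exp(z)))
            return weighted_ssr(predictor, trial, _data)
        zb = np.column_stack([np.log(lo), np.log(hi)])
        res = pso(obj, zb, swarm_size=swarm_size, iterations=iterations,
                  seed=int(rng.integers(2**31 - 1)),
                  x0=np.log([current[p] for p in names]))
        zbest, fbest = res.x, res.fun
        if polish:
            pres = optimize.minimize(obj, zbest, method="Nelder-Mead",
                                     options={"xatol": 1e-10, "fatol": 1e-14,
                                              "maxiter": 150 * len(names)})
            if pres.fun < fbest:
                zbest, fbest = np.clip(pres.x, zb[:, 0], zb[:, 1]), float(pres.fun)
        current.update(zip(names, np.exp(zbest)))
        traces.append(res.trace)
        stages.append({"stage": stage, "parameters": names,
                       "objective": fbest, "nfev": res.nfev})
    final_obj = weighted_ssr(predictor, current, datasets)
    resid = _residual_table(predictor, current, datasets)
    rt_rows = []
    for (cond, obs), g in resid.groupby(["condition", "observable"], sort=False):
        try:
            h, pval = runs_test(g["residual"].to_numpy())
        except DegenerateResidualError:
            h, pval = 0, np.nan
        rt_rows.append((cond, obs, h, pval))
    runs_df = pd.DataFrame(rt_rows, columns=["condition", "observable", "h", "p"])
    return FitResult(values={p: current[p] for p in fitted}, objective=final_obj,
                     objective_trace=np.concatenate(traces) if traces else np.array([]),
                     bounds=bounds_all, residuals=resid, runs_tests=runs_df,
                     stages=stages, seed=seed)


# ---------------------------------------------------------------------------
# runs test
# ---------------------------------------------------------------------------

def _runs_distribution(n1: int, n2: int) -> dict[int, float]:
    """Exact null distribution of the number of runs for n1 + n2 signs."""
    total = comb(n1 + n2, n1)
    dist: dict[int, float] = {}
    for k in range(1, min(n1, n2) + 1):
        dist[2 * k] = 2 * comb(n1 - 1, k - 1) * comb(n2 - 1, k - 1) / total
        c = comb(n1 - 1, k - 1) * comb(n2 - 1, k) + comb(n1 - 1, k) * comb(n2 - 1, k - 1)
        if c:
            dist[2 * k + 1] = c / total
    return dist


def runs_test(x, alpha: float = 0.05, exact_max_n: int = 30) -> tuple[int, float]:
    """Wald-Wolfowitz runs test about the sample mean.

    Returns ``(h, p)``: h = 1 rejects the null hypothesis of random order at
    level ``alpha``.  Values equal to the mean are removed; the two-sided p
    is the probability mass of run counts at least as far from the expected
    count as observed — exact for n ≤ 30, normal approximation with
    continuity correction beyond.
    """
    x = np.asarray(x, float)
    m = float(np.mean(x))
    signs = np.sign(x[x != m] - m)
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        raise DegenerateResidualError("all residuals on one side of the mean")
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 1 + 2 * n1 * n2 / n
    if n <= exact_max_n:
        dist = _runs_distribution(n1, n2)
        p = sum(prob for r, prob in dist.items() if abs(r - mu) >= abs(runs - mu) - 1e-12)
    else:
        var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n ** 2 * (n - 1))
        z = (abs(runs - mu) - 0.5) / math.sqrt(var)
        p = 2 * stats.norm.sf(max(z, 0.0))
    p = float(min(1.0, p))
    return (1 if p < alpha else 0, p)


# ---------------------------------------------------------------------------
# bootstrap UQ
# ---------------------------------------------------------------------------

@dataclass
class PredictionBand:
    """Percentile prediction band from case-resampling bootstrap."""

    table: pd.DataFrame  # observable, condition, time_h, lower, upper, median
    level: float
    n_boot: int
    seed: int | None
    point: pd.DataFrame | None = None
    parameter_samples: pd.DataFrame | None = None

    def interval(self, observable: str, condition: str):
        sub = self.table[(self.table["observable"] == observable)
                         & (self.table["condition"] == condition)]
        return (sub["time_h"].to_numpy(), sub["lower"].to_numpy(), sub["upper"].to_numpy())


def bootstrap_uq(predictor, datasets, fit: FitResult,
                 groups: dict[str, list[str]] | None = None,
                 n_boot: int = 100, level: float = 0.95,
                 seed: int | None = None,
                 swarm_size: int = 10, iterations: int = 40,
                 polish: bool = True,
                 prediction_times: np.ndarray | None = None,
                 condition_filters: dict | None = None) -> PredictionBand:
    """Case-resampling bootstrap prediction band.

    Data records are resampled with replacement within each (observable,
    condition, source) group; each replicate is refitted with a reduced
    optimisation budget (a documented fidelity/cost trade-off); the band is
    the percentile interval of the replicate predictions at each time.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if isinstance(datasets, ExperimentalDataset):
        datasets = [datasets]
    if groups is None:
        groups = {"vegf": sorted(fit.values)}
    rng = np.random.default_rng(seed)
    all_records = pd.concat([d.records for d in datasets], ignore_index=True)
    targets = list(all_records.groupby(["observable", "condition"], sort=False).groups)
    if prediction_times is None:
        tmax = float(all_records["time_h"].max())
        prediction_times = np.linspace(0.0, tmax, 25)
    preds: dict[tuple, list[np.ndarray]] = {k: [] for k in targets}
    params_rows = []
    for _ in range(n_boot):
        boot_frames = []
        for _, g in all_records.groupby(["observable", "condition", "source"], sort=False):
            if len(g) == 0:
                raise DatasetError("cannot resample an empty dataset group")
            idx = rng.integers(0, len(g), size=len(g))
            boot_frames.append(g.iloc[idx])
        boot_ds = ExperimentalDataset(pd.concat(boot_frames, ignore_index=True))
        refit = staged_fit(predictor, boot_ds, groups, baseline=dict(fit.values),
                           seed=int(rng.integers(2**31 - 1)),
                           swarm_size=swarm_size, iterations=iterations,
                           polish=polish, condition_filters=condition_filters)
        params_rows.append(refit.values)
        for obs, cond in targets:
            preds[(obs, cond)].append(
                np.asarray(predictor(refit.values, obs, cond, prediction_times), float))
    a = (1 - level) / 2
    rows = []
    for (obs, cond), mat in preds.items():
        M = np.vstack(mat)
        lo = np.quantile(M, a, axis=0)
        hi = np.quantile(M, 1 - a, axis=0)
        md = np.quantile(M, 0.5, axis=0)
        for t, l, u, m_ in zip(prediction_times, lo, hi, md):
            rows.append((obs, cond, t, l, u, m_))
    table = pd.DataFrame(rows, columns=["observable", "condition", "time_h",
                                        "lower", "upper", "median"])
    point_rows = []
    for obs, cond in targets:
        yhat = np.asarray(predictor(fit.values, obs, cond, prediction_times), float)
        for t, v in zip(prediction_times, yhat):
            point_rows.append((obs, cond, t, v))
    point = pd.DataFrame(point_rows, columns=["observable", "condition", "time_h", "value"])
    return PredictionBand(table=table, level=level, n_boot=n_boot, seed=seed,
                          point=point, parameter_samples=pd.DataFrame(params_rows))


def coverage_fraction(band: PredictionBand, dataset: ExperimentalDataset) -> float:
    """Fraction of data points inside [lower, upper] (nearest-time matching
    within half a band grid step)."""
    inside = 0
    total = 0
    for (obs, cond, _src), g in dataset.groups():
        t_band, lo, hi = band.interval(obs, cond)
        if len(t_band) == 0:
            continue
        half = 0.5 * np.median(np.diff(np.unique(t_band))) if len(t_band) > 1 else np.inf
        for t, v in zip(g["time_h"], g["value"]):
            i = int(np.argmin(np.abs(t_band - t)))
            if abs(t_band[i] - t) > half + 1e-12:
                continue
            total += 1
            if lo[i] - 1e-12 <= v <= hi[i] + 1e-12:
                inside += 1
    if total == 0:
        raise DatasetError("no data points match the band's observables/times")
    return inside / total
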