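"""Synthetic-data generation and toy reaction networks.

The calibration data the pipeline was designed for are digitized,
max-normalized Western-blot time courses — semi-quantitative values with
roughly constant coefficient of variation.  The generator emulates exactly
that: simulate a model at known "true" parameters, sample at a typical
Western-blot time grid, corrupt with multiplicative lognormal noise
(default), max-normalize, and clamp into [0, 1].  Because the truth is
known, parameter-recovery and bootstrap-coverage experiments are fully
reproducible with no external downloads.

The toy networks provide closed-form or brute-force-checkable behaviour:
a reversible binding (equilibrium [A][B]/[C] = koff/kon), a two-tier
Michaelis-Menten cascade (distinct parameter groups for staged fitting),
and a six-species two-cell mutual-inhibition motif that breaks symmetry
under differential input — the patterning mechanism in miniature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calib import ExperimentalDataset
from .network import ModelDefinition, Modifier, Parameter, Reaction, Species
from .sim import normalize_to_max, simulate

#: Typical Western-blot sampling grid, hours.
DEFAULT_SAMPLE_TIMES = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

TOY_KINDS = ("reversible-binding", "mm-cascade", "two-cell-mini-notch")


@dataclass
class NoiseModel:
    """Measurement-noise specification for synthetic time courses.

    multiplicative-lognormal (default): x ↦ x·exp(σZ), the constant-CV
    error structure of densitometry; additive-gaussian: x ↦ x + σZ, for
    robustness checks; none: exact values.
    """

    kind: str = "multiplicative-lognormal"
    sigma: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative-lognormal", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.sigma == 0:
            return values.copy()
        z = rng.standard_normal(values.shape)
        if self.kind == "multiplicative-lognormal":
            return values * np.exp(self.sigma * z)
        return values + self.sigma * z


def generate_synthetic_timecourses(model_or_predictor, protocols,
                                   true_params: dict[str, float],
                                   observables, sample_times=DEFAULT_SAMPLE_TIMES,
                                   noise: NoiseModel | None = None,
                                   solver_options: dict | None = None) -> ExperimentalDataset:
    """Simulate at the true parameters, add noise, max-normalize, and label.

    ``protocols`` maps condition labels to :class:`StimulusProtocol`s (or a
    single protocol under the label "default").  Alternatively a calibrated
    predictor callable can stand in for the model.  The dataset is
    reproducible for a given ``noise.seed`` and passes
    :class:`~tipstalk.calib.ExperimentalDataset` validation by construction.
    """
    if not observables:
        raise ValueError("need at least one observable")
    noise = noise or NoiseModel(kind="none", sigma=0.0)
    rng = np.random.default_rng(noise.seed)
    times = np.asarray(sample_times, float)
    if hasattr(protocols, "duration"):
        protocols = {"default": protocols}
    rows = []
    for cond, proto in protocols.items():
        if callable(model_or_predictor) and not isinstance(model_or_predictor, ModelDefinition):
            series = {obs: np.asarray(
                model_or_predictor(true_params, obs, cond, times), float)
                for obs in observables}
        else:
            if times.max() > proto.duration + 1e-9:
                raise ValueError("sample_times exceed the protocol duration")
            traj = simulate(model_or_predictor, proto,
                            t_grid=np.unique(np.concatenate([[0.0], times])),
                            solver_options=solver_options,
                            parameter_overrides=true_params)
            series = {obs: np.interp(times, traj.time_h, traj.series(obs))
                      for obs in observables}
        for obs, vals in series.items():
            noisy = noise.apply(vals, rng)
            if np.max(noisy) <= 0:
                noisy = np.zeros_like(noisy)
            else:
                noisy = np.clip(normalize_to_max(noisy), 0.0, 1.0)
            for t, v in zip(times, noisy):
                rows.append((t, obs, v, cond, "synthetic"))
    return ExperimentalDataset.from_records(rows)


def toy_network(kind: str) -> ModelDefinition:
    """Small networks with independently checkable behaviour."""
    if kind == "reversible-binding":
        return _reversible_binding()
    if kind == "mm-cascade":
        return _mm_cascade()
    if kind == "two-cell-mini-notch":
        return _mini_notch()
    raise ValueError(f"unknown toy network kind {kind!r}; valid: {TOY_KINDS}")


def _reversible_binding() -> ModelDefinition:
    m = ModelDefinition(name="reversible-binding")
    m.species = [Species("A", initial_value=1.0), Species("B", initial_value=0.8),
                 Species("C", initial_value=0.0)]
    m.parameters = {"kon": Parameter("kon", 1e-3, units="1/(uM*s)"),
                    "koff": Parameter("koff", 5e-4, units="1/s")}
    m.reactions = [
        Reaction("bind", [("A", 1), ("B", 1)], [("C", 1)], law_params={"k": "kon"}),
        Reaction("unbind", [("C", 1)], [("A", 1), ("B", 1)], law_params={"k": "koff"}),
    ]
    m.observables = {"C": "C", "A": "A"}
    m.validate()
    return m


def _mm_cascade() -> ModelDefinition:
    """Two MM tiers S→P (catalysed by E) and X→Y (catalysed by P), with
    first-order back-reactions; tier-1 and tier-2 parameters form natural
    staged-fitting groups."""
    m = ModelDefinition(name="mm-cascade")
    m.species = [Species("E", initial_value=1.0, is_constant=True,
                         initial_from_param="E0"),
                 Species("S", initial_value=2.0), Species("P", initial_value=0.0),
                 Species("X", initial_value=1.5, initial_from_param="X0"),
                 Species("Y", initial_value=0.0)]
    m.parameters = {
        "E0": Parameter("E0", 1.0, units="uM", status="known"),
        "X0": Parameter("X0", 1.5, units="uM", status="known"),
        "kcat1": Parameter("kcat1", 2e-3, units="1/s", status="fittable", group="vegf"),
        "Km1": Parameter("Km1", 0.8, units="uM", status="fittable", group="vegf"),
        "krev1": Parameter("krev1", 4e-4, units="1/s", status="fittable", group="vegf"),
        "kcat2": Parameter("kcat2", 3e-3, units="1/s", status="fittable", group="hypoxia"),
        "Km2": Parameter("Km2", 0.6, units="uM", status="fittable", group="hypoxia"),
        "krev2": Parameter("krev2", 5e-4, units="1/s", status="fittable", group="hypoxia"),
    }
    m.reactions = [
        Reaction("tier1", [("S", 1)], [("P", 1)], law="michaelis_menten",
                 law_params={"vmax": "kcat1", "km": "Km1", "substrate": "S", "enzyme": "E"}),
        Reaction("tier1_rev", [("P", 1)], [("S", 1)], law_params={"k": "krev1"}),
        Reaction("tier2", [("X", 1)], [("Y", 1)], law="michaelis_menten",
                 law_params={"vmax": "kcat2", "km": "Km2", "substrate": "X", "enzyme": "P"}),
        Reaction("tier2_rev", [("Y", 1)], [("X", 1)], law_params={"k": "krev2"}),
    ]
    m.observables = {"P": "P", "Y": "Y", "S": "S"}
    m.validate()
    return m


def _mini_notch() -> ModelDefinition:
    """Six-species two-cell lateral-inhibition motif.

    Per cell: activity A (driven by input v, repressed by inhibitor I with
    a squared Hill term), ligand D (produced from A), and inhibitor I
    (produced from the *neighbour's* D — the trans coupling).  Equal inputs
    give a symmetric steady state; a 2:1 input ratio leaves the low-input
    cell with the higher inhibitor level.
    """
    m = ModelDefinition(name="two-cell-mini-notch")
    for c, comp in (("c1", "cell1"), ("c2", "cell2")):
        m.species += [Species(f"A_{c}", comp, 0.0), Species(f"D_{c}", comp, 0.0),
                      Species(f"I_{c}", comp, 0.0)]
    m.parameters = {
        "v1": Parameter("v1", 1e-3, units="uM/s", status="known", group="vegf"),
        "v2": Parameter("v2", 1e-3, units="uM/s", status="known", group="vegf"),
        "KI": Parameter("KI", 1.0, units="uM", status="fittable", group="vegf"),
        "kD": Parameter("kD", 1e-3, units="1/s", status="fittable", group="vegf"),
        "kI": Parameter("kI", 1e-3, units="1/s", status="fittable", group="hypoxia"),
        "kdeg": Parameter("kdeg", 1e-3, units="1/s", status="fittable", group="hypoxia"),
    }
    for c, other, v in (("c1", "c2", "v1"), ("c2", "c1", "v2")):
        scope = "intra-cell1" if c == "c1" else "intra-cell2"
        m.reactions += [
            Reaction(f"input_{c}", [], [(f"A_{c}", 1)], law_params={"k": v},
                     modifiers=[Modifier(f"I_{c}", "inhibitor", "KI", 2.0)], scope=scope),
            Reaction(f"a_deg_{c}", [(f"A_{c}", 1)], [], law_params={"k": "kdeg"}, scope=scope),
            Reaction(f"d_prod_{c}", [(f"A_{c}", 1)], [(f"A_{c}", 1), (f"D_{c}", 1)],
                     law_params={"k": "kD"}, scope=scope),
            Reaction(f"d_deg_{c}", [(f"D_{c}", 1)], [], law_params={"k": "kdeg"}, scope=scope),
            Reaction(f"i_trans_{c}", [(f"D_{other}", 1)], [(f"D_{other}", 1), (f"I_{c}", 1)],
                     law_params={"k": "kI"}, scope="trans"),
            Reaction(f"i_deg_{c}", [(f"I_{c}", 1)], [], law_params={"k": "kdeg"}, scope=scope),
        ]
    m.observables = {n: n for n in ("A_c1", "D_c1", "I_c1", "A_c2", "D_c2", "I_c2")}
    m.validate()
    return m
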