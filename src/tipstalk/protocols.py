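"""Stimulus construction and unit conversions.

Protocols describe what the two cells experience: per-cell exogenous VEGF
(bolus set-value at t = 0, emulating a paracrine gradient), the ambient O₂
level, γ-secretase inhibition by DAPT, and optional mid-run set-value
events.  The VEGF gradient helper converts a tip-filopodium concentration
into the per-cell sensed doses using a linear 3.5%-per-10-µm decay along a
~100 µm cell with ~10 µm filopodia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AVOGADRO = 6.02214076e23

#: Dissolved O₂ at 21% (atmospheric) culture conditions, µM.
O2_NORMOXIA_UM = 209.0
NORMOXIA_PERCENT = 21.0

#: VEGFA molecular weight (g/mol) implied by the 50 ng/mL ↔ 0.0012 µM dose
#: pairing used throughout; the VEGF165 homodimer is ~45 kDa, so this sits
#: in the plausible range.  Configurable in :func:`ngml_to_micromolar`.
VEGFA_MW_DEFAULT = 50e-6 / 0.0012e-6  # = 41_666.7

#: Default stalk-cell gradient endpoints (front, rear), µM — the
#: front/rear concentrations implied by the standard two-cell geometry.
DEFAULT_STALK_ENDPOINTS = (0.00075, 0.000487)


class ProtocolError(ValueError):
    """Invalid stimulus or geometry specification."""


@dataclass
class StimulusProtocol:
    """Per-cell stimulus for one simulation experiment.

    vegf_cell1/vegf_cell2: exogenous VEGF boluses, µM, applied at t = 0.
    o2: ambient oxygen concentration, µM (209 = normoxia, 9.95 = 1% O₂).
    dapt: γ-secretase inhibitor dose, µM.
    duration: simulated time after stimulus onset, hours.
    events: list of (time_h, species_name, set_value) applied mid-run.
    pre_equilibrate_h: normoxic, VEGF-free settling time before t = 0 so
        stimuli act on a quasi-steady baseline.
    """

    vegf_cell1: float = 0.0
    vegf_cell2: float = 0.0
    o2: float = O2_NORMOXIA_UM
    dapt: float = 0.0
    duration: float = 12.0
    events: list[tuple[float, str, float]] = field(default_factory=list)
    pre_equilibrate_h: float = 24.0

    def __post_init__(self) -> None:
        for name in ("vegf_cell1", "vegf_cell2", "o2", "dapt"):
            if getattr(self, name) < 0:
                raise ProtocolError(f"{name} must be non-negative")
        if self.duration <= 0:
            raise ProtocolError("duration must be positive")

    def swapped(self) -> "StimulusProtocol":
        """The same protocol with the two cells' roles exchanged."""
        swap = {"_c1": "_c2", "_c2": "_c1"}
        events = []
        for t, sp, v in self.events:
            for suf, other in swap.items():
                if sp.endswith(suf):
                    sp = sp[: -len(suf)] + other
                    break
            events.append((t, sp, v))
        return StimulusProtocol(
            vegf_cell1=self.vegf_cell2, vegf_cell2=self.vegf_cell1,
            o2=self.o2, dapt=self.dapt, duration=self.duration,
            events=events, pre_equilibrate_h=self.pre_equilibrate_h)


@dataclass
class GradientGeometry:
    """Linear VEGF decay geometry between a tip filopodium and the stalk cell.

    ``mode="endpoints"`` (default) averages configured front/rear
    stalk concentrations; ``mode="geometric"`` evaluates the linear decay at
    ``front_distance_um``/``rear_distance_um``.  The two modes exist because
    the default endpoint pair is not uniquely recoverable from the stated
    cell/filopodia lengths alone.
    """

    v0: float = 0.0012
    decay_fraction_per_10um: float = 0.035
    cell_length: float = 100.0
    filopodia_length: float = 10.0
    mode: str = "endpoints"
    endpoint_concentrations: tuple[float, float] | None = DEFAULT_STALK_ENDPOINTS
    front_distance_um: float = 107.0
    rear_distance_um: float = 170.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.decay_fraction_per_10um < 1.0):
            raise ProtocolError("decay fraction per 10 µm must be in [0, 1)")
        if self.cell_length <= 0 or self.filopodia_length <= 0:
            raise ProtocolError("lengths must be positive")
        if self.mode not in ("endpoints", "geometric"):
            raise ProtocolError(f"unknown gradient mode {self.mode!r}")


def vegf_at_distance(g: GradientGeometry, d: float) -> float:
    """VEGF concentration (µM) at distance ``d`` µm from the filopodium tip.

    Linear decay ``v0 · max(0, 1 − f·d/10)`` clamped at zero beyond the
    extinction distance.
    """
    if d < 0:
        raise ProtocolError("distance must be non-negative")
    return g.v0 * max(0.0, 1.0 - g.decay_fraction_per_10um * d / 10.0)


def sensed_vegf_per_cell(g: GradientGeometry) -> tuple[float, float]:
    """(tip_vegf, stalk_vegf) in µM.

    The tip cell senses ``v0`` at its filopodium; the stalk cell, with
    receptors distributed along its length, senses the mean of its front and
    rear concentrations.
    """
    if g.mode == "endpoints":
        if g.endpoint_concentrations is None:
            raise ProtocolError("endpoints mode requires endpoint_concentrations")
        front, rear = g.endpoint_concentrations
    else:
        front = vegf_at_distance(g, g.front_distance_um)
        rear = vegf_at_distance(g, g.rear_distance_um)
    return g.v0, 0.5 * (front + rear)


def oxygen_percent_to_concentration(percent: float) -> float:
    """Dissolved O₂ (µM) from a gas-phase percentage, anchored 21% ↦ 209 µM."""
    if not (0.0 <= percent <= 100.0):
        raise ProtocolError("oxygen percent must be within [0, 100]")
    return O2_NORMOXIA_UM * percent / NORMOXIA_PERCENT


def oxygen_percent_to_mmhg(percent: float, atm_mmhg: float = 760.0) -> float:
    """O₂ partial pressure in mmHg for a gas-phase percentage of 1 atm."""
    if not (0.0 <= percent <= 100.0):
        raise ProtocolError("oxygen percent must be within [0, 100]")
    return atm_mmhg * percent / 100.0


def ngml_to_micromolar(dose: float, molecular_weight: float = VEGFA_MW_DEFAULT) -> float:
    """Convert a ng/mL dose to µM given a molecular weight in g/mol."""
    if dose < 0:
        raise ProtocolError("dose must be non-negative")
    if molecular_weight <= 0:
        raise ProtocolError("molecular weight must be positive")
    return dose * 1e-6 / molecular_weight * 1e6


def receptor_count_to_concentration(count: float, volume: float = 1e-12) -> float:
    """Receptors/cell → µM for a cell of ``volume`` liters (default 1 pL)."""
    if count < 0:
        raise ProtocolError("receptor count must be non-negative")
    if volume <= 0:
        raise ProtocolError("volume must be positive")
    return count / (AVOGADRO * volume) * 1e6


def apply_dapt(model, dose: float, ki_param: str = "Ki_DAPT",
               cleavage_param: str = "kcleave"):
    """Return a model copy with γ-secretase cleavage scaled by 1/(1+dose/Ki).

    DAPT competitively blocks NICD release; the scaling is monotone
    decreasing in dose and leaves the model untouched at dose 0.
    """
    if dose < 0:
        raise ProtocolError("DAPT dose must be non-negative")
    out = model.copy()
    if dose > 0:
        ki = out.parameters[ki_param].value
        out.parameters[cleavage_param].value /= (1.0 + dose / ki)
    return out


def dapt_scale(dose: float, ki: float) -> float:
    """The multiplicative cleavage factor 1/(1 + dose/Ki)."""
    if dose < 0:
        raise ProtocolError("DAPT dose must be non-negative")
    return 1.0 / (1.0 + dose / ki)
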