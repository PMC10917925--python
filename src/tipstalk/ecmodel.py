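"""The two-cell endothelial tip/stalk model and the ECPI observable.

Two structurally identical endothelial cells, each carrying six pathway
modules — VEGF-VEGFR, Notch, oxygen sensing (HIF), Akt-eNOS, Raf-MEK-ERK,
and calcium/NO cycling — interact exclusively through trans Dll4-Notch1
binding (lateral inhibition).  The wiring implements the canonical
patterning circuit:

* VEGF·VEGFR2 phosphorylation drives PLCγ/Ca²⁺, Akt, and ERK;
* phospho-ERK induces Dll4 mRNA (Hill, gain ``teta_ERKDll4``);
* a cell's Dll4 activates the neighbour's Notch1; γ-secretase releases
  NICD, which induces Hes1;
* Hes1 represses surface VEGFR2 production (Hill exponent ``n_HesR2``) and
  Dll4 mRNA, and upregulates VEGFR1 (``kNotchR1``) — closing the mutual
  inhibition loop that amplifies a small input asymmetry into a tip/stalk
  decision;
* HIF1α and HIF2α, stabilised when O₂-dependent degradation slows, drive
  VEGFA mRNA additively; autocrine VEGFA feeds only the same cell's
  Akt/NO survival arm and the VEGFR1 decoy, never the patterning flux;
* hypoxia opens a Na⁺/Ca²⁺-exchanger Ca²⁺ influx.

The Endothelial Cell Pattern Index ECPI = Hes1·VEGFR1 / (Dll4·VEGFR2) is
the stalk-vs-tip marker ratio: > 1 stalk-like, < 1 tip-like.

Default rate constants are the package's own (status="assumed"), seeded
from plausible signalling ranges (binding on-rates ~1-10 µM⁻¹s⁻¹, protein
half-lives ~0.5-8 h) and chosen so the circuit reproduces the expected
qualitative behaviours; they are configuration, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import ModelDefinition, Modifier, Parameter, Reaction, Species
from .protocols import O2_NORMOXIA_UM, receptor_count_to_concentration

MODULES = ("vegf", "notch", "hif", "akt_enos", "erk", "calcium")

CELL_VOLUME_L = 1e-12  # 1000 µm² cell footprint, ~1 pL

#: Initial receptor concentrations, µM (per-cell counts at 1 pL).
VEGFR2_0 = receptor_count_to_concentration(6000, CELL_VOLUME_L)
VEGFR1_0 = receptor_count_to_concentration(2000, CELL_VOLUME_L)
NRP1_0 = 0.0664
NOTCH1_0 = 0.0099


class UndefinedIndexError(ZeroDivisionError):
    """ECPI is undefined when Dll4·VEGFR2 vanishes."""


@dataclass
class EcpiState:
    """Marker concentrations (µM) of one cell at one instant."""

    hes1: float
    vegfr1: float
    dll4: float
    vegfr2: float


def ecpi(state: EcpiState) -> float:
    """Endothelial Cell Pattern Index Hes1·VEGFR1/(Dll4·VEGFR2).

    Raises :class:`UndefinedIndexError` on a zero denominator rather than
    returning an infinity.
    """
    if min(state.hes1, state.vegfr1, state.dll4, state.vegfr2) < 0:
        raise ValueError("ECPI markers must be non-negative")
    denom = state.dll4 * state.vegfr2
    if denom == 0.0:
        raise UndefinedIndexError("ECPI undefined: Dll4*VEGFR2 == 0")
    return state.hes1 * state.vegfr1 / denom


@dataclass
class InitialConditionSet:
    """Per-species initial concentrations, identical for both cells."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative initial value for {k!r}")


def default_initial_conditions() -> InitialConditionSet:
    """Baseline per-cell initial concentrations (µM).

    Receptor levels follow the receptor-count conversion (6000 VEGFR2/cell,
    2000 VEGFR1/cell, ~40,000 NRP1/cell at 1 pL); Notch1 starts at the
    VEGFR2-like 0.0099 µM; Dll4 protein and the Dll4/Notch1 mRNAs start at
    zero.  Everything else is an assumed baseline that the pre-equilibration
    phase relaxes to a quasi-steady state.
    """
    return InitialConditionSet({
        # VEGF module
        "R2": VEGFR2_0, "VR2": 0.0, "pVR2": 0.0, "iR2": 0.0, "VR2N": 0.0,
        "R1": VEGFR1_0, "VR1": 0.0, "NRP1": NRP1_0,
        # Notch module
        "mNotch1": 0.0, "Notch1": NOTCH1_0, "NB": 0.0, "Gs": 0.01,
        "NICD": 0.0, "Hes1": 0.002, "mDll4": 0.0, "Dll4": 0.0,
        # HIF module
        "HIF1a": 0.005, "HIF2a": 0.003, "HIF1b": 0.1, "mVEGFA": 0.01,
        "Vauto": 0.0,
        # Akt-eNOS
        "PIP2": 10.0, "PIP3": 0.0, "Akt": 0.5, "AktPIP3": 0.0, "pAkt": 0.0,
        "Hsp": 0.5, "pAktHsp": 0.0,
        "eNOS": 0.1, "eNOSin": 0.0, "peNOS": 0.0, "NO": 0.0,
        # calcium / NO cycling
        "PLC": 0.1, "pPLC": 0.0, "IP3": 0.0, "DAG": 0.0,
        "PKC": 0.5, "DAGPKC": 0.0, "aPKC": 0.0,
        "Ca": 0.1, "ER": 400.0, "CaM": 10.0, "CaCaM": 0.0, "Jcrac": 0.0,
        # Raf-MEK-ERK (+ S1P and Axl side arms)
        "Ras": 0.1, "RasGTP": 0.0, "Raf": 0.1, "pRaf": 0.0,
        "MEK": 1.0, "pMEK": 0.0, "ERK": 1.0, "pERK": 0.0,
        "SK1": 0.1, "aSK1": 0.0, "Sph": 1.0, "S1P": 0.0,
        "Axl": 0.1, "pAxl": 0.0,
    })


_CONSTANT = {"HIF1b", "Hsp", "Sph"}
_STATE_FLUX = {"Jcrac"}


# name: (value, units, status, group)
# The registry houses every parameter the sensitivity analysis discusses
# (kdeg_He, kp_Dll, n_HesR2, kNotchR1, teta_ERKDll4, ... O2, Caext) plus
# the package's own plumbing constants.
_PARAMS: dict[str, tuple[float, str, str, str]] = {
    # environment (shared, bound to constant species)
    "O2": (O2_NORMOXIA_UM, "uM", "known", "hypoxia"),
    "Caext": (1500.0, "uM", "known", "none"),
    "Vext1": (0.0, "uM", "known", "vegf"),
    "Vext2": (0.0, "uM", "known", "vegf"),
    "Ki_DAPT": (0.02, "uM", "assumed", "none"),
    # VEGF-VEGFR module
    "kvr2on": (10.0, "1/(uM*s)", "assumed", "vegf"),
    "kvr2off": (1e-2, "1/s", "assumed", "vegf"),
    "kp_vr2": (5e-3, "1/s", "fittable", "vegf"),
    "kdp_vr2": (2e-3, "1/s", "fittable", "vegf"),
    "kp_iVR2": (5e-4, "1/s", "fittable", "vegf"),
    "krec_iR2": (5e-4, "1/s", "fittable", "vegf"),
    "kdeg_iR2": (2e-5, "1/s", "assumed", "vegf"),
    "kprod_R2": (1.0e-6, "uM/s", "assumed", "vegf"),
    "kdeg_R2": (1e-4, "1/s", "assumed", "vegf"),
    "khesr2": (0.03, "uM", "fittable", "vegf"),
    "n_HesR2": (2.0, "dimensionless", "assumed", "vegf"),
    "kNRP1VEGFR2on": (1.0, "1/(uM*s)", "assumed", "vegf"),
    "kNRP1VEGFR2off": (1e-2, "1/s", "fittable", "vegf"),
    "kp_vr2n": (2e-2, "1/s", "assumed", "vegf"),
    "kdegR2NRPnp": (1e-4, "1/s", "fittable", "vegf"),
    "kprod_NRP1": (6.64e-7, "uM/s", "assumed", "vegf"),
    "kdeg_NRP1": (1e-5, "1/s", "assumed", "vegf"),
    "kprod_R1": (3.0e-7, "uM/s", "assumed", "vegf"),
    "kdeg_R1": (1e-4, "1/s", "assumed", "vegf"),
    "kNotchR1": (0.05, "uM", "fittable", "vegf"),
    "kvr1on": (10.0, "1/(uM*s)", "assumed", "vegf"),
    "kvr1off": (1e-2, "1/s", "assumed", "vegf"),
    # Notch module
    "kform_Notch": (1e-6, "uM/s", "fittable", "vegf"),
    "kdeg_mNotch": (2e-4, "1/s", "assumed", "vegf"),
    "ktransl_Notch": (2e-4, "1/s", "assumed", "vegf"),
    "kdeg_Notch1": (1e-4, "1/s", "assumed", "vegf"),
    "ktrans_DllNotch": (0.01, "1/(uM*s)", "assumed", "vegf"),
    "kdeg_NB": (2e-3, "1/s", "assumed", "vegf"),
    "kcleave": (20.0, "1/(uM*s)", "assumed", "vegf"),
    "kform_Gs": (1e-6, "uM/s", "fittable", "vegf"),
    "kdeg_Gs": (1e-4, "1/s", "assumed", "vegf"),
    "kdeg_NICD": (4e-4, "1/s", "assumed", "vegf"),
    "kp_He": (4e-5, "uM/s", "fittable", "vegf"),
    "Km_He": (0.0011, "uM", "assumed", "vegf"),
    "n_He": (4.0, "dimensionless", "assumed", "vegf"),
    "kbasal_He": (8e-7, "uM/s", "assumed", "vegf"),
    "kdeg_He": (4e-4, "1/s", "fittable", "vegf"),
    "teta_ERKDll4": (4e-6, "uM/s", "fittable", "vegf"),
    "K_ERKDll4": (0.27, "uM", "assumed", "vegf"),
    "n_ERKDll4": (2.0, "dimensionless", "assumed", "vegf"),
    "K_HeDll4": (0.05, "uM", "assumed", "vegf"),
    "kdeg_mDll4": (4e-4, "1/s", "fittable", "vegf"),
    "ktransl_Dll4": (4e-5, "uM/s", "fittable", "vegf"),
    "kp_Dll": (0.01, "uM", "fittable", "vegf"),
    "kdeg_Dll4": (1e-3, "1/s", "assumed", "vegf"),
    # HIF / oxygen sensing
    "ktranslmHIF1a": (1e-5, "uM/s", "fittable", "hypoxia"),
    "kdeg_HIF1a": (2e-3, "1/s", "fittable", "hypoxia"),
    "Km_O2HIF": (100.0, "uM", "assumed", "hypoxia"),
    "kdeg_HIF1a_basal": (1e-5, "1/s", "assumed", "hypoxia"),
    "ktransl_HIF2a": (5e-6, "uM/s", "assumed", "hypoxia"),
    "k12_degHIF1a": (1.5e-3, "1/s", "fittable", "hypoxia"),
    "delta_ox22": (80.0, "uM", "fittable", "hypoxia"),
    "ktx_VEGFA": (2e-3, "1/(uM*s)", "assumed", "hypoxia"),
    "kdeg_mVEGFA": (2e-4, "1/s", "fittable", "hypoxia"),
    "ktransl_VEGFA": (1e-4, "1/s", "assumed", "hypoxia"),
    "kdeg_Vauto": (1e-3, "1/s", "assumed", "hypoxia"),
    "khif1eNOS": (0.05, "1/(uM*s)", "fittable", "hypoxia"),
    "krel_eNOS": (1e-3, "1/s", "assumed", "hypoxia"),
    # Akt-eNOS
    "kgenPIP2": (1e-3, "uM/s", "fittable", "vegf"),
    "kdeg_PIP2": (1e-4, "1/s", "assumed", "vegf"),
    "kcat_PI3K": (0.1, "1/s", "assumed", "vegf"),
    "Km_PI3K": (5.0, "uM", "assumed", "vegf"),
    "Ka_Axl": (0.05, "uM", "assumed", "vegf"),
    "kdeg_PIP3": (5e-3, "1/s", "assumed", "vegf"),
    "kf_AktPIP3": (1.0, "1/(uM*s)", "assumed", "vegf"),
    "kr_AktPIP3": (1e-2, "1/s", "fittable", "vegf"),
    "kp_Akt": (1e-2, "1/s", "assumed", "vegf"),
    "Ka_S1P": (0.1, "uM", "assumed", "vegf"),
    "Ka_auto": (0.005, "uM", "assumed", "hypoxia"),
    "kdp_Akt": (1e-3, "1/s", "fittable", "vegf"),
    "kformAkt": (5e-5, "uM/s", "fittable", "vegf"),
    "kdeg_Akt": (1e-4, "1/s", "assumed", "vegf"),
    "kf_paktHsp": (1.0, "1/(uM*s)", "assumed", "vegf"),
    "kr_paktHsp": (1e-2, "1/s", "fittable", "vegf"),
    "kdpAkt": (5e-4, "1/s", "fittable", "vegf"),
    "kf_eNOSHSP": (5e-3, "1/s", "fittable", "vegf"),
    "Km_eNOS": (0.5, "uM", "assumed", "vegf"),
    "Ka_CaCaM": (1.0, "uM", "assumed", "vegf"),
    "kdp_eNOS": (2e-3, "1/s", "assumed", "vegf"),
    "kNO": (1e-3, "1/s", "assumed", "vegf"),
    "kdeg_NO": (1e-3, "1/s", "assumed", "vegf"),
    # calcium / NO cycling
    "kf_PLCy": (0.1, "1/s", "assumed", "vegf"),
    "Km_PLC": (0.5, "uM", "assumed", "vegf"),
    "kdp_PLCy": (1e-3, "1/s", "assumed", "vegf"),
    "kcat_PLCy": (0.05, "1/s", "assumed", "vegf"),
    "KmPIP2PLCy": (5.0, "uM", "fittable", "vegf"),
    "kdeg_IP3": (2e-3, "1/s", "assumed", "vegf"),
    "kdeg_DAG": (2e-3, "1/s", "assumed", "vegf"),
    "kIP3R": (1e-3, "1/s", "assumed", "vegf"),
    "Km_IP3R": (0.5, "uM", "fittable", "vegf"),
    "n_IP3R": (2.0, "dimensionless", "assumed", "vegf"),
    "kSERCA": (0.5, "uM/s", "assumed", "vegf"),
    "Km_SERCA": (0.3, "uM", "assumed", "vegf"),
    "n_SERCA": (2.0, "dimensionless", "assumed", "vegf"),
    "kleak_ER": (2e-5, "1/s", "assumed", "vegf"),
    "kcrac_on": (1e-3, "uM/s", "assumed", "vegf"),
    "K_crac": (100.0, "uM", "assumed", "vegf"),
    "kcrac_off": (1e-2, "1/s", "assumed", "vegf"),
    "kJcrac": (2e-6, "1/(uM*s)", "assumed", "vegf"),
    "kNCX": (2e-7, "1/(uM*s)", "fittable", "hypoxia"),
    "K_NCX_O2": (20.0, "uM", "assumed", "hypoxia"),
    "kPMCA": (0.2, "uM/s", "assumed", "vegf"),
    "Km_PMCA": (0.25, "uM", "assumed", "vegf"),
    "n_PMCA": (2.0, "dimensionless", "assumed", "vegf"),
    "kf_CaCaM": (0.1, "1/(uM*s)", "fittable", "vegf"),
    "kr_CaCaM": (0.05, "1/s", "assumed", "vegf"),
    "kon_DAGPKC": (1.0, "1/(uM*s)", "fittable", "vegf"),
    "koff_DAGPKC": (1e-2, "1/s", "assumed", "vegf"),
    "kon_capkc": (1.0, "1/(uM*s)", "assumed", "vegf"),
    "koff_capkc": (0.1, "1/s", "fittable", "vegf"),
    # Raf-MEK-ERK (+ S1P, Axl)
    "kRasAct": (0.2, "1/s", "assumed", "vegf"),
    "Km_Ras": (0.2, "uM", "assumed", "vegf"),
    "kRasGAP": (1e-2, "1/s", "fittable", "vegf"),
    "kf_Raf": (0.2, "1/s", "assumed", "vegf"),
    "Km_Raf": (0.5, "uM", "assumed", "vegf"),
    "kcatPKC": (0.1, "1/s", "fittable", "vegf"),
    "kmPKCRaf": (0.5, "uM", "fittable", "vegf"),
    "kdp_Raf": (0.02, "1/s", "assumed", "vegf"),
    "kf_MEK": (0.05, "1/s", "assumed", "vegf"),
    "Km_MEK": (0.5, "uM", "assumed", "vegf"),
    "kdp_MEK": (5e-3, "1/s", "assumed", "vegf"),
    "kcatERK": (0.01, "1/s", "fittable", "vegf"),
    "Km_ERK": (0.5, "uM", "assumed", "vegf"),
    "kdp_ERK": (5e-3, "1/s", "assumed", "vegf"),
    "kf_SK1": (0.05, "1/s", "assumed", "vegf"),
    "Km_SK1": (0.5, "uM", "assumed", "vegf"),
    "koffSK1": (1e-3, "1/s", "fittable", "vegf"),
    "kcatSK1Sph": (0.1, "1/s", "fittable", "vegf"),
    "Km_Sph": (1.0, "uM", "assumed", "vegf"),
    "kdpS1P": (1e-3, "1/s", "fittable", "vegf"),
    "kp_pAxl": (0.5, "1/(uM*s)", "fittable", "vegf"),
    "kdp_Axl": (1e-3, "1/s", "assumed", "vegf"),
}


@dataclass
class ECModelConfig:
    """Module toggles and overrides for :func:`build_two_cell_model`."""

    modules: tuple[str, ...] = MODULES
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    initial_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.modules:
            if m not in MODULES:
                raise ValueError(f"unknown module {m!r}; valid: {MODULES}")


def build_two_cell_model(config: ECModelConfig | None = None) -> ModelDefinition:
    """Construct the two-cell model.

    The two cell submodels are built from the same template (identical
    species, parameters and initial values); only the trans Dll4→Notch1
    binding couples them.  ``config.initial_overrides`` uses bare per-cell
    species names (applied to both cells) or suffixed names (``Dll4_c2``)
    for a single cell.
    """
    cfg = config or ECModelConfig()
    enabled = set(cfg.modules)
    ics = default_initial_conditions().values

    model = ModelDefinition(name="ec-two-cell")
    for pname, (val, units, status, group) in _PARAMS.items():
        model.parameters[pname] = Parameter(pname, val, units=units, status=status, group=group)
    for pname, val in cfg.parameter_overrides.items():
        if pname not in model.parameters:
            raise KeyError(f"parameter override for unknown canonical name {pname!r}")
        model.parameters[pname].value = val

    # shared environment species, bound to registry parameters
    model.species.append(Species("O2_env", "extracellular", is_constant=True,
                                 initial_from_param="O2"))
    model.species.append(Species("Caext_env", "extracellular", is_constant=True,
                                 initial_from_param="Caext"))

    for cell, vparam in (("c1", "Vext1"), ("c2", "Vext2")):
        comp = "cell1" if cell == "c1" else "cell2"
        model.species.append(Species(f"V_{cell}", "extracellular", is_constant=True,
                                     initial_from_param=vparam))
        for base, v0 in ics.items():
            name = f"{base}_{cell}"
            init = cfg.initial_overrides.get(name, cfg.initial_overrides.get(base, v0))
            model.species.append(Species(
                name, comp, initial_value=init,
                is_constant=base in _CONSTANT,
                is_state_flux=base in _STATE_FLUX))

    for cell, other in (("c1", "c2"), ("c2", "c1")):
        _add_cell_reactions(model, cell, other, enabled)

    model.observables = _observables()
    model.validate()
    return model


def _add_cell_reactions(model: ModelDefinition, cell: str, other: str,
                        enabled: set[str]) -> None:
    scope = "intra-cell1" if cell == "c1" else "intra-cell2"

    def s(base: str, c: str | None = None) -> str:
        return f"{base}_{c or cell}"

    def add(name, reactants, products, law="mass_action", lp=None, mods=None,
            module="", rscope=None):
        model.reactions.append(Reaction(
            name=f"{name}_{cell}", reactants=reactants, products=products,
            law=law, law_params=lp or {}, modifiers=mods or [],
            scope=rscope or scope, module=module))

    def ma(k):
        return {"k": k}

    def mm(vmax, km, substrate, enzyme=None):
        d = {"vmax": vmax, "km": km, "substrate": substrate}
        if enzyme:
            d["enzyme"] = enzyme
        return d

    def hill(vmax, k, n, substrate, enzyme=None):
        d = {"vmax": vmax, "k": k, "n": n, "substrate": substrate}
        if enzyme:
            d["enzyme"] = enzyme
        return d

    if "vegf" in enabled:
        add("vegf_r2_bind", [(s("V"), 1), (s("R2"), 1)], [(s("VR2"), 1)], lp=ma("kvr2on"), module="vegf")
        add("vegf_r2_unbind", [(s("VR2"), 1)], [(s("V"), 1), (s("R2"), 1)], lp=ma("kvr2off"), module="vegf")
        add("vr2_phos", [(s("VR2"), 1)], [(s("pVR2"), 1)], lp=ma("kp_vr2"), module="vegf")
        add("pvr2_dephos", [(s("pVR2"), 1)], [(s("VR2"), 1)], lp=ma("kdp_vr2"), module="vegf")
        add("pvr2_internalise", [(s("pVR2"), 1)], [(s("iR2"), 1)], lp=ma("kp_iVR2"), module="vegf")
        add("ir2_recycle", [(s("iR2"), 1)], [(s("R2"), 1)], lp=ma("krec_iR2"), module="vegf")
        add("ir2_degrade", [(s("iR2"), 1)], [], lp=ma("kdeg_iR2"), module="vegf")
        # Hes1 represses VEGFR2 production (Hill exponent n_HesR2)
        add("r2_production", [], [(s("R2"), 1)], lp=ma("kprod_R2"),
            mods=[Modifier(s("Hes1"), "inhibitor", "khesr2", "n_HesR2")], module="vegf")
        add("r2_degrade", [(s("R2"), 1)], [], lp=ma("kdeg_R2"), module="vegf")
        add("vr2_degrade", [(s("VR2"), 1)], [], lp=ma("kdeg_R2"), module="vegf")
        add("pvr2_degrade", [(s("pVR2"), 1)], [], lp=ma("kdeg_R2"), module="vegf")
        add("nrp1_r2_bind", [(s("NRP1"), 1), (s("VR2"), 1)], [(s("VR2N"), 1)],
            lp=ma("kNRP1VEGFR2on"), module="vegf")
        add("nrp1_r2_unbind", [(s("VR2N"), 1)], [(s("NRP1"), 1), (s("VR2"), 1)],
            lp=ma("kNRP1VEGFR2off"), module="vegf")
        add("vr2n_phos", [(s("VR2N"), 1)], [(s("pVR2"), 1), (s("NRP1"), 1)],
            lp=ma("kp_vr2n"), module="vegf")
        add("vr2n_degrade", [(s("VR2N"), 1)], [], lp=ma("kdegR2NRPnp"), module="vegf")
        add("nrp1_production", [], [(s("NRP1"), 1)], lp=ma("kprod_NRP1"), module="vegf")
        add("nrp1_degrade", [(s("NRP1"), 1)], [], lp=ma("kdeg_NRP1"), module="vegf")
        # VEGFR1: decoy receptor, Notch/Hes1-upregulated, no downstream signalling
        add("r1_production", [], [(s("R1"), 1)], lp=ma("kprod_R1"),
            mods=[Modifier(s("Hes1"), "activator", "kNotchR1")], module="vegf")
        add("r1_degrade", [(s("R1"), 1)], [], lp=ma("kdeg_R1"), module="vegf")
        add("vegf_r1_bind", [(s("V"), 1), (s("R1"), 1)], [(s("VR1"), 1)], lp=ma("kvr1on"), module="vegf")
        add("vegf_r1_unbind", [(s("VR1"), 1)], [(s("V"), 1), (s("R1"), 1)], lp=ma("kvr1off"), module="vegf")
        add("vr1_degrade", [(s("VR1"), 1)], [], lp=ma("kdeg_R1"), module="vegf")
        if "hif" in enabled:
            add("vauto_r1_bind", [(s("Vauto"), 1), (s("R1"), 1)], [(s("VR1"), 1)],
                lp=ma("kvr1on"), module="vegf")

    if "notch" in enabled:
        add("mnotch_production", [], [(s("mNotch1"), 1)], lp=ma("kform_Notch"), module="notch")
        add("mnotch_degrade", [(s("mNotch1"), 1)], [], lp=ma("kdeg_mNotch"), module="notch")
        add("notch_translate", [(s("mNotch1"), 1)], [(s("mNotch1"), 1), (s("Notch1"), 1)],
            lp=ma("ktransl_Notch"), module="notch")
        add("notch_degrade", [(s("Notch1"), 1)], [], lp=ma("kdeg_Notch1"), module="notch")
        # the ONLY trans interaction: neighbour Dll4 binds this cell's Notch1
        add("dll4_notch_trans", [(s("Dll4", other), 1), (s("Notch1"), 1)], [(s("NB"), 1)],
            lp=ma("ktrans_DllNotch"), module="notch", rscope="trans")
        add("nb_degrade", [(s("NB"), 1)], [], lp=ma("kdeg_NB"), module="notch")
        add("gs_production", [], [(s("Gs"), 1)], lp=ma("kform_Gs"), module="notch")
        add("gs_degrade", [(s("Gs"), 1)], [], lp=ma("kdeg_Gs"), module="notch")
        add("nicd_cleave", [(s("NB"), 1), (s("Gs"), 1)], [(s("NICD"), 1), (s("Gs"), 1)],
            lp=ma("kcleave"), module="notch")
        add("nicd_degrade", [(s("NICD"), 1)], [], lp=ma("kdeg_NICD"), module="notch")
        add("hes1_induction", [], [(s("Hes1"), 1)],
            law="hill", lp=hill("kp_He", "Km_He", "n_He", s("NICD")), module="notch")
        add("hes1_basal", [], [(s("Hes1"), 1)], lp=ma("kbasal_He"), module="notch")
        add("hes1_degrade", [(s("Hes1"), 1)], [], lp=ma("kdeg_He"), module="notch")
        # ERK induces Dll4 mRNA; Hes1 represses it (stalk cells silence Dll4)
        add("mdll4_production", [], [(s("mDll4"), 1)],
            law="hill", lp=hill("teta_ERKDll4", "K_ERKDll4", "n_ERKDll4", s("pERK")),
            mods=[Modifier(s("Hes1"), "inhibitor", "K_HeDll4", 4.0)], module="notch")
        add("mdll4_degrade", [(s("mDll4"), 1)], [], lp=ma("kdeg_mDll4"), module="notch")
        add("dll4_translate", [], [(s("Dll4"), 1)],
            law="michaelis_menten", lp=mm("ktransl_Dll4", "kp_Dll", s("mDll4")), module="notch")
        add("dll4_degrade", [(s("Dll4"), 1)], [], lp=ma("kdeg_Dll4"), module="notch")

    if "hif" in enabled:
        add("hif1a_translate", [], [(s("HIF1a"), 1)], lp=ma("ktranslmHIF1a"), module="hif")
        # O2-dependent (PHD/VHL) degradation: fast at normoxia, slow at 1% O2
        add("hif1a_degrade_o2", [(s("HIF1a"), 1)], [],
            law="michaelis_menten", lp=mm("kdeg_HIF1a", "Km_O2HIF", "O2_env"),
            module="hif")
        add("hif1a_degrade_basal", [(s("HIF1a"), 1)], [], lp=ma("kdeg_HIF1a_basal"), module="hif")
        add("hif2a_translate", [], [(s("HIF2a"), 1)], lp=ma("ktransl_HIF2a"), module="hif")
        add("hif2a_degrade_o2", [(s("HIF2a"), 1)], [],
            law="michaelis_menten", lp=mm("k12_degHIF1a", "delta_ox22", "O2_env"),
            module="hif")
        add("hif2a_degrade_basal", [(s("HIF2a"), 1)], [], lp=ma("kdeg_HIF1a_basal"), module="hif")
        # HIF1a and HIF2a drive VEGFA mRNA additively (two separate reactions)
        add("mvegfa_from_hif1", [(s("HIF1a"), 1), (s("HIF1b"), 1)],
            [(s("HIF1a"), 1), (s("HIF1b"), 1), (s("mVEGFA"), 1)], lp=ma("ktx_VEGFA"), module="hif")
        add("mvegfa_from_hif2", [(s("HIF2a"), 1), (s("HIF1b"), 1)],
            [(s("HIF2a"), 1), (s("HIF1b"), 1), (s("mVEGFA"), 1)], lp=ma("ktx_VEGFA"), module="hif")
        add("mvegfa_degrade", [(s("mVEGFA"), 1)], [], lp=ma("kdeg_mVEGFA"), module="hif")
        add("vauto_translate", [(s("mVEGFA"), 1)], [(s("mVEGFA"), 1), (s("Vauto"), 1)],
            lp=ma("ktransl_VEGFA"), module="hif")
        add("vauto_degrade", [(s("Vauto"), 1)], [], lp=ma("kdeg_Vauto"), module="hif")
        if "akt_enos" in enabled:
            add("enos_hif_sequester", [(s("eNOS"), 1), (s("HIF1a"), 1)],
                [(s("eNOSin"), 1), (s("HIF1a"), 1)], lp=ma("khif1eNOS"), module="hif")
            add("enos_hif_release", [(s("eNOSin"), 1)], [(s("eNOS"), 1)],
                lp=ma("krel_eNOS"), module="hif")

    if "akt_enos" in enabled:
        add("pip2_generate", [], [(s("PIP2"), 1)], lp=ma("kgenPIP2"), module="akt_enos")
        add("pip2_degrade", [(s("PIP2"), 1)], [], lp=ma("kdeg_PIP2"), module="akt_enos")
        add("pi3k_pip3", [(s("PIP2"), 1)], [(s("PIP3"), 1)],
            law="michaelis_menten", lp=mm("kcat_PI3K", "Km_PI3K", s("PIP2"), enzyme=s("pVR2")),
            mods=[Modifier(s("pAxl"), "activator", "Ka_Axl")], module="akt_enos")
        add("pip3_dephos", [(s("PIP3"), 1)], [(s("PIP2"), 1)], lp=ma("kdeg_PIP3"), module="akt_enos")
        add("akt_pip3_bind", [(s("Akt"), 1), (s("PIP3"), 1)], [(s("AktPIP3"), 1)],
            lp=ma("kf_AktPIP3"), module="akt_enos")
        add("akt_pip3_unbind", [(s("AktPIP3"), 1)], [(s("Akt"), 1), (s("PIP3"), 1)],
            lp=ma("kr_AktPIP3"), module="akt_enos")
        # autocrine VEGFA (Vauto) and S1P promote the survival arm here only
        add("akt_phos", [(s("AktPIP3"), 1)], [(s("pAkt"), 1), (s("PIP3"), 1)],
            lp=ma("kp_Akt"),
            mods=[Modifier(s("S1P"), "activator", "Ka_S1P"),
                  Modifier(s("Vauto"), "activator", "Ka_auto")], module="akt_enos")
        add("pakt_dephos", [(s("pAkt"), 1)], [(s("Akt"), 1)], lp=ma("kdp_Akt"), module="akt_enos")
        add("akt_production", [], [(s("Akt"), 1)], lp=ma("kformAkt"), module="akt_enos")
        add("akt_degrade", [(s("Akt"), 1)], [], lp=ma("kdeg_Akt"), module="akt_enos")
        add("pakt_hsp_bind", [(s("pAkt"), 1), (s("Hsp"), 1)], [(s("pAktHsp"), 1)],
            lp=ma("kf_paktHsp"), module="akt_enos")
        add("pakt_hsp_unbind", [(s("pAktHsp"), 1)], [(s("pAkt"), 1), (s("Hsp"), 1)],
            lp=ma("kr_paktHsp"), module="akt_enos")
        add("pakthsp_dephos", [(s("pAktHsp"), 1)], [(s("Akt"), 1), (s("Hsp"), 1)],
            lp=ma("kdpAkt"), module="akt_enos")
        add("pakt_degrade", [(s("pAkt"), 1)], [], lp=ma("kdeg_Akt"), module="akt_enos")
        add("pakthsp_degrade", [(s("pAktHsp"), 1)], [(s("Hsp"), 1)],
            lp=ma("kdeg_Akt"), module="akt_enos")
        add("enos_phos", [(s("eNOS"), 1)], [(s("peNOS"), 1)],
            law="michaelis_menten", lp=mm("kf_eNOSHSP", "Km_eNOS", s("eNOS"), enzyme=s("pAktHsp")),
            mods=[Modifier(s("CaCaM"), "activator", "Ka_CaCaM")], module="akt_enos")
        add("penos_dephos", [(s("peNOS"), 1)], [(s("eNOS"), 1)], lp=ma("kdp_eNOS"), module="akt_enos")
        add("no_production", [(s("peNOS"), 1)], [(s("peNOS"), 1), (s("NO"), 1)],
            lp=ma("kNO"), mods=[Modifier(s("CaCaM"), "activator", "Ka_CaCaM")], module="akt_enos")
        add("no_degrade", [(s("NO"), 1)], [], lp=ma("kdeg_NO"), module="akt_enos")

    if "calcium" in enabled:
        add("plc_phos", [(s("PLC"), 1)], [(s("pPLC"), 1)],
            law="michaelis_menten", lp=mm("kf_PLCy", "Km_PLC", s("PLC"), enzyme=s("pVR2")),
            module="calcium")
        add("plc_dephos", [(s("pPLC"), 1)], [(s("PLC"), 1)], lp=ma("kdp_PLCy"), module="calcium")
        add("plc_hydrolysis", [(s("PIP2"), 1)], [(s("IP3"), 1), (s("DAG"), 1)],
            law="michaelis_menten", lp=mm("kcat_PLCy", "KmPIP2PLCy", s("PIP2"), enzyme=s("pPLC")),
            module="calcium")
        add("ip3_degrade", [(s("IP3"), 1)], [], lp=ma("kdeg_IP3"), module="calcium")
        add("dag_degrade", [(s("DAG"), 1)], [], lp=ma("kdeg_DAG"), module="calcium")
        add("ip3r_release", [(s("ER"), 1)], [(s("Ca"), 1)],
            law="hill", lp=hill("kIP3R", "Km_IP3R", "n_IP3R", s("IP3")),
            module="calcium")
        add("serca_uptake", [(s("Ca"), 1)], [(s("ER"), 1)],
            law="hill", lp=hill("kSERCA", "Km_SERCA", "n_SERCA", s("Ca")), module="calcium")
        add("er_leak", [(s("ER"), 1)], [(s("Ca"), 1)], lp=ma("kleak_ER"), module="calcium")
        # CRAC current carried as a state variable, activated by store depletion
        add("jcrac_activate", [], [(s("Jcrac"), 1)], lp=ma("kcrac_on"),
            mods=[Modifier(s("ER"), "inhibitor", "K_crac", 2.0)], module="calcium")
        add("jcrac_decay", [(s("Jcrac"), 1)], [], lp=ma("kcrac_off"), module="calcium")
        add("crac_influx", [(s("Jcrac"), 1), ("Caext_env", 1)],
            [(s("Jcrac"), 1), ("Caext_env", 1), (s("Ca"), 1)], lp=ma("kJcrac"), module="calcium")
        # hypoxia-gated Na+/Ca2+ exchanger influx (O2 inhibits)
        add("ncx_influx", [("Caext_env", 1)], [("Caext_env", 1), (s("Ca"), 1)],
            lp=ma("kNCX"), mods=[Modifier("O2_env", "inhibitor", "K_NCX_O2", 2.0)],
            module="calcium")
        add("pmca_efflux", [(s("Ca"), 1)], [],
            law="hill", lp=hill("kPMCA", "Km_PMCA", "n_PMCA", s("Ca")), module="calcium")
        add("cacam_bind", [(s("Ca"), 1), (s("CaM"), 1)], [(s("CaCaM"), 1)],
            lp=ma("kf_CaCaM"), module="calcium")
        add("cacam_unbind", [(s("CaCaM"), 1)], [(s("Ca"), 1), (s("CaM"), 1)],
            lp=ma("kr_CaCaM"), module="calcium")
        add("dag_pkc_bind", [(s("DAG"), 1), (s("PKC"), 1)], [(s("DAGPKC"), 1)],
            lp=ma("kon_DAGPKC"), module="calcium")
        add("dag_pkc_unbind", [(s("DAGPKC"), 1)], [(s("DAG"), 1), (s("PKC"), 1)],
            lp=ma("koff_DAGPKC"), module="calcium")
        add("pkc_activate", [(s("DAGPKC"), 1), (s("Ca"), 1)], [(s("aPKC"), 1)],
            lp=ma("kon_capkc"), module="calcium")
        add("pkc_deactivate", [(s("aPKC"), 1)], [(s("DAGPKC"), 1), (s("Ca"), 1)],
            lp=ma("koff_capkc"), module="calcium")

    if "erk" in enabled:
        add("ras_activate", [(s("Ras"), 1)], [(s("RasGTP"), 1)],
            law="michaelis_menten", lp=mm("kRasAct", "Km_Ras", s("Ras"), enzyme=s("pVR2")),
            module="erk")
        add("ras_gap", [(s("RasGTP"), 1)], [(s("Ras"), 1)], lp=ma("kRasGAP"), module="erk")
        add("raf_phos_ras", [(s("Raf"), 1)], [(s("pRaf"), 1)],
            law="michaelis_menten", lp=mm("kf_Raf", "Km_Raf", s("Raf"), enzyme=s("RasGTP")),
            module="erk")
        add("raf_phos_pkc", [(s("Raf"), 1)], [(s("pRaf"), 1)],
            law="michaelis_menten", lp=mm("kcatPKC", "kmPKCRaf", s("Raf"), enzyme=s("aPKC")),
            module="erk")
        add("raf_dephos", [(s("pRaf"), 1)], [(s("Raf"), 1)], lp=ma("kdp_Raf"), module="erk")
        add("mek_phos", [(s("MEK"), 1)], [(s("pMEK"), 1)],
            law="michaelis_menten", lp=mm("kf_MEK", "Km_MEK", s("MEK"), enzyme=s("pRaf")),
            module="erk")
        add("mek_dephos", [(s("pMEK"), 1)], [(s("MEK"), 1)], lp=ma("kdp_MEK"), module="erk")
        add("erk_phos", [(s("ERK"), 1)], [(s("pERK"), 1)],
            law="michaelis_menten", lp=mm("kcatERK", "Km_ERK", s("ERK"), enzyme=s("pMEK")),
            module="erk")
        add("erk_dephos", [(s("pERK"), 1)], [(s("ERK"), 1)], lp=ma("kdp_ERK"), module="erk")
        add("sk1_activate", [(s("SK1"), 1)], [(s("aSK1"), 1)],
            law="michaelis_menten", lp=mm("kf_SK1", "Km_SK1", s("SK1"), enzyme=s("pERK")),
            module="erk")
        add("sk1_deactivate", [(s("aSK1"), 1)], [(s("SK1"), 1)], lp=ma("koffSK1"), module="erk")
        add("s1p_production", [(s("Sph"), 1)], [(s("Sph"), 1), (s("S1P"), 1)],
            law="michaelis_menten", lp=mm("kcatSK1Sph", "Km_Sph", s("Sph"), enzyme=s("aSK1")),
            module="erk")
        add("s1p_dephos", [(s("S1P"), 1)], [], lp=ma("kdpS1P"), module="erk")
        add("axl_phos", [(s("Axl"), 1), (s("pVR2"), 1)], [(s("pAxl"), 1), (s("pVR2"), 1)],
            lp=ma("kp_pAxl"), module="erk")
        add("axl_dephos", [(s("pAxl"), 1)], [(s("Axl"), 1)], lp=ma("kdp_Axl"), module="erk")


def _observables() -> dict[str, str]:
    obs: dict[str, str] = {}
    for c in ("c1", "c2"):
        obs[f"VEGFR2_{c}"] = f"R2_{c} + VR2_{c} + pVR2_{c} + VR2N_{c}"
        obs[f"pVEGFR2_{c}"] = f"pVR2_{c}"
        obs[f"VEGFR1_{c}"] = f"R1_{c} + VR1_{c}"
        obs[f"NICD_rel_Notch1_{c}"] = f"NICD_{c} / (Notch1_{c} + NB_{c} + NICD_{c} + 1e-30)"
        obs[f"pAkt_tot_{c}"] = f"pAkt_{c} + pAktHsp_{c}"
        obs[f"pPLCy_{c}"] = f"pPLC_{c}"
        for base in ("Hes1", "Dll4", "mDll4", "NICD", "NO", "Ca", "pERK",
                     "peNOS", "HIF1a", "HIF2a", "mVEGFA"):
            obs[f"{base}_{c}"] = f"{base}_{c}"
    return obs


#: Species names entering the ECPI for each cell (observable expressions).
ECPI_COMPONENTS = {
    c: {"hes1": f"Hes1_{c}", "vegfr1": f"VEGFR1_{c}",
        "dll4": f"Dll4_{c}", "vegfr2": f"VEGFR2_{c}"}
    for c in ("c1", "c2")
}
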