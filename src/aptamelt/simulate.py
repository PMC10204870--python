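"""Synthetic thermofluorimetric plate simulator.

Generates plate-style melt-curve datasets with the structure a TFA
(thermofluorimetric analysis) of an aptamer-target mixture produces: two
melting species — free aptamer at a lower Tm and target-bound aptamer at a
higher Tm — populated by a 1:1 binding equilibrium, read out by an
intercalating dye whose fluorescence is proportional to the folded fraction
of each species, on top of a linear baseline with i.i.d. Gaussian noise.

The default scan protocol mirrors a real-time PCR melt run: 4 to 80 deg C in
0.5 deg C steps, three replicate tubes per condition plus three buffer-only
blanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import MeltCurveSet

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987204259e-3

#: Celsius/Kelvin offset.
T0_KELVIN = 273.15

#: Default dissociation constant, nM. No experimental Kd is available for
#: the AP273-AFP pair, so this is a configurable placeholder chosen so the
#: standard 1.25-80 nM aptamer gradient spans sub- to super-saturation of a
#: ~1.45 nM target.
DEFAULT_KD_NM = 25.0


@dataclass(frozen=True)
class TwoStateSpecies:
    """A two-state melting species.

    Parameters
    ----------
    name : str
        Label, e.g. ``"free_aptamer"``.
    tm : float
        Melting temperature in deg C (the temperature of half-unfolding).
    dh_vh : float
        Apparent van 't Hoff unfolding enthalpy in kcal/mol; must be > 0.
        Larger values give sharper transitions.
    amplitude : float
        Fluorescence per unit folded concentration, a.u./nM.
    """

    name: str
    tm: float
    dh_vh: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.dh_vh <= 0:
            raise ValueError("dh_vh must be positive")


#: Default species for the free and target-bound aptamer. The bound aptamer
#: is target-stabilised, hence the higher Tm. Apparent van 't Hoff enthalpies
#: reflect the cooperative melting of a multi-stem ssDNA aptamer fold
#: (~8 kcal/mol per stacked base pair over 15+ bp of stem), which yields the
#: sharp, few-degree-wide derivative peaks seen in real-time PCR melt runs.
DEFAULT_FREE_SPECIES = TwoStateSpecies("free_aptamer", tm=35.0, dh_vh=110.0, amplitude=1.0)
DEFAULT_BOUND_SPECIES = TwoStateSpecies("bound_aptamer", tm=60.0, dh_vh=130.0, amplitude=1.0)


@dataclass(frozen=True)
class BindingSystem:
    """A 1:1 aptamer-target mixture with two melting species.

    The bound species must melt above the free species: target binding
    stabilises the aptamer fold.
    """

    aptamer_conc: float  # nM
    target_conc: float  # nM
    kd: float = DEFAULT_KD_NM  # nM
    free_species: TwoStateSpecies = DEFAULT_FREE_SPECIES
    bound_species: TwoStateSpecies = DEFAULT_BOUND_SPECIES

    def __post_init__(self) -> None:
        if self.aptamer_conc < 0 or self.target_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if not self.bound_species.tm > self.free_species.tm:
            raise ValueError("bound species must melt above the free species")

    def species_concentrations(self) -> dict[str, float]:
        """Equilibrium concentrations (nM) of the free and bound species."""
        fb = equilibrium_bound_fraction(self.aptamer_conc, self.target_conc, self.kd)
        bound = fb * self.aptamer_conc
        return {"free": self.aptamer_conc - bound, "bound": bound}


@dataclass(frozen=True)
class ScanProtocol:
    """Melt scan protocol and plate noise model.

    Defaults follow the standard TFA melt run: 4 to 80 deg C in 0.5 deg C
    steps, three replicate tubes per condition. ``noise_sd=None`` resolves
    to 1% of the maximum clean signal on the plate at simulation time.
    """

    t_start: float = 4.0
    t_end: float = 80.0
    t_step: float = 0.5
    replicates: int = 3
    noise_sd: float | None = None
    baseline_slope: float = -0.02  # a.u. per deg C; dye background bleaches slightly
    baseline_offset: float = 5.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.t_step <= 0:
            raise ValueError("t_step must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------


def folded_fraction(t_kelvin, species: TwoStateSpecies):
    """Two-state van 't Hoff folded fraction at absolute temperature.

    theta(T) = 1 / (1 + exp[-(dH_vH/R) (1/T - 1/Tm)])

    Strictly decreasing in T with theta(Tm) = 1/2; the transition sharpens
    as dh_vh grows. Accepts scalars or arrays of temperatures in kelvin.
    """
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    tm_k = species.tm + T0_KELVIN
    x = (species.dh_vh / R_KCAL) * (1.0 / t - 1.0 / tm_k)
    # logistic, stable for large |x|
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    return float(out) if np.isscalar(t_kelvin) else out


def equilibrium_bound_fraction(aptamer_conc: float, target_conc: float, kd: float) -> float:
    """Fraction of total aptamer bound at 1:1 mass-action equilibrium.

    For total aptamer A, total target P and dissociation constant Kd, the
    complex concentration C is the physical root of
    C^2 - C (A + P + Kd) + A P = 0; the bound fraction is C/A.

    Evaluated in the cancellation-free form 2AP / (s + sqrt(s^2 - 4AP)) with
    s = A + P + Kd, accurate to ~1e-15 relative across concentration scales.
    """
    if aptamer_conc < 0 or target_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if aptamer_conc == 0 or target_conc == 0:
        return 0.0
    s = aptamer_conc + target_conc + kd
    disc = s * s - 4.0 * aptamer_conc * target_conc
    complex_conc = 2.0 * aptamer_conc * target_conc / (s + np.sqrt(disc))
    return float(min(1.0, complex_conc / aptamer_conc))


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


def clean_signal(temperature_c: np.ndarray, system: BindingSystem, protocol: ScanProtocol) -> np.ndarray:
    """Noise-free fluorescence trace: baseline + additive species signals."""
    t_k = np.asarray(temperature_c, dtype=float) + T0_KELVIN
    conc = system.species_concentrations()
    signal = protocol.baseline_offset + protocol.baseline_slope * np.asarray(temperature_c)
    signal = signal + system.free_species.amplitude * conc["free"] * folded_fraction(t_k, system.free_species)
    signal = signal + system.bound_species.amplitude * conc["bound"] * folded_fraction(t_k, system.bound_species)
    return signal


def _resolve_noise_sd(protocol: ScanProtocol, max_signal: float) -> float:
    if protocol.noise_sd is not None:
        return protocol.noise_sd
    return 0.01 * abs(max_signal)


def _warn_tm_range(species: TwoStateSpecies, protocol: ScanProtocol) -> None:
    if not (protocol.t_start <= species.tm <= protocol.t_end):
        warnings.warn(
            f"{species.name}: Tm {species.tm} deg C lies outside the scan range "
            f"[{protocol.t_start}, {protocol.t_end}]",
            stacklevel=3,
        )


def simulate_plate(
    system: BindingSystem,
    protocol: ScanProtocol,
    condition_id: str = "cond1",
    buffer_id: str | None = None,
    n_blanks: int | None = None,
) -> MeltCurveSet:
    """Simulate one condition's replicate wells plus buffer-only blanks.

    Blank wells carry baseline + noise only. Fully reproducible for a fixed
    ``protocol.seed``.
    """
    return _simulate_conditions([(condition_id, system)], protocol, buffer_id, n_blanks)


def _simulate_conditions(
    conditions: list[tuple[str, BindingSystem]],
    protocol: ScanProtocol,
    buffer_id: str | None = None,
    n_blanks: int | None = None,
) -> MeltCurveSet:
    temperature = protocol.grid()
    rng = np.random.default_rng(protocol.seed)
    n_blanks = protocol.replicates if n_blanks is None else n_blanks

    for _, system in conditions:
        _warn_tm_range(system.free_species, protocol)
        _warn_tm_range(system.bound_species, protocol)

    clean = {cid: clean_signal(temperature, system, protocol) for cid, system in conditions}
    max_signal = max(float(np.max(np.abs(tr))) for tr in clean.values())
    sd = _resolve_noise_sd(protocol, max_signal)

    traces: dict[str, np.ndarray] = {}
    meta_rows = {}
    for cid, system in conditions:
        for rep in range(1, protocol.replicates + 1):
            well = f"{cid}_r{rep}"
            noise = rng.normal(0.0, sd, size=temperature.shape) if sd > 0 else 0.0
            traces[well] = clean[cid] + noise
            meta_rows[well] = {
                "condition_id": cid,
                "replicate": rep,
                "is_blank": False,
                "aptamer_conc": system.aptamer_conc,
                "buffer_id": buffer_id,
            }
    baseline = protocol.baseline_offset + protocol.baseline_slope * temperature
    for rep in range(1, n_blanks + 1):
        well = f"blank_r{rep}"
        noise = rng.normal(0.0, sd, size=temperature.shape) if sd > 0 else 0.0
        traces[well] = baseline + noise
        meta_rows[well] = {
            "condition_id": "blank",
            "replicate": rep,
            "is_blank": True,
            "aptamer_conc": 0.0,
            "buffer_id": buffer_id,
        }

    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "well"
    return MeltCurveSet(
        temperature=temperature,
        traces=traces,
        meta=meta,
        attrs={"seed": protocol.seed, "noise_sd": sd, "sign_convention": "-dF/dT"},
    )


def simulate_gradient(
    concs,
    target_conc: float,
    kd: float = DEFAULT_KD_NM,
    protocol: ScanProtocol = ScanProtocol(),
    free_species: TwoStateSpecies = DEFAULT_FREE_SPECIES,
    bound_species: TwoStateSpecies = DEFAULT_BOUND_SPECIES,
    buffer_id: str | None = None,
) -> MeltCurveSet:
    """Simulate a gradient of aptamer concentrations against a fixed target.

    One condition per concentration (labelled ``c<conc>nM``), each with
    ``protocol.replicates`` wells, plus one shared set of blank wells. As
    aptamer concentration grows the bound-species concentration saturates at
    the available target while the free species keeps increasing.
    """
    concs = list(concs)
    if not concs:
        raise ValueError("concentration list must be non-empty")
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive")
    conditions = [
        (
            f"c{c:g}nM",
            BindingSystem(
                aptamer_conc=float(c),
                target_conc=float(target_conc),
                kd=kd,
                free_species=free_species,
                bound_species=bound_species,
            ),
        )
        for c in concs
    ]
    return _simulate_conditions(conditions, protocol, buffer_id=buffer_id)


def gradient_conditions(concs) -> list[str]:
    """Condition IDs that :func:`simulate_gradient` assigns, in input order."""
    return [f"c{float(c):g}nM" for c in concs]


#: The standard 7-point aptamer gradient (nM) used against ~1.45 nM target.
STANDARD_GRADIENT_NM = (1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0)

#: Standard target concentration: 100 ng/mL AFP at ~69 kDa.
STANDARD_TARGET_NM = 1.45
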