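"""Reproducible end-to-end studies built from the analysis stages.

These are the package's own validation workflows: a seeded Tm/bound-ratio
recovery study (simulate -> preprocess -> deconvolve, compared against the
generating truth) and a noise-free aptamer-gradient area study that traces
how the free and bound peak areas respond to the binding equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import peaks as peaks_mod
from . import preprocess, simulate

#: Study conditions of the recovery harness: a balanced two-peak system so
#: both the free and the bound component carry comparable signal.
RECOVERY_SYSTEM = dict(aptamer_conc=20.0, target_conc=20.0, kd=5.0)


@dataclass
class RecoveryStudy:
    """Per-run Tm and bound-ratio recovery against the generating truth."""

    table: pd.DataFrame  # one row per seeded run
    median_abs_err_free: float  # deg C
    median_abs_err_bound: float  # deg C
    ratio_bias: float  # mean (measured - true) bound ratio
    all_converged: bool
    all_ordered: bool  # free Tm < bound Tm in every converged fit


def tm_recovery_study(n_runs: int = 20, base_seed: int = 0) -> RecoveryStudy:
    """Recover Tm 35/60 and the bound ratio from seeded noisy plates.

    Each run simulates a three-replicate plate of the balanced system at the
    default 1% noise on the standard 4-80 deg C / 0.5 deg C scan, processes
    it through the full pipeline and deconvolves the two peaks.
    """
    system = simulate.BindingSystem(**RECOVERY_SYSTEM)
    truth_ratio = simulate.equilibrium_bound_fraction(**RECOVERY_SYSTEM)
    rows = []
    for i in range(n_runs):
        seed = (base_seed * 100_003 + i) % 2**31
        plate = simulate.simulate_plate(system, simulate.ScanProtocol(seed=seed))
        curve = preprocess.process_condition(plate, "cond1")
        fit = peaks_mod.deconvolve_two_peaks(curve)
        ratio = peaks_mod.bound_ratio(fit) if fit.converged else np.nan
        rows.append(
            {
                "seed": seed,
                "converged": fit.converged,
                "tm_free": fit.free_peak.tm,
                "tm_bound": fit.bound_peak.tm,
                "err_free": fit.free_peak.tm - system.free_species.tm,
                "err_bound": fit.bound_peak.tm - system.bound_species.tm,
                "bound_ratio": ratio,
                "ratio_err": (ratio - truth_ratio) if ratio is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    conv = table[table["converged"]]
    return RecoveryStudy(
        table=table,
        median_abs_err_free=float(conv["err_free"].abs().median()),
        median_abs_err_bound=float(conv["err_bound"].abs().median()),
        ratio_bias=float(conv["ratio_err"].mean()),
        all_converged=bool(table["converged"].all()),
        all_ordered=bool((conv["tm_free"] < conv["tm_bound"]).all()),
    )


@dataclass
class GradientStudy:
    """Free/bound peak areas along the standard aptamer gradient (noise-free)."""

    table: pd.DataFrame
    bound_nondecreasing: bool
    free_increasing: bool


def gradient_area_study(seed: int = 0, concs=simulate.STANDARD_GRADIENT_NM) -> GradientStudy:
    """Noise-free gradient against the standard target; nonparametric areas.

    Areas come from detected peaks on blank-corrected (unnormalized) curves:
    absolute areas are what mass action constrains, whereas per-curve 0-100
    normalization rescales each condition to its own maximum.
    """
    protocol = simulate.ScanProtocol(noise_sd=0.0, seed=seed)
    plate = simulate.simulate_gradient(concs, simulate.STANDARD_TARGET_NM, protocol=protocol)
    curves = preprocess.process_plate(plate, normalized=False)
    rows = []
    for conc, cid in zip(concs, simulate.gradient_conditions(concs)):
        pks = peaks_mod.detect_peaks(curves[cid], min_prominence=0.005, min_separation=5.0)
        if len(pks) != 2:
            raise RuntimeError(f"expected a two-peak signature for {cid}, found {len(pks)}")
        free, bound = pks
        rows.append(
            {
                "condition_id": cid,
                "aptamer_conc": float(conc),
                "free_area": free.area,
                "bound_area": bound.area,
                "bound_true_nM": simulate.equilibrium_bound_fraction(
                    float(conc), simulate.STANDARD_TARGET_NM, simulate.DEFAULT_KD_NM
                )
                * float(conc),
            }
        )
    table = pd.DataFrame(rows)
    return GradientStudy(
        table=table,
        bound_nondecreasing=bool(np.all(np.diff(table["bound_area"]) >= -1e-9)),
        free_increasing=bool(np.all(np.diff(table["free_area"]) > 0)),
    )
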