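"""Melt-curve containers and the derivative-curve preprocessing pipeline.

Raw plate traces from a thermofluorimetric analysis (TFA) run are turned into
corrected, normalized derivative melting curves in a fixed order:

    average replicates -> derivative (-dF/dT) -> blank-correct -> normalize

Blanks are processed through the same averaging/derivative steps and the
subtraction happens on the derivative curves, mirroring how real-time PCR
melt exports are post-processed. Sign convention: instruments plot melting
as positive peaks, so :func:`derivative` returns the negative derivative
-dF/dT; axis labels elsewhere call it "dF/dT" for parity with such plots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.signal import savgol_filter

logger = logging.getLogger("aptamelt")

#: Tolerance on the uniformity of the temperature grid spacing, in deg C.
GRID_SPACING_TOL = 1e-9

#: Savitzky-Golay smoothing defaults for the derivative step.
DEFAULT_WINDOW = 7
DEFAULT_POLYORDER = 3

META_COLUMNS = ["well", "condition_id", "replicate", "is_blank", "aptamer_conc", "buffer_id"]


class GridMismatchError(ValueError):
    """Two curves that must share a temperature grid do not."""


@dataclass
class MeltCurveSet:
    """Raw plate fluorescence traces with well-level metadata.

    Parameters
    ----------
    temperature : ndarray
        Strictly increasing temperature grid in deg C with constant spacing.
    traces : dict[str, ndarray]
        Fluorescence series per well, each aligned to ``temperature``.
    meta : DataFrame
        One row per well, indexed by well ID, with columns ``condition_id``,
        ``replicate``, ``is_blank``, ``aptamer_conc`` (nM) and ``buffer_id``.
    """

    temperature: np.ndarray
    traces: dict[str, np.ndarray]
    meta: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.temperature.ndim != 1 or len(self.temperature) < 2:
            raise ValueError("temperature grid must be 1-D with >= 2 points")
        steps = np.diff(self.temperature)
        if np.any(steps <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.ptp(steps) > GRID_SPACING_TOL:
            raise ValueError("temperature grid spacing must be constant")
        n = len(self.temperature)
        for well, tr in self.traces.items():
            tr = np.asarray(tr, dtype=float)
            if tr.shape != (n,):
                raise ValueError(f"trace for well {well!r} does not match the grid length {n}")
            self.traces[well] = tr
        missing = set(self.traces) - set(self.meta.index)
        if missing:
            raise ValueError(f"wells without metadata: {sorted(missing)}")

    # -- selection helpers -------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        """Non-blank condition IDs in plate order."""
        m = self.meta[~self.meta["is_blank"]]
        return list(dict.fromkeys(m["condition_id"]))

    def wells_for(self, condition_id: str) -> list[str]:
        sel = self.meta[(self.meta["condition_id"] == condition_id) & (~self.meta["is_blank"])]
        if sel.empty:
            raise KeyError(f"unknown condition {condition_id!r}")
        return list(sel.index)

    def blank_wells(self) -> list[str]:
        return list(self.meta[self.meta["is_blank"]].index)

    # -- I/O ---------------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for well, tr in self.traces.items():
            m = self.meta.loc[well]
            rows.append(
                pd.DataFrame(
                    {
                        "well": well,
                        "condition_id": m["condition_id"],
                        "replicate": m["replicate"],
                        "is_blank": m["is_blank"],
                        "temperature_C": self.temperature,
                        "fluorescence": tr,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path, sample_sheet=None) -> None:
        """Write long-format CSV and, optionally, a YAML sample sheet."""
        self.to_long_frame().to_csv(path, index=False)
        if sample_sheet is not None:
            sheet = {
                well: {
                    "condition_id": str(m["condition_id"]),
                    "replicate": int(m["replicate"]),
                    "is_blank": bool(m["is_blank"]),
                    "aptamer_conc": None if pd.isna(m["aptamer_conc"]) else float(m["aptamer_conc"]),
                    "buffer_id": None if pd.isna(m["buffer_id"]) else str(m["buffer_id"]),
                }
                for well, m in self.meta.iterrows()
            }
            with open(sample_sheet, "w") as fh:
                yaml.safe_dump(sheet, fh, sort_keys=True)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, sheet: dict | None = None) -> "MeltCurveSet":
        traces: dict[str, np.ndarray] = {}
        meta_rows = {}
        temperature = None
        for well, grp in df.groupby("well", sort=False):
            grp = grp.sort_values("temperature_C")
            t = grp["temperature_C"].to_numpy(dtype=float)
            if temperature is None:
                temperature = t
            elif not np.allclose(t, temperature, atol=GRID_SPACING_TOL):
                raise GridMismatchError(f"well {well!r} is not aligned to the plate grid")
            traces[str(well)] = grp["fluorescence"].to_numpy(dtype=float)
            info = sheet.get(str(well), {}) if sheet else {}
            first = grp.iloc[0]
            meta_rows[str(well)] = {
                "condition_id": info.get("condition_id", first.get("condition_id", "cond")),
                "replicate": int(info.get("replicate", first.get("replicate", 0))),
                "is_blank": bool(info.get("is_blank", first.get("is_blank", False))),
                "aptamer_conc": info.get("aptamer_conc", first.get("aptamer_conc", np.nan)),
                "buffer_id": info.get("buffer_id", first.get("buffer_id", None)),
            }
        meta = pd.DataFrame.from_dict(meta_rows, orient="index")
        meta.index.name = "well"
        return cls(temperature=temperature, traces=traces, meta=meta)

    @classmethod
    def read_csv(cls, path, sample_sheet=None) -> "MeltCurveSet":
        """Read a plate export, auto-detecting long vs wide layout.

        Long layout has ``well``/``temperature_C``/``fluorescence`` columns
        (the simulator's dialect); a wide layout has one temperature column
        followed by one column per well.
        """
        df = pd.read_csv(path)
        sheet = None
        if sample_sheet is not None:
            with open(sample_sheet) as fh:
                sheet = yaml.safe_load(fh)
        cols = {c.lower() for c in df.columns}
        if {"well", "fluorescence"} <= cols:
            return cls.from_long_frame(df, sheet)
        # wide: first column is temperature, remaining columns are wells
        tcol = df.columns[0]
        long = df.melt(id_vars=[tcol], var_name="well", value_name="fluorescence")
        long = long.rename(columns={tcol: "temperature_C"})
        return cls.from_long_frame(long, sheet)


@dataclass
class DerivativeCurve:
    """A derivative melting curve (-dF/dT) on the interior temperature grid.

    ``stage`` tracks provenance through the pipeline: ``raw`` after the
    derivative step, ``corrected`` after blank subtraction, ``normalized``
    after the 0-100 rescale. ``degenerate`` flags constant input that could
    not be normalized.
    """

    temperature: np.ndarray
    dfdt: np.ndarray
    stage: str = "raw"
    condition_id: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.dfdt = np.asarray(self.dfdt, dtype=float)
        if self.temperature.shape != self.dfdt.shape:
            raise ValueError("temperature and dfdt must have equal length")


# ---------------------------------------------------------------------------
# pipeline operations
# ---------------------------------------------------------------------------


def average_replicates(curveset: MeltCurveSet, condition_id: str) -> np.ndarray:
    """Pointwise mean fluorescence over a condition's replicate wells."""
    wells = curveset.wells_for(condition_id)
    return np.mean([curveset.traces[w] for w in wells], axis=0)


def average_blanks(curveset: MeltCurveSet) -> np.ndarray:
    wells = curveset.blank_wells()
    if not wells:
        raise ValueError("plate has no blank wells; blank correction requires >= 1")
    return np.mean([curveset.traces[w] for w in wells], axis=0)


def derivative(
    temperature: np.ndarray,
    trace: np.ndarray,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    condition_id: str | None = None,
) -> DerivativeCurve:
    """Smoothed negative derivative -dF/dT of a fluorescence trace.

    Savitzky-Golay by default; ``window=1`` degrades to plain central finite
    differences (forward/backward at the ends). The negative sign makes
    melting transitions appear as positive peaks.
    """
    temperature = np.asarray(temperature, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > 1 and polyorder >= window:
        raise ValueError("polyorder must be < window")
    if len(trace) < window:
        raise ValueError("trace shorter than the smoothing window")
    dt = float(temperature[1] - temperature[0])
    if window == 1:
        dfdt = np.gradient(trace, dt)
    else:
        dfdt = savgol_filter(trace, window_length=window, polyorder=polyorder, deriv=1, delta=dt)
    return DerivativeCurve(temperature=temperature, dfdt=-dfdt, stage="raw", condition_id=condition_id)


def blank_correct(curve: DerivativeCurve, blank: DerivativeCurve) -> DerivativeCurve:
    """Subtract the blank's derivative curve pointwise."""
    if curve.temperature.shape != blank.temperature.shape or not np.allclose(
        curve.temperature, blank.temperature, atol=GRID_SPACING_TOL
    ):
        raise GridMismatchError("curve and blank temperature grids differ")
    return DerivativeCurve(
        temperature=curve.temperature,
        dfdt=curve.dfdt - blank.dfdt,
        stage="corrected",
        condition_id=curve.condition_id,
    )


def normalize(curve: DerivativeCurve) -> DerivativeCurve:
    """Affine rescale of a derivative curve to the 0-100 range.

    Invariant under any prior affine transform of the input. A constant
    (degenerate) curve cannot be rescaled; it maps to all zeros with a
    logged warning and ``degenerate=True`` rather than raising.
    """
    lo = float(np.min(curve.dfdt))
    hi = float(np.max(curve.dfdt))
    if hi - lo <= 0:
        logger.warning("normalize: constant curve for condition %s; returning zeros", curve.condition_id)
        return DerivativeCurve(
            temperature=curve.temperature,
            dfdt=np.zeros_like(curve.dfdt),
            stage="normalized",
            condition_id=curve.condition_id,
            degenerate=True,
        )
    vals = (curve.dfdt - lo) / (hi - lo) * 100.0
    return DerivativeCurve(
        temperature=curve.temperature,
        dfdt=vals,
        stage="normalized",
        condition_id=curve.condition_id,
    )


def process_condition(
    curveset: MeltCurveSet,
    condition_id: str,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    normalized: bool = True,
) -> DerivativeCurve:
    """Full pipeline for one condition: average, derive, blank-correct, normalize."""
    avg = average_replicates(curveset, condition_id)
    curve = derivative(curveset.temperature, avg, window, polyorder, condition_id)
    try:
        blank_avg = average_blanks(curveset)
    except ValueError:
        warnings.warn("no blank wells on plate; skipping blank correction")
        corrected = DerivativeCurve(curve.temperature, curve.dfdt, "corrected", condition_id)
    else:
        blank_curve = derivative(curveset.temperature, blank_avg, window, polyorder, "blank")
        corrected = blank_correct(curve, blank_curve)
    return normalize(corrected) if normalized else corrected


def process_plate(
    curveset: MeltCurveSet,
    window: int = DEFAULT_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
    normalized: bool = True,
) -> dict[str, DerivativeCurve]:
    """Run the pipeline for every non-blank condition on the plate."""
    return {
        cid: process_condition(curveset, cid, window, polyorder, normalized)
        for cid in curveset.conditions
    }


def curves_to_frame(curves: dict[str, DerivativeCurve]) -> pd.DataFrame:
    """Tidy long-format table of processed curves (for CSV export)."""
    rows = []
    for cid, c in curves.items():
        rows.append(
            pd.DataFrame(
                {
                    "condition_id": cid,
                    "temperature_C": c.temperature,
                    "dfdt": c.dfdt,
                    "stage": c.stage,
                    "sign_convention": "-dF/dT",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
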