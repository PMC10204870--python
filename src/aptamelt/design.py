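"""Orthogonal buffer design, ionic strength and condition ranking.

A 4-factor, 3-level (L9) orthogonal array lets nine buffers cover all
pairwise combinations of the varied metal ions (Mg2+, Na+, K+, Ca2+) with
strength-2 balance: every level appears three times per column and every
ordered level pair of any two columns appears exactly once. The canonical
construction works over GF(3) — for run indices (a, b) in {0,1,2}^2 the four
columns are a, b, a+b and a+2b (mod 3); a seed reproducibly permutes the
level-to-symbol assignment of each column.

The module also computes buffer ionic strength I = 1/2 * sum(c_i z_i^2) with
or without the chloride counter-ions brought in by the metal salts, and
ranks buffer conditions by their melt-derived responses (bound-peak Tm,
with peak area and buffer ID as tie-breaks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

logger = logging.getLogger("aptamelt")

N_LEVELS = 3
N_FACTORS = 4

#: Canonical factor labels for the metal-ion design.
ION_FACTORS = ("Mg", "Na", "K", "Ca")

#: Charges of the varied metal ions.
ION_CHARGES = {"Mg": 2, "Na": 1, "K": 1, "Ca": 2}

#: Concentration levels (mM) screened for each metal ion.
ION_LEVELS = {
    "Mg": (1.0, 2.0, 5.0),
    "Na": (100.0, 120.0, 140.0),
    "K": (2.0, 4.0, 5.0),
    "Ca": (1.0, 2.0, 2.5),
}


@dataclass(frozen=True)
class BufferComposition:
    """An ionic buffer: (species, charge, concentration mM) plus optional buffer salt."""

    buffer_id: str
    ions: tuple  # of (species, charge, concentration_mM)
    buffer_salt: tuple | None = None  # (name, concentration_mM), a 1:1 monovalent salt

    def __post_init__(self) -> None:
        for species, charge, conc in self.ions:
            if conc < 0:
                raise ValueError(f"{species}: concentration must be >= 0")
            if int(charge) == 0 or charge != int(charge):
                raise ValueError(f"{species}: charge must be a nonzero integer")


@dataclass
class OrthogonalDesign:
    """An L9 orthogonal array with named factors and per-factor level values."""

    factors: tuple
    levels: dict  # factor -> tuple of 3 values
    array: np.ndarray  # (9, 4) level indices in {0,1,2}
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Runs as actual level values, one row per buffer."""
        data = {
            f: [self.levels[f][i] for i in self.array[:, j]]
            for j, f in enumerate(self.factors)
        }
        df = pd.DataFrame(data)
        df.insert(0, "buffer_id", [str(i + 1) for i in range(len(df))])
        return df


@dataclass
class ValidationResult:
    passed: bool
    diagnostics: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def generate_design(factors=ION_FACTORS, levels=None, seed: int = 300) -> OrthogonalDesign:
    """Build the seeded L9 array for 4 factors at 3 levels each.

    The GF(3) construction guarantees strength-2 orthogonality; the seed
    permutes which symbol each level index maps to, column by column, so
    different seeds give different (but always valid) L9 fractions.
    """
    factors = tuple(factors)
    if levels is None:
        levels = {f: ION_LEVELS[f] for f in factors} if set(factors) <= set(ION_LEVELS) else None
    if levels is None or len(factors) != N_FACTORS or any(len(levels[f]) != N_LEVELS for f in factors):
        raise ValueError("this release supports exactly 4 factors with 3 levels each")

    base = np.array([[a, b, (a + b) % 3, (a + 2 * b) % 3] for a, b in product(range(3), repeat=2)])
    rng = np.random.default_rng(seed)
    array = np.empty_like(base)
    for j in range(N_FACTORS):
        perm = rng.permutation(N_LEVELS)
        array[:, j] = perm[base[:, j]]
    design = OrthogonalDesign(factors=factors, levels=dict(levels), array=array, seed=seed)
    check = validate_orthogonality(array)
    assert check.passed, check.diagnostics  # construction guarantee
    return design


def validate_orthogonality(array) -> ValidationResult:
    """Exhaustive strength-2 check of a candidate L9 array.

    Verifies the run count (levels^2 = 9), per-column level balance (each
    level exactly 3 times) and pairwise coverage (each of the 9 ordered
    level pairs exactly once per column pair). No sampling.
    """
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError("design array must be rectangular (2-D)")
    n_runs, n_cols = arr.shape
    diags: list[str] = []
    if n_runs != N_LEVELS**2:
        diags.append(f"run count {n_runs} != {N_LEVELS**2} (L9 requires levels^2 runs)")
    for j in range(n_cols):
        vals, counts = np.unique(arr[:, j], return_counts=True)
        if len(vals) != N_LEVELS or not np.all(counts == n_runs // N_LEVELS):
            diags.append(f"column {j}: level counts {dict(zip(vals.tolist(), counts.tolist()))} are unbalanced")
    for j, k in combinations(range(n_cols), 2):
        pairs = {}
        for row in arr:
            pairs[(row[j], row[k])] = pairs.get((row[j], row[k]), 0) + 1
        bad = {p: c for p, c in pairs.items() if c != 1}
        if len(pairs) != N_LEVELS**2 or bad:
            diags.append(f"columns ({j}, {k}): pair coverage violated ({len(pairs)} distinct pairs)")
    return ValidationResult(passed=not diags, diagnostics=diags)


# ---------------------------------------------------------------------------
# the nine-buffer ion table (packaged fixture)
# ---------------------------------------------------------------------------

#: Metal-ion concentrations (mM) of the nine orthogonally designed buffers,
#: columns Mg2+, Na+, K+, Ca2+; HEPES-Na 20 mM is the shared buffer salt.
TABLE1_IONS_MM = {
    "1": (1.0, 120.0, 5.0, 2.5),
    "2": (5.0, 100.0, 4.0, 2.5),
    "3": (2.0, 140.0, 2.0, 2.5),
    "4": (5.0, 140.0, 5.0, 1.0),
    "5": (2.0, 100.0, 5.0, 2.0),
    "6": (1.0, 100.0, 2.0, 1.0),
    "7": (1.0, 140.0, 4.0, 2.0),
    "8": (5.0, 120.0, 2.0, 2.0),
    "9": (2.0, 120.0, 4.0, 1.0),
}

BUFFER_SALT = ("HEPES-Na", 20.0)


def table1_buffers(buffer_salt: tuple | None = BUFFER_SALT) -> list[BufferComposition]:
    """The nine-buffer fixture as :class:`BufferComposition` objects."""
    out = []
    for bid, concs in TABLE1_IONS_MM.items():
        ions = tuple(
            (f, ION_CHARGES[f], c) for f, c in zip(ION_FACTORS, concs)
        )
        out.append(BufferComposition(buffer_id=bid, ions=ions, buffer_salt=buffer_salt))
    return out


def table1_frame() -> pd.DataFrame:
    """The nine-buffer fixture as a tidy table (buffer_id, Mg_mM, Na_mM, K_mM, Ca_mM)."""
    rows = [
        {"buffer_id": bid, **{f"{f}_mM": c for f, c in zip(ION_FACTORS, concs)}}
        for bid, concs in TABLE1_IONS_MM.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ionic strength
# ---------------------------------------------------------------------------


def ionic_strength(
    buffer: BufferComposition,
    include_counterions: bool = True,
    include_buffer_salt: bool = False,
) -> float:
    """Ionic strength I = 1/2 * sum(c_i z_i^2), in mM.

    With ``include_counterions`` the chloride (or, for anions, sodium)
    counter-ions that the listed salts bring along are added
    stoichiometrically: a cation at concentration c and charge z contributes
    z*c of a monovalent counter-ion. The buffer salt, when included, is
    treated as a fully dissociated 1:1 monovalent salt.
    """
    total = 0.0
    for _species, charge, conc in buffer.ions:
        total += conc * charge**2
        if include_counterions:
            total += abs(charge) * conc  # monovalent counter-ion, z^2 = 1
    if include_buffer_salt and buffer.buffer_salt is not None:
        _name, conc = buffer.buffer_salt
        total += 2 * conc  # 1:1 salt: c*1^2 for each of the two ions
    return 0.5 * total


def ionic_strength_table(
    buffers, include_counterions: bool = True, include_buffer_salt: bool = False
) -> pd.Series:
    """Ionic strength of each buffer, indexed by buffer_id (mM)."""
    return pd.Series(
        {
            b.buffer_id: ionic_strength(b, include_counterions, include_buffer_salt)
            for b in buffers
        },
        name="ionic_strength_mM",
    )


# ---------------------------------------------------------------------------
# response analysis
# ---------------------------------------------------------------------------


@dataclass
class RankResult:
    order: list  # buffer_ids, best first
    selected: list  # top-k buffer_ids
    table: pd.DataFrame
    excluded: list


def rank_conditions(
    tm_responses: dict,
    areas: dict | None = None,
    k: int = 3,
) -> RankResult:
    """Rank buffers by mean bound-peak Tm, best (highest) first.

    ``tm_responses`` maps buffer_id to replicate Tm values (deg C). Ties are
    broken by bound-peak area (descending) then buffer_id (ascending).
    Buffers with missing responses are excluded and logged.
    """
    if len(tm_responses) < 2:
        raise ValueError("ranking requires >= 2 conditions")
    areas = areas or {}
    rows = []
    excluded = []
    for bid, reps in tm_responses.items():
        reps = [] if reps is None else list(np.atleast_1d(reps))
        if not reps or any(not np.isfinite(v) for v in reps):
            excluded.append(bid)
            logger.warning("rank_conditions: buffer %s has missing responses; excluded", bid)
            continue
        rows.append(
            {
                "buffer_id": bid,
                "tm_mean": float(np.mean(reps)),
                "n": len(reps),
                "area": float(areas.get(bid, 0.0)),
            }
        )
    if not rows:
        raise ValueError("no condition has usable responses")
    table = pd.DataFrame(rows).sort_values(
        by=["tm_mean", "area", "buffer_id"], ascending=[False, False, True], kind="mergesort"
    )
    table = table.reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    order = list(table["buffer_id"])
    return RankResult(order=order, selected=order[:k], table=table, excluded=excluded)


def main_effects(design: OrthogonalDesign, responses) -> pd.DataFrame:
    """Per-factor, per-level mean response over the design's runs.

    In an orthogonal array each level of each factor is seen in exactly
    ``runs / levels`` runs, so the mean of any factor's level means equals
    the grand mean.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape != (design.array.shape[0],):
        raise ValueError("need exactly one response per design run")
    rows = []
    for j, f in enumerate(design.factors):
        for li, value in enumerate(design.levels[f]):
            mask = design.array[:, j] == li
            rows.append(
                {
                    "factor": f,
                    "level": value,
                    "mean_response": float(responses[mask].mean()),
                    "n_runs": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def mass_to_molar(mass_conc_ng_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert ng/mL to nM: nM = (ng/mL) / (g/mol) * 1e3.

    e.g. a 69 kDa protein at 100 ng/mL is 1.45 nM (2 d.p.).
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be positive")
    if mass_conc_ng_per_ml < 0:
        raise ValueError("mass concentration must be >= 0")
    return mass_conc_ng_per_ml / molar_mass_g_per_mol * 1e3
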