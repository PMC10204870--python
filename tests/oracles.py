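"""Independent oracles and toy-fixture builders shared across the test suite.

Every function here recomputes a quantity by a route independent of the
implementation it checks: bisection for the binding equilibrium, plain loops
for means/fluctuations, exhaustive double loops for hydrogen bonds and
contacts, a quaternion grid search (plus simplex polish) for minimal RMSD,
and textbook normal equations for ordinary least squares.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from aptamelt.structmetrics import COVALENT_H_DIST, Trajectory

# ---------------------------------------------------------------------------
# binding equilibrium
# ---------------------------------------------------------------------------


def bisection_bound_fraction(a_tot: float, p_tot: float, kd: float, tol: float = 1e-14) -> float:
    """Solve the 1:1 mass-action balance (A-C)(P-C) = Kd*C by bisection."""
    if a_tot == 0 or p_tot == 0:
        return 0.0
    lo, hi = 0.0, min(a_tot, p_tot)

    def g(c):
        return (a_tot - c) * (p_tot - c) - kd * c

    # g decreases from A*P > 0 to -Kd*min(A,P) <= 0 on [lo, hi]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi) / a_tot


# ---------------------------------------------------------------------------
# elementary loop oracles
# ---------------------------------------------------------------------------


def loop_mean(traces) -> np.ndarray:
    traces = [np.asarray(t) for t in traces]
    out = np.zeros_like(traces[0], dtype=float)
    for i in range(len(out)):
        s = 0.0
        for t in traces:
            s += t[i]
        out[i] = s / len(traces)
    return out


def central_difference(y: np.ndarray, dt: float) -> np.ndarray:
    """Central differences in the interior, one-sided at the ends."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    out[0] = (y[1] - y[0]) / dt
    out[-1] = (y[-1] - y[-2]) / dt
    for i in range(1, len(y) - 1):
        out[i] = (y[i + 1] - y[i - 1]) / (2 * dt)
    return out


def ols_normal_equations(x, y) -> tuple[float, float, float]:
    """Slope, intercept, r^2 from the textbook normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(slope), float(intercept), r2


def two_pass_rmsf(frames: np.ndarray) -> np.ndarray:
    """Per-atom RMSF by the direct two-pass formula, plain loops."""
    n_frames, n_atoms, _ = frames.shape
    out = np.zeros(n_atoms)
    for i in range(n_atoms):
        mean = np.zeros(3)
        for m in range(n_frames):
            mean += frames[m, i]
        mean /= n_frames
        acc = 0.0
        for m in range(n_frames):
            d = frames[m, i] - mean
            acc += float(d @ d)
        out[i] = math.sqrt(acc / n_frames)
    return out


# ---------------------------------------------------------------------------
# minimal-RMSD oracle: quaternion grid search + simplex polish
# ---------------------------------------------------------------------------


def grid_search_rmsd(frame_a: np.ndarray, frame_b: np.ndarray, n_grid: int = 9) -> float:
    """Minimal RMSD over proper rotations, found without the Kabsch algorithm.

    Dense grid over unit quaternions (n_grid points per component) followed
    by a Nelder-Mead polish on the rotation-vector parametrization starting
    from the best grid point.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    axis = np.linspace(-1.0, 1.0, n_grid)
    q = np.stack(np.meshgrid(axis, axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 4)
    norms = np.linalg.norm(q, axis=1)
    q = q[norms > 1e-9] / norms[norms > 1e-9, None]
    mats = Rotation.from_quat(q).as_matrix()  # (M, 3, 3)
    rotated = np.einsum("mij,nj->mni", mats, a)
    costs = np.mean(np.sum((rotated - b[None]) ** 2, axis=2), axis=1)
    best = np.argmin(costs)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        d = a @ r.T - b
        return float(np.mean(np.sum(d**2, axis=1)))

    start = Rotation.from_matrix(mats[best]).as_rotvec()
    res = minimize(cost, start, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return math.sqrt(min(res.fun, float(costs[best])))


# ---------------------------------------------------------------------------
# exhaustive geometric oracles
# ---------------------------------------------------------------------------


def brute_force_hbonds(coords, atoms: pd.DataFrame, dist_cutoff: float, angle_cutoff: float) -> set:
    """All (donor, acceptor) pairs meeting the geometric criteria, by double loop."""
    coords = np.asarray(coords, dtype=float)
    el = list(atoms["element"])
    res = list(zip(atoms["chain"], atoms["resnum"]))
    n = len(el)
    h_of = {
        i: [j for j in range(n) if el[j] == "H" and np.linalg.norm(coords[i] - coords[j]) <= COVALENT_H_DIST]
        for i in range(n)
        if el[i] in ("N", "O")
    }
    have_h = any(e == "H" for e in el)
    found = set()
    for d in range(n):
        if el[d] not in ("N", "O"):
            continue
        if have_h and not h_of[d]:
            continue
        for a in range(n):
            if el[a] not in ("N", "O") or a == d or res[a] == res[d]:
                continue
            if np.linalg.norm(coords[d] - coords[a]) > dist_cutoff:
                continue
            if have_h:
                ok = False
                for h in h_of[d]:
                    v1 = coords[d] - coords[h]
                    v2 = coords[a] - coords[h]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = math.degrees(math.acos(max(-1.0, min(1.0, float(cosang)))))
                    if ang >= angle_cutoff:
                        ok = True
                if not ok:
                    continue
            found.add((d, a))
    return found


def brute_force_contacts(coords, atoms: pd.DataFrame, sel_a, sel_b, cutoff: float) -> set:
    """Distinct residue pairs with any heavy-atom pair below cutoff, by double loop."""
    coords = np.asarray(coords, dtype=float)
    el = list(atoms["element"])
    res = list(zip(atoms["chain"], atoms["resnum"]))
    pairs = set()
    for i in sel_a:
        if el[i] == "H":
            continue
        for j in sel_b:
            if el[j] == "H":
                continue
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                pairs.add((res[i], res[j]))
    return pairs


# ---------------------------------------------------------------------------
# toy structure builders
# ---------------------------------------------------------------------------


def make_atoms(spec) -> pd.DataFrame:
    """Atom table from (name, element, resname, resnum, chain) tuples."""
    rows = [
        {"serial": i + 1, "name": nm, "element": elx, "resname": rn, "resnum": num, "chain": ch}
        for i, (nm, elx, rn, num, ch) in enumerate(spec)
    ]
    return pd.DataFrame(rows)


def random_complex(seed: int, n_res_a: int = 4, n_res_b: int = 3, with_h: bool = True) -> Trajectory:
    """A random two-chain toy complex: small 'protein' chain A near 'nucleic' chain B.

    Atoms are scattered in two adjacent 8 A boxes so some interfacial pairs
    fall inside typical hydrogen-bond/contact cutoffs and some do not.
    """
    rng = np.random.default_rng(seed)
    spec = []
    coords = []
    for r in range(n_res_a):
        base = rng.uniform(0, 8, size=3)
        for nm, elx in (("N", "N"), ("CA", "C"), ("O", "O")) + ((("H", "H"),) if with_h else ()):
            spec.append((nm, elx, "GLY", r + 1, "A"))
            if elx == "H":
                # covalently attach to this residue's N
                coords.append(coords[-3] + _rand_unit(rng) * rng.uniform(0.95, 1.1))
            else:
                coords.append(base + rng.uniform(-1.5, 1.5, size=3))
    for r in range(n_res_b):
        base = rng.uniform(0, 8, size=3) + np.array([6.0, 0.0, 0.0])
        for nm, elx in (("P", "P"), ("O5'", "O"), ("N1", "N")) + ((("H1", "H"),) if with_h else ()):
            spec.append((nm, elx, "DT", r + 1, "B"))
            if elx == "H":
                coords.append(coords[-1] + _rand_unit(rng) * rng.uniform(0.95, 1.1))
            else:
                coords.append(base + rng.uniform(-1.5, 1.5, size=3))
    return Trajectory(coords=np.array(coords)[None], atoms=make_atoms(spec))


def _rand_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def rigid_transform(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply a random proper rotation + translation to a coordinate frame."""
    rng = np.random.default_rng(seed)
    rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    shift = rng.uniform(-20, 20, size=3)
    return coords @ rot.T + shift
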