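"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity from first principles along a different
code path from the package: plain pairwise loops for forces and torques,
a hand-written conditional cascade for the secondary-structure rules, and
a quaternion-search minimiser for superposition RMSD.  They are kept
deliberately naive.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

KC = 1.439964  # e^2/(4 pi eps0), eV nm


# -------------------------------------------------------------- forces

def brute_force_on_site(i, positions, charges, hydro, eps_rel, beta):
    """Plain pairwise-loop Coulomb + displacement force on site i (eV/nm)."""
    total = np.zeros(3)
    for j in range(len(positions)):
        if abs(i - j) <= 1:
            continue
        rvec = positions[i] - positions[j]
        d = np.sqrt((rvec**2).sum())
        u = rvec / d
        total = total + (KC / eps_rel) * charges[i] * charges[j] / d**2 * u
        if hydro[i] > 0.0:
            total = total + beta * charges[j] ** 2 / d**5 * u
    return total


def brute_torque(pivot, positions, charges, hydro, eps_rel, beta, thermal):
    """Signed torque about the pivot-bond axis via explicit cross products.

    The mobile flank is the smaller one (ties -> C side); ``thermal`` maps
    block position -> extra force vector.
    """
    n = len(positions)
    left = list(range(0, pivot + 1))
    right = list(range(pivot + 1, n))
    block = left if len(left) < len(right) else right
    axis = positions[pivot + 1] - positions[pivot]
    axis = axis / np.sqrt((axis**2).sum())
    tau = np.zeros(3)
    for slot, i in enumerate(block):
        f = brute_force_on_site(i, positions, charges, hydro, eps_rel, beta)
        f = f + thermal[slot]
        tau = tau + np.cross(positions[i] - positions[pivot], f)
    return float(tau @ axis)


# -------------------------------------------------- secondary structure

def _helix_case(n, sq, pq, sh, qi):
    if n in (1, 2):
        return (
            (0.0 < sq < 0.2 and pq > 0.0)
            or (sq < -0.5 and abs(pq) <= 1e-12)
            or (len(qi) > 0 and qi[0] > 0.9 and sh < -0.3)
            or (0.1 < sq < 0.5 and pq < 0.0)
        )
    if n in (3, 4):
        return (sq > 1.0 and len(qi) >= 2 and qi[0] != qi[1]) or (
            abs(sq) < 0.5 and sh < -6.0
        )
    if n in (5, 6):
        return (
            (0.3 < sq < 0.5)
            or abs(sq) > 1.0
            or all(q > 0.0 for q in qi)
            or max(abs(q) for q in qi) > 0.6
        )
    return False


def direct_scan_labels(q, h, philic):
    """Hand-written scan: helix brackets then beta windows, H/E/C labels.

    ``philic[i]`` is True for hydrophilic residues.  Bracket sums run over
    the whole bracket; the charge product over the intervening residues.
    """
    n = len(q)
    lab = ["C"] * n
    i = 0
    while i < n:
        if not philic[i]:
            i += 1
            continue
        close = -1
        for j in range(i + 1, min(i + 6, n - 1) + 1):
            if philic[j]:
                close = j
                break
        if close < 0:
            i += 1
            continue
        inner = list(range(i + 1, close))
        sq = sum(q[k] for k in range(i, close + 1))
        sh = sum(h[k] for k in range(i, close + 1))
        pq = 1.0
        for k in inner:
            pq *= q[k]
        if not inner:
            pq = 0.0
        qi = [q[k] for k in inner]
        if inner and _helix_case(len(inner), sq, pq, sh, qi):
            for k in range(i, close + 1):
                lab[k] = "H"
            i = close + 1
        else:
            i = close
    i = 0
    while i <= n - 5:
        if all(lab[i + k] == "C" for k in range(5)):
            saq = sum(abs(q[i + k]) for k in range(5))
            sh = sum(h[i + k] for k in range(5))
            if saq - sh < 0.3 and sh > 0.1:
                for k in range(5):
                    lab[i + k] = "E"
                i += 5
                continue
        i += 1
    return "".join(lab)


# ----------------------------------------------------------------- RMSD

def brute_rmsd(A, B, n_grid=4000, seed=7):
    """Minimum superposition RMSD by quaternion search + simplex refine."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)

    def cost(quat):
        quat = np.asarray(quat)
        nrm = np.sqrt((quat**2).sum())
        if nrm == 0:
            return np.inf
        R = Rotation.from_quat(quat / nrm).as_matrix()
        d = Ac - Bc @ R.T
        return np.sqrt((d**2).sum() / len(A))

    rng = np.random.default_rng(seed)
    quats = rng.standard_normal((n_grid, 4))
    best = min(quats, key=cost)
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return float(res.fun)
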