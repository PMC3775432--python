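"""The three explicit forces, entropy-modified mobility, and drift speed.

Internal units are nm / elementary charge e / eV, so force is eV/nm.  The
Coulomb prefactor e^2/(4 pi eps_0) = 1.439964 eV nm keeps every quantity
of order one.

Forces acting between coarse sites:

  Coulomb       F = q1 q2 / (4 pi eps r^2), screened by the uniform water
                dielectric eps_w = 78 eps_0; repulsive for like signs.
  displacement  F = beta |q|^2 / r^5, acting on hydrophobic (nonpolar)
                sites, directed strictly away from the charge: polar water
                drawn toward the field sweeps nonpolar matter out of it.
  thermal       an isotropic random force of fixed magnitude gamma k T,
                the generalized-force equivalent of diffusion.

A fourth contribution, global entropy change, is not a force: it rescales
the mobility.  Writing the lumped entropy-temperature energy scale as dST,
a proposed move carries

    mu(sign) = D / (k T - sign * dST),   sign in {+1, 0, -1},

so entropy-increasing moves (sign +1) proceed with higher mobility than
entropy-decreasing ones, and dST = 0 recovers the Einstein relation
mu = D / kT.  Drift speed is mu * F.

Neither beta nor gamma is a measured constant; both are calibrated:
beta so the displacement force on a nonpolar site at 0.1 nm from a unit
charge matches the screened Coulomb force between unit charges at that
distance, gamma so the thermal force is 10% of the screened unit-charge
Coulomb force at 0.5 nm (strong close-range pairs must overwhelm thermal
noise early in folding).  Both remain plain config scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .chain_model import CoarseChain

__all__ = [
    "ForceFieldParams",
    "ForceVector",
    "COULOMB_EV_NM",
    "BOLTZMANN_EV_PER_K",
    "coulomb_force",
    "displacement_force",
    "thermal_force",
    "mobility",
    "drift_speed",
    "net_force_on_site",
    "pairwise_force_table",
    "DegenerateGeometryError",
]

#: e^2 / (4 pi eps_0) in eV nm (vacuum Coulomb prefactor for unit charges).
COULOMB_EV_NM = 1.439964

#: Boltzmann constant in eV / K.
BOLTZMANN_EV_PER_K = 8.617333e-5

#: Relative dielectric of water used throughout.
EPS_REL_WATER = 78.0


class DegenerateGeometryError(ValueError):
    """Coincident interaction sites (zero separation)."""


class ParameterError(ValueError):
    """A parameter configuration with no physical meaning (e.g. mu <= 0)."""


def _default_beta() -> float:
    # beta |q|^2 / r^5 == kC q^2 / (eps_rel r^2) at r = 0.1 nm, unit charge
    r = 0.1
    return COULOMB_EV_NM / EPS_REL_WATER * r**3


def _default_gamma() -> float:
    # gamma k T = 0.1 * screened Coulomb force of unit charges at 0.5 nm,
    # evaluated at T = 300 K; gamma itself is temperature independent.
    f_ref = 0.1 * COULOMB_EV_NM / EPS_REL_WATER / 0.5**2
    return f_ref / (BOLTZMANN_EV_PER_K * 300.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """All constants of the force/mobility model (nm, e, eV unit system).

    dST is the lumped global entropy-temperature energy scale (eV) by
    which a move's mobility denominator shifts; it is an opaque magnitude
    knob, not a tabulated physical constant, and must stay below kT for
    entropy-increasing moves to remain well defined.
    """

    temperature_K: float = 300.0
    eps_rel: float = EPS_REL_WATER
    beta: float = field(default_factory=_default_beta)
    gamma: float = field(default_factory=_default_gamma)
    D: float = 1.0  # diffusivity, nm^2 per simulation time unit
    dST: float = 0.005  # eV; 0 disables the entropy bias
    k: float = BOLTZMANN_EV_PER_K

    def __post_init__(self) -> None:
        if self.temperature_K < 0:
            raise ParameterError("temperature must be >= 0 K")
        for name in ("eps_rel", "beta", "gamma", "D", "k"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if self.dST < 0:
            raise ParameterError("dST must be >= 0")

    @property
    def kT(self) -> float:
        return self.k * self.temperature_K

    @property
    def coulomb_prefactor(self) -> float:
        """Screened prefactor q1 q2 kC / eps_rel, eV nm per e^2."""
        return COULOMB_EV_NM / self.eps_rel


@dataclass(frozen=True)
class ForceVector:
    components: np.ndarray  # (3,) eV/nm
    source: str  # coulomb | displacement | thermal | net
    site: int = -1

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.components)):
            raise ValueError("force components must be finite")

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.components))


def coulomb_force(
    q1: float,
    q2: float,
    r: np.ndarray | float,
    eps_rel: float = EPS_REL_WATER,
) -> np.ndarray | float:
    """Screened Coulomb force of charge 2 on charge 1.

    With a separation *vector* ``r`` pointing from site 2 to site 1, the
    returned vector acts on site 1 (positive product -> repulsion, i.e.
    along +r).  With a scalar ``r`` the signed magnitude is returned
    (positive = repulsive).
    """
    vec = isinstance(r, np.ndarray)
    d = float(np.linalg.norm(r)) if vec else float(r)
    if d <= 0.0:
        raise DegenerateGeometryError("Coulomb force at zero separation")
    mag = COULOMB_EV_NM / eps_rel * q1 * q2 / d**2
    if not vec:
        return mag
    return mag * (np.asarray(r, dtype=float) / d)


def displacement_force(
    q: float, r: np.ndarray | float, beta: float | None = None
) -> np.ndarray | float:
    """Dielectric displacement force of a charge q on a nonpolar site.

    Magnitude beta |q|^2 / r^5, always directed away from the charge (a
    vector ``r`` must point charge -> nonpolar site).  Scalar ``r`` returns
    the magnitude.
    """
    if beta is None:
        beta = _default_beta()
    vec = isinstance(r, np.ndarray)
    d = float(np.linalg.norm(r)) if vec else float(r)
    if d <= 0.0:
        raise DegenerateGeometryError("displacement force at zero separation")
    mag = beta * q * q / d**5
    if not vec:
        return mag
    return mag * (np.asarray(r, dtype=float) / d)


def thermal_force(
    params: ForceFieldParams, rng: np.random.Generator
) -> np.ndarray:
    """One isotropic thermal force draw: magnitude gamma k T exactly.

    The direction is uniform on the sphere (normalized Gaussian triple)
    and fully determined by the generator state, so seeded runs repeat.
    """
    if params.temperature_K == 0.0:
        rng.standard_normal(3)  # keep the stream aligned across temperatures
        return np.zeros(3)
    v = rng.standard_normal(3)
    norm = np.linalg.norm(v)
    while norm == 0.0:  # pragma: no cover - probability zero
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
    return (params.gamma * params.kT / norm) * v


def mobility(params: ForceFieldParams, entropy_change_sign: int = 0) -> float:
    """Entropy-modified drift mobility, nm^2 / (eV * time unit).

    sign +1: the proposed move increases global entropy (higher mobility);
    sign -1: it decreases entropy (lower mobility); 0 or dST = 0 gives the
    plain Einstein relation D / kT.
    """
    if entropy_change_sign not in (-1, 0, 1):
        raise ValueError("entropy_change_sign must be -1, 0 or +1")
    if params.temperature_K == 0.0:
        raise ParameterError("mobility undefined at T = 0 (kT = 0)")
    denom = params.kT - entropy_change_sign * params.dST
    if denom <= 0.0:
        raise ParameterError(
            f"mobility denominator kT - sign*dST = {denom:g} <= 0; lower dST"
        )
    return params.D / denom


def drift_speed(mu: float, F: float) -> float:
    """Drift speed mu * F (length / time)."""
    if mu < 0:
        raise ValueError("mobility must be >= 0")
    return mu * F


# --------------------------------------------------------------------------
# Chain-level force summation

def pairwise_force_table(chain: "CoarseChain", params: ForceFieldParams) -> np.ndarray:
    """Deterministic (Coulomb + displacement) force on every site, (n,3).

    Site j exerts on site i: the screened Coulomb force when both carry
    charge, plus the displacement push away from j when site i is
    hydrophobic (h_i > 0) and j is charged.  Self-interactions and
    nearest bonded neighbours are excluded.  Vectorized over all pairs.
    """
    pos = chain.positions
    n = len(pos)
    if n < 2:
        return np.zeros((n, 3))
    diff = pos[:, None, :] - pos[None, :, :]  # diff[i, j] = r_j -> r_i
    dist = np.linalg.norm(diff, axis=2)
    idx = np.arange(n)
    excluded = np.abs(idx[:, None] - idx[None, :]) <= 1
    interacting = ~excluded
    if np.any(dist[interacting] == 0.0):
        raise DegenerateGeometryError("coincident non-bonded sites")
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_d = np.where(dist > 0, 1.0 / dist, 0.0)
    q = chain.charges
    coul = params.coulomb_prefactor * (q[:, None] * q[None, :]) * inv_d**2
    nonpolar_i = (chain.hydrophobicity > 0.0).astype(float)
    disp = params.beta * (q[None, :] ** 2) * inv_d**5 * nonpolar_i[:, None]
    mag = np.where(interacting, coul + disp, 0.0)
    unit = diff * inv_d[:, :, None]
    return np.einsum("ij,ijk->ik", mag, unit)


def net_force_on_site(
    site: int,
    chain: "CoarseChain",
    params: ForceFieldParams,
    rng: np.random.Generator | None = None,
    thermal: np.ndarray | None = None,
) -> ForceVector:
    """Summed Coulomb + displacement + one thermal draw on one site.

    ``thermal`` may supply a pre-drawn thermal vector (used when an
    external caller wants to share draws with an independent check);
    otherwise one draw is taken from ``rng``; with neither, the thermal
    term is omitted.
    """
    n = len(chain.positions)
    if n < 2:
        raise ValueError("chain must have at least 2 sites")
    total = pairwise_force_table(chain, params)[site].copy()
    if thermal is not None:
        total += np.asarray(thermal, dtype=float)
    elif rng is not None:
        total += thermal_force(params, rng)
    return ForceVector(components=total, source="net", site=site)
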