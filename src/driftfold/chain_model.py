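"""Coarse-grained Calpha chain: tagging, templates, coarse-graining, pivots.

The chain is a list of 3D sites.  Each site carries the charge and
hydrophobicity of the residues it represents (side-chain properties are
assigned to the backbone site), a residue span, and a rigid-group id.
Consecutive sites are joined by *pivot bonds*; a folding move rotates one
whole flank of the chain rigidly about a pivot-bond axis.

Secondary-structure regions are inserted as ideal immutable templates
(helix: 0.15 nm rise and 100 deg turn per residue about the axis; strand:
0.35 nm extended rise), their interior pivots frozen, and may then be
*coarse-grained*: a whole rigid region collapses to a single effective
site at its centroid carrying the summed charge and hydrophobicity.  The
member geometry is retained in a body frame so the full Calpha trace can
be re-expanded after folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .residue_props import AnnotatedSequence
from .ss_rules import SecondaryStructureAnnotation

__all__ = [
    "CoarseChain",
    "PivotBond",
    "SSTemplate",
    "RigidBody",
    "DEFAULT_TEMPLATES",
    "VIRTUAL_BOND_NM",
    "build_extended_chain",
    "insert_templates",
    "coarse_grain_regions",
    "rotate_about_pivot",
    "expand_to_residues",
    "radius_of_gyration",
    "FrozenPivotError",
]

#: Canonical Calpha-Calpha virtual bond length, nm.
VIRTUAL_BOND_NM = 0.38


class FrozenPivotError(RuntimeError):
    """Attempt to rotate about a frozen pivot bond."""


@dataclass
class PivotBond:
    """Rotatable bond between consecutive sites (i, i+1).

    ``win_count`` counts consecutive max-torque wins; once it reaches the
    engine's freeze threshold the pivot is frozen for the rest of the run.
    """

    i: int
    frozen: bool = False
    win_count: int = 0

    @property
    def site_pair(self) -> tuple[int, int]:
        return (self.i, self.i + 1)


@dataclass(frozen=True)
class SSTemplate:
    """Ideal-geometry parameters for one secondary-structure kind."""

    kind: str  # "helix" | "strand"
    rise_per_residue: float  # nm along the template axis
    turn_per_residue: float  # degrees about the axis (0 for strands)
    radius: float = 0.0  # nm, helical radius of the Calpha trace

    def local_coords(self, n: int) -> np.ndarray:
        """(n,3) template coordinates, first site at origin, axis = +x."""
        i = np.arange(n, dtype=float)
        if self.turn_per_residue == 0.0 or self.radius == 0.0:
            coords = np.column_stack([self.rise_per_residue * i, 0 * i, 0 * i])
        else:
            phase = np.deg2rad(self.turn_per_residue) * i
            coords = np.column_stack(
                [
                    self.rise_per_residue * i,
                    self.radius * np.cos(phase),
                    self.radius * np.sin(phase),
                ]
            )
        return coords - coords[0]


DEFAULT_TEMPLATES: Mapping[str, SSTemplate] = {
    "H": SSTemplate("helix", rise_per_residue=0.15, turn_per_residue=100.0, radius=0.23),
    "E": SSTemplate("strand", rise_per_residue=0.35, turn_per_residue=0.0),
}


@dataclass
class RigidBody:
    """Body-frame record that lets a coarse site re-expand to residues.

    ``offsets`` are member-Calpha positions relative to the site position
    in the body frame at coarse-graining time; ``rotation`` accumulates
    every rigid rotation applied to the site afterwards.
    """

    residue_indices: tuple[int, ...]
    offsets: np.ndarray  # (m, 3)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def world_coords(self, site_position: np.ndarray) -> np.ndarray:
        return site_position + self.offsets @ self.rotation.T


@dataclass
class CoarseChain:
    """Ordered coarse sites with tags, pivots and re-expansion records."""

    positions: np.ndarray  # (n, 3) nm
    charges: np.ndarray  # (n,) e
    hydrophobicity: np.ndarray  # (n,) scale units
    spans: list[tuple[int, int]]  # residue span represented by each site
    rigid_group: np.ndarray  # (n,) int, -1 = no group
    pivots: list[PivotBond]
    bodies: dict[int, RigidBody] = field(default_factory=dict)
    bond_length: float = VIRTUAL_BOND_NM
    n_residues: int = 0

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.charges) == len(self.hydrophobicity) == len(self.spans) == n):
            raise ValueError("site arrays must share one length")
        if len(self.pivots) != max(n - 1, 0):
            raise ValueError("need exactly n-1 pivot bonds")
        if self.n_residues == 0:
            self.n_residues = max(e for _, e in self.spans) + 1 if self.spans else 0

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def copy(self) -> "CoarseChain":
        return CoarseChain(
            positions=self.positions.copy(),
            charges=self.charges.copy(),
            hydrophobicity=self.hydrophobicity.copy(),
            spans=list(self.spans),
            rigid_group=self.rigid_group.copy(),
            pivots=[replace(p) for p in self.pivots],
            bodies={
                k: RigidBody(b.residue_indices, b.offsets.copy(), b.rotation.copy())
                for k, b in self.bodies.items()
            },
            bond_length=self.bond_length,
            n_residues=self.n_residues,
        )

    def unfrozen_pivots(self) -> list[PivotBond]:
        return [p for p in self.pivots if not p.frozen]

    def total_charge(self) -> float:
        return float(self.charges.sum())


def build_extended_chain(
    seq: AnnotatedSequence, bond_length: float = VIRTUAL_BOND_NM
) -> CoarseChain:
    """One collinear site per residue at ``bond_length`` spacing along +x."""
    n = len(seq)
    positions = np.zeros((n, 3))
    positions[:, 0] = bond_length * np.arange(n)
    return CoarseChain(
        positions=positions,
        charges=np.asarray(seq.q, dtype=float),
        hydrophobicity=np.asarray(seq.h, dtype=float),
        spans=[(i, i) for i in range(n)],
        rigid_group=np.full(n, -1, dtype=int),
        pivots=[PivotBond(i) for i in range(n - 1)],
        bond_length=bond_length,
        n_residues=n,
    )


def insert_templates(
    chain: CoarseChain,
    ss: SecondaryStructureAnnotation,
    templates: Mapping[str, SSTemplate] = DEFAULT_TEMPLATES,
) -> CoarseChain:
    """Replace each H/E region by immutable ideal geometry.

    The chain is rebuilt site by site along +x (intended for a freshly
    built extended chain, before any folding move): unstructured residues
    continue at the virtual bond spacing, template regions are spliced in
    with their axis along the chain direction.  Region sites share a
    rigid-group id and every pivot interior to a region is frozen.
    """
    if len(ss) != chain.n_residues:
        raise ValueError("annotation length must match chain residues")
    region_of: dict[int, int] = {}
    for gid, (start, end, kind) in enumerate(ss.regions):
        for r in range(start, end + 1):
            if r in region_of:
                raise ValueError("overlapping secondary-structure regions")
            region_of[r] = gid

    out = chain.copy()
    n = chain.n_sites
    positions = np.zeros((n, 3))
    rigid = np.full(n, -1, dtype=int)
    cursor = np.zeros(3)
    placed_first = False
    i = 0
    while i < n:
        r0 = chain.spans[i][0]
        gid = region_of.get(r0)
        if gid is None:
            positions[i] = cursor if not placed_first else cursor + np.array(
                [chain.bond_length, 0.0, 0.0]
            )
            cursor = positions[i]
            placed_first = True
            i += 1
            continue
        start, end, kind = ss.regions[gid]
        m = end - start + 1
        local = templates[kind].local_coords(m)
        anchor = cursor if not placed_first else cursor + np.array(
            [chain.bond_length, 0.0, 0.0]
        )
        block = anchor + local
        positions[i : i + m] = block
        rigid[i : i + m] = gid
        cursor = block[-1]
        placed_first = True
        i += m

    out.positions = positions
    out.rigid_group = rigid
    for p in out.pivots:
        gi, gj = rigid[p.i], rigid[p.i + 1]
        if gi >= 0 and gi == gj:
            p.frozen = True
    return out


def coarse_grain_regions(chain: CoarseChain) -> CoarseChain:
    """Collapse each rigid region to one effective site at its centroid.

    The site carries the summed charge and hydrophobicity of its members
    and a body-frame record of their geometry for later re-expansion;
    unstructured sites pass through unchanged.  With no rigid regions the
    chain is returned as a copy, unchanged.
    """
    groups = chain.rigid_group
    if np.all(groups < 0):
        return chain.copy()
    positions, charges, hydro, spans = [], [], [], []
    bodies: dict[int, RigidBody] = {}
    i = 0
    while i < chain.n_sites:
        g = groups[i]
        if g < 0:
            positions.append(chain.positions[i])
            charges.append(chain.charges[i])
            hydro.append(chain.hydrophobicity[i])
            spans.append(chain.spans[i])
            i += 1
            continue
        members = [j for j in range(i, chain.n_sites) if groups[j] == g]
        block = chain.positions[members]
        centroid = block.mean(axis=0)
        new_index = len(positions)
        positions.append(centroid)
        charges.append(float(chain.charges[members].sum()))
        hydro.append(float(chain.hydrophobicity[members].sum()))
        spans.append((chain.spans[members[0]][0], chain.spans[members[-1]][1]))
        bodies[new_index] = RigidBody(
            residue_indices=tuple(
                r
                for j in members
                for r in range(chain.spans[j][0], chain.spans[j][1] + 1)
            ),
            offsets=block - centroid,
        )
        i = members[-1] + 1
    n_new = len(positions)
    return CoarseChain(
        positions=np.asarray(positions),
        charges=np.asarray(charges),
        hydrophobicity=np.asarray(hydro),
        spans=spans,
        rigid_group=np.full(n_new, -1, dtype=int),
        pivots=[PivotBond(i) for i in range(n_new - 1)],
        bodies=bodies,
        bond_length=chain.bond_length,
        n_residues=chain.n_residues,
    )


def mobile_block(chain: CoarseChain, pivot: int) -> tuple[np.ndarray, int]:
    """Indices of the flank that moves for this pivot, and its direction.

    The smaller flank moves (ties break to the C-terminal side); the
    returned direction is -1 for the N-side block (sites 0..pivot) and +1
    for the C-side block (sites pivot+1..end).
    """
    n = chain.n_sites
    n_left = pivot + 1
    n_right = n - pivot - 1
    if n_left < n_right:
        return np.arange(0, pivot + 1), -1
    return np.arange(pivot + 1, n), +1


def rotate_about_pivot(
    chain: CoarseChain, pivot: int, theta: float, inplace: bool = False
) -> CoarseChain:
    """Rotate the mobile flank rigidly by ``theta`` about the pivot bond.

    The axis is the unit vector from site ``pivot`` to site ``pivot+1``
    and the rotation line passes through site ``pivot``; the sign of
    ``theta`` follows the right-hand rule about that axis.  Frozen pivots
    reject the move.
    """
    if not 0 <= pivot < chain.n_sites - 1:
        raise IndexError(f"pivot {pivot} out of range")
    bond = chain.pivots[pivot]
    if bond.frozen:
        raise FrozenPivotError(f"pivot {pivot} is frozen")
    out = chain if inplace else chain.copy()
    if theta == 0.0:
        return out
    axis = out.positions[pivot + 1] - out.positions[pivot]
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise ValueError("degenerate pivot bond (coincident sites)")
    rot = Rotation.from_rotvec(theta * axis / norm)
    block, _ = mobile_block(out, pivot)
    origin = out.positions[pivot]
    out.positions[block] = origin + rot.apply(out.positions[block] - origin)
    mat = rot.as_matrix()
    for idx in block:
        body = out.bodies.get(int(idx))
        if body is not None:
            body.rotation = mat @ body.rotation
    return out


def expand_to_residues(chain: CoarseChain) -> np.ndarray:
    """Per-residue Calpha coordinates, (n_residues, 3).

    Coarse-grained sites re-expand through their body frames; per-residue
    sites contribute their own position.  A chain that was never
    coarse-grained (one site per residue) expands to its site positions.
    """
    coords = np.zeros((chain.n_residues, 3))
    seen = np.zeros(chain.n_residues, dtype=bool)
    for i in range(chain.n_sites):
        body = chain.bodies.get(i)
        if body is not None:
            world = body.world_coords(chain.positions[i])
            for k, r in enumerate(body.residue_indices):
                coords[r] = world[k]
                seen[r] = True
        else:
            r0, r1 = chain.spans[i]
            for r in range(r0, r1 + 1):
                coords[r] = chain.positions[i]
                seen[r] = True
    if not seen.all():
        raise ValueError("expansion mapping does not cover every residue")
    return coords


def curl_chain(chain: CoarseChain, angle: float = 0.15) -> CoarseChain:
    """Bend the chain into a gentle deterministic 3D curl.

    A perfectly collinear chain is a fixed point of bond-axis pivot
    rotations (every site lies on every rotation axis, so no torque can
    act and no move changes anything); folding must start from a
    non-collinear, physically permissible conformation.  This bends the
    chain at every pivot by ``angle`` radians about axes perpendicular to
    the local bond (alternating between two perpendicular directions, so
    the curve is genuinely three-dimensional), rotating each C-terminal
    tail rigidly: all bond lengths and intra-body geometry are preserved
    exactly.
    """
    out = chain.copy()
    perp = (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    for k in range(out.n_sites - 1):
        bond = out.positions[k + 1] - out.positions[k]
        bond = bond / np.linalg.norm(bond)
        axis = perp[k % 2] - (perp[k % 2] @ bond) * bond
        norm = np.linalg.norm(axis)
        if norm < 1e-12:  # bond parallel to the probe axis: use the other
            axis = perp[(k + 1) % 2] - (perp[(k + 1) % 2] @ bond) * bond
            norm = np.linalg.norm(axis)
        rot = Rotation.from_rotvec(angle * axis / norm)
        tail = np.arange(k + 1, out.n_sites)
        origin = out.positions[k]
        out.positions[tail] = origin + rot.apply(out.positions[tail] - origin)
        mat = rot.as_matrix()
        for idx in tail:
            body = out.bodies.get(int(idx))
            if body is not None:
                body.rotation = mat @ body.rotation
    return out


def radius_of_gyration(coords: np.ndarray) -> float:
    """Root-mean-square distance of points from their centroid."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))
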