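"""Potentials and exact energy bookkeeping for the two-chain system.

The vesicle is a closed bead-spring ring (N+1 beads, N+1 bonds including
the closure bond) carrying FENE bonds and intra-chain Morse excluded
volume but no bending energy ("soft" vesicle).  The polymer is a linear
chain (N+1 beads, N bonds) carrying the same FENE and Morse terms plus a
bending penalty ``kappa * (1 + cos(theta))`` at each of its N-1 interior
vertices.  The two chains interact only through a truncated
Lennard-Jones well of depth ``eps_vp``::

    U_VP(r) = eps_vp * [ (rm/r)^12 - 2 (rm/r)^6 ],   r <= lj_cutoff

whose minimum is exactly ``-eps_vp`` at ``r = lj_rm``.  Any bond whose
length leaves the open interval (l_min, l_max) makes the configuration
invalid: its FENE energy is +inf and a Metropolis move producing it is
always rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .params import ModelParams

Role = Literal["vesicle", "polymer"]


# ---------------------------------------------------------------------------
# scalar / array potentials
# ---------------------------------------------------------------------------

def fene_energy(l, params: ModelParams):
    """FENE bond energy -(k r0^2 / 2) ln[1 - ((l-l0)/r0)^2].

    Diverges (returns +inf) for bond lengths at or outside
    (l_min, l_max); raises for non-positive lengths.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("bond length must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l - params.l0) / params.r0
        inside = (l > params.l_min) & (l < params.l_max)
        e = np.where(
            inside,
            -0.5 * params.fene_k * params.r0**2 * np.log(np.where(inside, 1.0 - t * t, 1.0)),
            np.inf,
        )
    return float(e) if e.ndim == 0 else e


def morse_energy(r, params: ModelParams):
    """Morse pair energy eps*(e^{-2a(r-rmin)} - 2 e^{-a(r-rmin)}), truncated
    (unshifted) at ``morse_cutoff``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    x = np.exp(-params.morse_alpha * (r - params.morse_rmin))
    e = params.morse_eps * (x * x - 2.0 * x)
    e = np.where(r <= params.morse_cutoff, e, 0.0)
    return float(e) if e.ndim == 0 else e


def lj_energy(r, params: ModelParams):
    """Vesicle-polymer LJ energy eps_vp*[(rm/r)^12 - 2 (rm/r)^6], truncated
    (unshifted) at ``lj_cutoff``; the well depth is exactly ``-eps_vp`` at
    ``r = lj_rm``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    s6 = (params.lj_rm / r) ** 6
    e = params.eps_vp * (s6 * s6 - 2.0 * s6)
    e = np.where(r <= params.lj_cutoff, e, 0.0)
    return float(e) if e.ndim == 0 else e


def vertex_angle(p_prev, p_mid, p_next) -> float:
    """Interior angle at ``p_mid`` between the rays to ``p_prev`` and
    ``p_next``, in [0, pi]; a straight chain gives pi."""
    a = np.asarray(p_prev, dtype=float) - np.asarray(p_mid, dtype=float)
    b = np.asarray(p_next, dtype=float) - np.asarray(p_mid, dtype=float)
    na = np.hypot(a[0], a[1])
    nb = np.hypot(b[0], b[1])
    if na == 0.0 or nb == 0.0:
        raise ValueError("vertex angle undefined for coincident points")
    c = np.clip((a @ b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(c))


def bending_energy(theta, params: ModelParams):
    """Bending energy kappa*(1 + cos(theta)): 0 for a straight vertex
    (theta = pi), 2*kappa for a fully folded one (theta = 0)."""
    theta = np.asarray(theta, dtype=float)
    e = params.kappa * (1.0 + np.cos(theta))
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# topology and configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainTopology:
    """Connectivity of one chain: the vesicle ring or the linear polymer."""

    role: Role
    n_beads: int

    @property
    def closed(self) -> bool:
        return self.role == "vesicle"

    @property
    def bending_active(self) -> bool:
        return self.role == "polymer"

    @property
    def bond_pairs(self) -> list[tuple[int, int]]:
        n = self.n_beads
        pairs = [(i, i + 1) for i in range(n - 1)]
        if self.closed:
            pairs.append((n - 1, 0))
        return pairs

    def are_bonded(self, i: int, j: int) -> bool:
        d = abs(i - j)
        return d == 1 or (self.closed and d == self.n_beads - 1)


@dataclass
class Conformation:
    """2D coordinates of both chains in an unbounded plane (no box)."""

    vesicle_xy: np.ndarray
    polymer_xy: np.ndarray

    def __post_init__(self) -> None:
        self.vesicle_xy = np.ascontiguousarray(self.vesicle_xy, dtype=float)
        self.polymer_xy = np.ascontiguousarray(self.polymer_xy, dtype=float)
        if self.vesicle_xy.shape != self.polymer_xy.shape or self.vesicle_xy.ndim != 2 \
                or self.vesicle_xy.shape[1] != 2:
            raise ValueError("both chains must be (n_beads, 2) arrays of equal shape")

    @property
    def n_beads(self) -> int:
        return self.vesicle_xy.shape[0]

    def chain(self, role: Role) -> np.ndarray:
        return self.vesicle_xy if role == "vesicle" else self.polymer_xy

    def bond_lengths(self, role: Role) -> np.ndarray:
        xy = self.chain(role)
        if role == "vesicle":
            d = np.roll(xy, -1, axis=0) - xy  # N+1 bonds incl. ring closure
        else:
            d = np.diff(xy, axis=0)  # N bonds
        return np.hypot(d[:, 0], d[:, 1])

    def is_valid(self, params: ModelParams) -> bool:
        for role in ("vesicle", "polymer"):
            bl = self.bond_lengths(role)
            if np.any(bl <= params.l_min) or np.any(bl >= params.l_max):
                return False
        return True

    def copy(self) -> "Conformation":
        return Conformation(self.vesicle_xy.copy(), self.polymer_xy.copy())

    def packed(self) -> np.ndarray:
        """Both chains stacked (vesicle first) as one (2(N+1), 2) array."""
        return np.ascontiguousarray(np.vstack([self.vesicle_xy, self.polymer_xy]))

    @classmethod
    def from_packed(cls, pos: np.ndarray) -> "Conformation":
        n = pos.shape[0] // 2
        return cls(pos[:n].copy(), pos[n:].copy())


@dataclass
class EnergyBreakdown:
    """Per-term energies of one configuration and their total."""

    fene_vesicle: float
    fene_polymer: float
    morse_vesicle: float
    morse_polymer: float
    bend_polymer: float
    lj_inter: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        s = (self.fene_vesicle + self.fene_polymer + self.morse_vesicle
             + self.morse_polymer + self.bend_polymer + self.lj_inter)
        if self.total is None:
            self.total = s


# ---------------------------------------------------------------------------
# full and incremental energies
# ---------------------------------------------------------------------------

def _pair_distances(xy_a: np.ndarray, xy_b: np.ndarray) -> np.ndarray:
    d = xy_a[:, None, :] - xy_b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def _chain_intra(xy: np.ndarray, topo: ChainTopology, params: ModelParams) -> tuple[float, float]:
    """(FENE sum over bonds, Morse sum over non-bonded pairs) for one chain."""
    n = topo.n_beads
    if topo.closed:
        d = np.roll(xy, -1, axis=0) - xy
    else:
        d = np.diff(xy, axis=0)
    bl = np.hypot(d[:, 0], d[:, 1])
    fene = float(np.sum(fene_energy(bl, params)))

    morse = 0.0
    if params.morse_eps > 0 and n > 2:
        r = _pair_distances(xy, xy)
        iu, ju = np.triu_indices(n, k=2)
        keep = np.ones(iu.shape, dtype=bool)
        if topo.closed:
            keep &= ~((iu == 0) & (ju == n - 1))  # closure pair is bonded
        rij = r[iu[keep], ju[keep]]
        rij = rij[rij <= params.morse_cutoff]
        if rij.size:
            morse = float(np.sum(morse_energy(rij, params)))
    return fene, morse


def total_energy(conf: Conformation, params: ModelParams) -> EnergyBreakdown:
    """Full energy breakdown of a configuration.

    FENE over every bond of both chains (the ring closure bond included),
    Morse over intra-chain non-bonded pairs within its cutoff, bending
    over the polymer's interior vertices, and LJ over vesicle-polymer
    pairs within its cutoff.  A bond at or beyond (l_min, l_max) makes
    the corresponding FENE term (and the total) +inf.
    """
    n = conf.n_beads
    tv = ChainTopology("vesicle", n)
    tp = ChainTopology("polymer", n)
    fene_v, morse_v = _chain_intra(conf.vesicle_xy, tv, params)
    fene_p, morse_p = _chain_intra(conf.polymer_xy, tp, params)

    bend = 0.0
    if params.kappa > 0 and n >= 3:
        a = conf.polymer_xy[:-2] - conf.polymer_xy[1:-1]
        b = conf.polymer_xy[2:] - conf.polymer_xy[1:-1]
        cos_t = np.einsum("ij,ij->i", a, b) / (
            np.hypot(a[:, 0], a[:, 1]) * np.hypot(b[:, 0], b[:, 1])
        )
        bend = float(np.sum(params.kappa * (1.0 + np.clip(cos_t, -1.0, 1.0))))

    lj = 0.0
    if params.eps_vp > 0:
        r = _pair_distances(conf.vesicle_xy, conf.polymer_xy)
        rij = r[r <= params.lj_cutoff]
        if rij.size:
            lj = float(np.sum(lj_energy(rij, params)))

    return EnergyBreakdown(fene_v, fene_p, morse_v, morse_p, bend, lj)


def local_energy_delta(
    conf: Conformation,
    chain: Role,
    bead: int,
    new_xy,
    params: ModelParams,
) -> float:
    """Energy change of moving one bead, from the touched terms only.

    Returns ``U(moved) - U(current)`` using only the moved bead's bonds,
    the bending vertices it participates in, and its Morse and LJ
    partners; +inf if any touched bond leaves (l_min, l_max).  This is
    the O(N) companion of :func:`total_energy` used by the Metropolis
    engine; the two agree to floating-point roundoff.
    """
    n = conf.n_beads
    if not 0 <= bead < n:
        raise IndexError(f"bead index {bead} out of range for {n} beads")
    new_xy = np.asarray(new_xy, dtype=float)
    own = conf.chain(chain)
    other = conf.chain("polymer" if chain == "vesicle" else "vesicle")
    topo = ChainTopology(chain, n)
    old_xy = own[bead]

    def at(i: int, moved: bool) -> np.ndarray:
        return new_xy if (moved and i == bead) else own[i]

    if chain == "vesicle":
        neighbours = [(bead - 1) % n, (bead + 1) % n]
    else:
        neighbours = [i for i in (bead - 1, bead + 1) if 0 <= i < n]

    du = 0.0
    # FENE bonds touching the bead (a 2-bead ring has two bonds to the
    # same partner; both are counted, matching total_energy)
    for j in neighbours:
        for moved, sign in ((False, -1.0), (True, 1.0)):
            l = float(np.hypot(*(at(bead, moved) - own[j])))
            e = fene_energy(l, params)
            if np.isinf(e) and sign > 0:
                return float("inf")
            du += sign * e

    # bending at touched polymer vertices
    if chain == "polymer" and params.kappa > 0:
        for v in (bead - 1, bead, bead + 1):
            if 1 <= v <= n - 2:
                for moved, sign in ((False, -1.0), (True, 1.0)):
                    th = vertex_angle(at(v - 1, moved), at(v, moved), at(v + 1, moved))
                    du += sign * bending_energy(th, params)

    # Morse partners (same chain, non-bonded)
    if params.morse_eps > 0:
        excl = {bead, *neighbours}
        for j in range(n):
            if j in excl:
                continue
            r_old = float(np.hypot(*(old_xy - own[j])))
            r_new = float(np.hypot(*(new_xy - own[j])))
            du += morse_energy(r_new, params) - morse_energy(r_old, params)

    # LJ partners on the other chain
    if params.eps_vp > 0:
        r_old = np.hypot(*(old_xy[:, None] - other.T))
        r_new = np.hypot(*(new_xy[:, None] - other.T))
        du += float(np.sum(lj_energy(r_new, params)) - np.sum(lj_energy(r_old, params)))

    return du
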