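"""Initial system construction.

The vesicle starts as a regular (N+1)-gon with every edge at the
equilibrium bond length; the polymer starts either as a straight
segment tangent to the vesicle circle at the LJ contact distance
(adsorption then nucleates quickly) or as a self-avoiding random walk
outside the vesicle.  Replicas differ by a random rigid rotation of the
polymer about the vesicle centre.
"""

from __future__ import annotations

import numpy as np

from .model import Conformation
from .params import ModelParams


def init_vesicle(n_beads: int, l0: float) -> np.ndarray:
    """Regular ``n_beads``-gon centred at the origin with edge exactly
    ``l0``; circumradius ``l0 / (2 sin(pi/n_beads))``."""
    if n_beads < 3:
        raise ValueError("a ring needs at least 3 beads")
    r = l0 / (2.0 * np.sin(np.pi / n_beads))
    th = 2.0 * np.pi * np.arange(n_beads) / n_beads
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _min_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", d, d)).min())


def init_polymer(
    n_beads: int,
    l0: float,
    vesicle_xy: np.ndarray,
    rng: np.random.Generator,
    mode: str = "straight-tangent",
    params: ModelParams | None = None,
    max_retries: int = 200,
) -> np.ndarray:
    """Place the polymer outside the vesicle.

    ``straight-tangent``: a straight (n_beads-1)*l0 segment tangent to
    the circle through the vesicle beads at the LJ contact distance,
    rotated by a random angle about the vesicle centre.
    ``random-walk``: a self-avoiding walk grown outward, retried up to
    ``max_retries`` times.  Either way every bond is exactly ``l0``, the
    nearest vesicle approach is at least the LJ contact distance and no
    non-bonded pair (either chain) is closer than 0.9 * morse_rmin.
    """
    p = params or ModelParams()
    contact = p.lj_rm
    centre = vesicle_xy.mean(axis=0)
    radius = float(np.hypot(*(vesicle_xy - centre).T).max())

    if mode == "straight-tangent":
        phi = rng.uniform(0.0, 2.0 * np.pi)
        d = radius + contact
        normal = np.array([np.cos(phi), np.sin(phi)])
        tangent = np.array([-np.sin(phi), np.cos(phi)])
        offsets = (np.arange(n_beads) - (n_beads - 1) / 2.0) * l0
        xy = centre + d * normal + offsets[:, None] * tangent
        if _min_cross_distance(xy, vesicle_xy) < contact * (1.0 - 1e-9):
            raise RuntimeError("tangent placement failed to clear the vesicle")
        return xy

    if mode != "random-walk":
        raise ValueError(f"unknown init mode {mode!r}")

    clear = 0.9 * p.morse_rmin
    for _ in range(max_retries):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        start = centre + (radius + contact + l0) * np.array([np.cos(phi), np.sin(phi)])
        pts = [start]
        heading = phi  # grow pointing away from the vesicle on average
        ok = True
        for _ in range(n_beads - 1):
            placed = False
            for _ in range(40):
                ang = heading + rng.uniform(-0.9, 0.9)
                cand = pts[-1] + l0 * np.array([np.cos(ang), np.sin(ang)])
                arr = np.array(pts)
                d_self = np.hypot(*(arr - cand).T)
                d_ves = np.hypot(*(vesicle_xy - cand).T)
                if (d_self[:-1].min() if len(pts) > 1 else np.inf) >= clear \
                        and d_ves.min() >= contact:
                    pts.append(cand)
                    heading = ang
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError(f"random-walk placement failed after {max_retries} retries")


def default_initial(params: ModelParams, rng: np.random.Generator,
                    mode: str = "straight-tangent") -> Conformation:
    """The standard starting state: polygon vesicle plus polymer placed
    by ``init_polymer`` with a replica-specific rotation."""
    ves = init_vesicle(params.n_beads, params.l0)
    pol = init_polymer(params.n_beads, params.l0, ves, rng, mode=mode, params=params)
    return Conformation(ves, pol)


def initial_factory(params: ModelParams, mode: str = "straight-tangent"):
    """Factory suitable for :func:`vesiflex.engine.run_replicas`."""

    def make(replica_index: int, rng: np.random.Generator) -> Conformation:
        return default_initial(params, rng, mode=mode)

    return make
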