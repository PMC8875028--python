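"""Metropolis dynamics, measurement schedule and replica management.

Two implementations of the same dynamics live here.  ``draw_move`` /
``metropolis_accept`` / ``run_mcs`` are a transparent pure-Python
reference driven by a ``numpy.random.Generator``; ``run`` executes the
identical move set through the compiled kernels of
:mod:`vesiflex._kernels` and is the production path.  Both perform
single-bead displacements: one Monte Carlo step (MCS) is ``2(N+1)``
attempted moves, each picking a bead uniformly over both chains and a
displacement uniform on the open square (-max_disp, max_disp)^2,
accepted with probability ``min(exp(-dU/kBT), 1)``.

Reproducibility: a run is a pure function of (initial conformation,
parameters, schedule, seed).  The compiled RNG is reseeded at every
block boundary (the equilibration span, then each measurement interval)
with a seed derived from ``(seed, block_index)`` via
``numpy.random.SeedSequence``, so a checkpoint needs only the positions
and the next block index to resume bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from . import _kernels
from .model import Conformation, EnergyBreakdown, local_energy_delta
from .observables import MeasurementRecord, measure
from .params import ModelParams, Schedule

RESYNC_EVERY_MCS = 10_000  # full-energy resynchronisation cadence


@dataclass(frozen=True)
class MoveProposal:
    """One trial displacement of a single bead."""

    chain: Literal["vesicle", "polymer"]
    bead: int
    dx: float
    dy: float


@dataclass
class RunResult:
    """Outcome of one independent Monte Carlo run."""

    seed: int
    records: list[MeasurementRecord]
    final_conformation: Conformation
    acceptance_rate: float


# ---------------------------------------------------------------------------
# reference (pure-Python) dynamics
# ---------------------------------------------------------------------------

def draw_move(rng: np.random.Generator, params: ModelParams) -> MoveProposal:
    """Draw one trial move: bead uniform over all 2(N+1) beads, increments
    uniform on (-max_disp, max_disp), independent."""
    n = params.n_beads
    k = int(rng.integers(0, 2 * n))
    chain = "vesicle" if k < n else "polymer"
    dx, dy = (rng.random(2) * 2.0 - 1.0) * params.max_disp
    return MoveProposal(chain, k % n, float(dx), float(dy))


def metropolis_accept(delta_u: float, rng: np.random.Generator, kBT: float) -> bool:
    """Metropolis rule: accept with probability min(exp(-dU/kBT), 1).

    dU <= 0 always accepts; the +inf sentinel (bond bound violation)
    always rejects without consuming randomness.
    """
    if delta_u <= 0.0:
        return True
    if math.isinf(delta_u):
        return False
    return rng.random() < math.exp(-delta_u / kBT)


def run_mcs(
    conf: Conformation, params: ModelParams, rng: np.random.Generator
) -> tuple[Conformation, int]:
    """Advance one MCS (2(N+1) trial moves) in place; returns (conf, accepted)."""
    accepted = 0
    for _ in range(2 * params.n_beads):
        mv = draw_move(rng, params)
        xy = conf.chain(mv.chain)
        new_xy = xy[mv.bead] + (mv.dx, mv.dy)
        du = local_energy_delta(conf, mv.chain, mv.bead, new_xy, params)
        if metropolis_accept(du, rng, params.kBT):
            xy[mv.bead] = new_xy
            accepted += 1
    return conf, accepted


# ---------------------------------------------------------------------------
# compiled production path
# ---------------------------------------------------------------------------

def _kernel_args(params: ModelParams) -> tuple:
    return (
        params.fene_k, params.l0, params.l_min, params.l_max, params.r0,
        params.morse_alpha, params.morse_rmin, params.morse_eps,
        params.morse_cutoff, params.kappa, params.eps_vp,
        params.lj_rm, params.lj_cutoff,
    )


def kernel_energy(pos: np.ndarray, nv: int, params: ModelParams) -> EnergyBreakdown:
    """Full energy breakdown through the compiled double-loop kernel."""
    fv, fp, mv, mp, bb, lj = _kernels.full_energy(pos, nv, *_kernel_args(params))
    return EnergyBreakdown(fv, fp, mv, mp, bb, lj)


def block_seed(seed: int, block: int) -> int:
    """Deterministic per-block kernel seed (< 2^31)."""
    return int(np.random.SeedSequence([seed, block]).generate_state(1)[0] & 0x7FFFFFFF)


def advance(
    pos: np.ndarray,
    nv: int,
    params: ModelParams,
    n_mcs: int,
    seed: int,
    e_run: float = 0.0,
    resync_every: int = RESYNC_EVERY_MCS,
) -> tuple[int, float]:
    """Advance ``n_mcs`` MCS in place with the compiled kernel, seeded with
    ``seed``; returns (accepted count, running total energy)."""
    _kernels.seed_rng(seed)
    fk, l0, lmin, lmax, r0, ma, mr, me, mc, kp, ev, rm, lc = _kernel_args(params)
    return _kernels.mc_block(
        pos, nv, n_mcs, params.max_disp, params.kBT,
        fk, l0, lmin, lmax, r0, ma, mr, me, mc, kp, ev, rm, lc,
        e_run, resync_every,
    )


def run(
    initial: Conformation,
    params: ModelParams,
    schedule: Schedule,
    seed: int,
    start_block: int = 0,
    trajectory_sink=None,
) -> RunResult:
    """One independent run: equilibrate, then measure on the schedule.

    Equilibrates for ``equil_mcs`` MCS (block 0), then records one
    MeasurementRecord every ``measure_every`` MCS until
    ``n_measurements`` are collected (blocks 1..n).  Fully deterministic
    given (initial, params, schedule, seed).  ``start_block`` resumes a
    checkpointed run; ``trajectory_sink``, if given, receives
    (conformation, mcs) at every measurement.
    """
    if not initial.is_valid(params):
        raise ValueError("initial conformation has a bond outside (l_min, l_max)")
    pos = initial.packed()
    nv = initial.n_beads
    e_run = kernel_energy(pos, nv, params).total
    accepted = 0
    tried = 0
    records: list[MeasurementRecord] = []

    if start_block == 0 and schedule.equil_mcs > 0:
        acc, e_run = advance(pos, nv, params, schedule.equil_mcs, block_seed(seed, 0), e_run)
        accepted += acc
        tried += schedule.equil_mcs * pos.shape[0]
    for m in range(schedule.n_measurements):
        block = m + 1
        if block < max(start_block, 1):
            continue
        acc, e_run = advance(pos, nv, params, schedule.measure_every, block_seed(seed, block), e_run)
        accepted += acc
        tried += schedule.measure_every * pos.shape[0]
        mcs = schedule.equil_mcs + block * schedule.measure_every
        conf = Conformation.from_packed(pos)
        records.append(measure(conf, params, mcs))
        if trajectory_sink is not None:
            trajectory_sink(conf, mcs)

    return RunResult(
        seed=seed,
        records=records,
        final_conformation=Conformation.from_packed(pos),
        acceptance_rate=accepted / tried if tried else 0.0,
    )


def sample_pair_distance(
    initial: Conformation,
    params: ModelParams,
    pair: tuple[int, int],
    n_samples: int,
    sample_every: int,
    seed: int,
) -> np.ndarray:
    """Time series of the distance between two beads (packed indices:
    vesicle beads first) sampled every ``sample_every`` MCS.  Used by the
    detailed-balance checks against the bond-length quadrature oracle."""
    pos = initial.packed()
    _kernels.seed_rng(seed)
    return _kernels.mc_sample_distance(
        pos, initial.n_beads, pair[0], pair[1], n_samples, sample_every,
        params.max_disp, params.kBT, *_kernel_args(params),
    )


def sample_mean_cos_angle(
    initial: Conformation,
    params: ModelParams,
    n_samples: int,
    sample_every: int,
    seed: int,
) -> np.ndarray:
    """Time series of the polymer's mean interior-vertex cos(theta),
    sampled every ``sample_every`` MCS.  Used by the bending-statistics
    checks against the single-vertex quadrature oracle."""
    pos = initial.packed()
    _kernels.seed_rng(seed)
    return _kernels.mc_sample_mean_cos(
        pos, initial.n_beads, n_samples, sample_every,
        params.max_disp, params.kBT, *_kernel_args(params),
    )


# ---------------------------------------------------------------------------
# replica management
# ---------------------------------------------------------------------------

@dataclass
class ObservableStat:
    mean: float
    stderr: float
    n: int


@dataclass
class ReplicaStatistics:
    """Pooled statistics over n_runs x n_measurements samples."""

    u_vl: ObservableStat
    r_ee: ObservableStat
    asphericity: ObservableStat
    acceptance_rate: float
    tt_corr_mean: np.ndarray
    tt_corr_stderr: np.ndarray
    shape_counts: dict[str, int]
    run_results: list[RunResult]

    @property
    def n_samples(self) -> int:
        return self.u_vl.n

    @property
    def shape_label(self) -> str:
        """Most frequent per-sample label (ties resolve alphabetically)."""
        return sorted(self.shape_counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def _pooled(values: np.ndarray) -> ObservableStat:
    n = values.size
    se = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ObservableStat(float(values.mean()), se, n)


def replica_seeds(base_seed: int, n_runs: int) -> list[tuple[int, np.random.Generator]]:
    """Per-replica (run seed, initial-conformation rng), both derived from
    the base seed through SeedSequence spawning."""
    children = np.random.SeedSequence(base_seed).spawn(n_runs)
    out = []
    for child in children:
        run_ss, init_ss = child.spawn(2)
        run_seed = int(run_ss.generate_state(1)[0] & 0x7FFFFFFF)
        out.append((run_seed, np.random.default_rng(init_ss)))
    return out


def run_replicas(
    initial_factory: Callable[[int, np.random.Generator], Conformation],
    params: ModelParams,
    schedule: Schedule,
    keep_runs: bool = True,
) -> ReplicaStatistics:
    """n_runs independent runs with distinct seeds and distinct initial
    conformations; pooled mean and standard error per observable."""
    if schedule.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results: list[RunResult] = []
    for idx, (run_seed, init_rng) in enumerate(replica_seeds(schedule.base_seed, schedule.n_runs)):
        initial = initial_factory(idx, init_rng)
        results.append(run(initial, params, schedule, run_seed))
    return aggregate(results, keep_runs=keep_runs)


def aggregate(results: Sequence[RunResult], keep_runs: bool = True) -> ReplicaStatistics:
    """Pool the measurement records of several runs."""
    u = np.array([r.u_vl for res in results for r in res.records])
    ree = np.array([r.r_ee for res in results for r in res.records])
    asph = np.array([r.asphericity_vesicle for res in results for r in res.records])
    corr = np.array([r.tt_corr for res in results for r in res.records])
    n = corr.shape[0]
    c_se = corr.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros(corr.shape[1])
    counts: dict[str, int] = {}
    for res in results:
        for r in res.records:
            counts[r.shape_label] = counts.get(r.shape_label, 0) + 1
    return ReplicaStatistics(
        u_vl=_pooled(u),
        r_ee=_pooled(ree),
        asphericity=_pooled(asph),
        acceptance_rate=float(np.mean([res.acceptance_rate for res in results])),
        tt_corr_mean=corr.mean(axis=0),
        tt_corr_stderr=np.asarray(c_se),
        shape_counts=counts,
        run_results=list(results) if keep_runs else [],
    )


# ---------------------------------------------------------------------------
# checkpoint file (flat text; bit-exact round trip)
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    conf: Conformation,
    params: ModelParams,
    seed: int,
    next_block: int,
) -> None:
    """Write a flat-text checkpoint: parameter header, RNG state token
    (the run seed and next block index), one bead per line."""
    from dataclasses import fields

    lines = ["# vesiflex checkpoint v1"]  # header values written with repr()
    for f in fields(params):
        lines.append(f"# param {f.name} {getattr(params, f.name)!r}")
    lines.append(f"# rng-token seed={seed} next_block={next_block}")
    for tag, xy in (("V", conf.vesicle_xy), ("P", conf.polymer_xy)):
        for i, (x, y) in enumerate(xy):
            lines.append(f"{tag} {i} {float(x)!r} {float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_checkpoint(path: str | Path) -> tuple[Conformation, ModelParams, int, int]:
    """Read a checkpoint back; coordinates round-trip bit-exactly."""
    pvals: dict[str, object] = {}
    seed = next_block = None
    beads: dict[str, list[tuple[int, float, float]]] = {"V": [], "P": []}
    for line in Path(path).read_text().splitlines():
        if line.startswith("# param "):
            _, _, name, val = line.split(maxsplit=3)
            import ast

            pvals[name] = ast.literal_eval(val)
        elif line.startswith("# rng-token"):
            parts = dict(p.split("=") for p in line.split()[2:])
            seed, next_block = int(parts["seed"]), int(parts["next_block"])
        elif line and not line.startswith("#"):
            tag, idx, x, y = line.split()
            beads[tag].append((int(idx), float(x), float(y)))
    if seed is None:
        raise ValueError(f"{path}: missing rng-token line")
    params = ModelParams(**{k: v for k, v in pvals.items()})
    arrs = {}
    for tag, rows in beads.items():
        rows.sort()
        arrs[tag] = np.array([(x, y) for _, x, y in rows])
    return Conformation(arrs["V"], arrs["P"]), params, seed, next_block
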