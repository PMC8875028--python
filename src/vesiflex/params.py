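"""Model parameters and Monte Carlo schedule.

All quantities are in reduced units: length in units of the maximum bond
extension ``l_max`` and energy in units of the thermal energy ``k_B T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass
class ModelParams:
    """Every physical constant of the two-chain model.

    Both chains (the closed vesicle ring and the linear semiflexible
    polymer) carry ``n_bonds + 1`` beads built from identical monomers.
    Bonded neighbours interact through a FENE spring, non-bonded monomers
    of the same chain through a short-ranged Morse potential (excluded
    volume), the polymer additionally through a bending penalty
    ``kappa * (1 + cos(theta))``, and vesicle-polymer bead pairs through a
    Lennard-Jones well of depth ``eps_vp`` at distance ``lj_rm``.
    """

    n_bonds: int = 60
    fene_k: float = 20.0
    l0: float = 0.7
    l_min: float = 0.4
    l_max: float = 1.0
    r0: float | None = None  # filled in as l_max - l0
    morse_alpha: float = 24.0
    morse_rmin: float = 0.8
    morse_eps: float = 1.0
    morse_cutoff: float = 1.0
    kappa: float = 10.0
    eps_vp: float = 2.0
    lj_rm: float = 0.8
    lj_cutoff: float = 2.0
    kBT: float = 1.0
    max_disp: float = 0.25

    def __post_init__(self) -> None:
        if self.r0 is None:
            self.r0 = self.l_max - self.l0
        self.validate()

    def validate(self) -> None:
        if self.n_bonds < 1:
            raise ValueError("n_bonds must be >= 1")
        if not (self.l_min < self.l0 < self.l_max):
            raise ValueError("require l_min < l0 < l_max")
        if not math.isclose(self.r0, self.l_max - self.l0, rel_tol=0, abs_tol=1e-12):
            raise ValueError("r0 must equal l_max - l0")
        for name in ("fene_k", "morse_alpha", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("morse_eps", "eps_vp", "kappa", "max_disp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.morse_cutoff < self.morse_rmin:
            raise ValueError("morse_cutoff must be >= morse_rmin")
        if self.lj_cutoff < self.lj_rm:
            raise ValueError("lj_cutoff must be >= lj_rm")

    @property
    def n_beads(self) -> int:
        """Beads per chain (both chains have the same count)."""
        return self.n_bonds + 1

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        kwargs.setdefault("r0", None if {"l0", "l_max"} & kwargs.keys() else self.r0)
        return replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        return cls(**_parse_kv(path, {f.name for f in fields(cls)}))


@dataclass
class Schedule:
    """Monte Carlo schedule: run length, measurement cadence, replicas.

    One Monte Carlo step (MCS) is ``2 * (n_bonds + 1)`` attempted
    single-bead displacements.  The defaults are the full production
    protocol: 3e8 MCS per run, a measurement every 1e6 MCS, 100
    measurements per run (so the final 1e8 MCS are the measurement
    window and the first 2e8 equilibrate), and 100 independent replicas,
    pooling 10,000 samples per state point.
    """

    total_mcs: int = 300_000_000
    equil_mcs: int = 200_000_000
    measure_every: int = 1_000_000
    n_measurements: int = 100
    n_runs: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.total_mcs, self.measure_every, self.n_measurements, self.n_runs) < 1:
            raise ValueError("schedule counts must be >= 1")
        if self.equil_mcs < 0:
            raise ValueError("equil_mcs must be >= 0")
        if self.equil_mcs + self.n_measurements * self.measure_every > self.total_mcs:
            raise ValueError(
                "equil_mcs + n_measurements*measure_every exceeds total_mcs"
            )

    @classmethod
    def scaled(
        cls, total_mcs: int, n_runs: int, n_measurements: int = 100, base_seed: int = 0
    ) -> "Schedule":
        """A reduced schedule preserving the 2:1 equilibration:measurement split."""
        equil = (2 * total_mcs) // 3
        every = max(1, (total_mcs - equil) // n_measurements)
        return cls(
            total_mcs=total_mcs,
            equil_mcs=equil,
            measure_every=every,
            n_measurements=n_measurements,
            n_runs=n_runs,
            base_seed=base_seed,
        )

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)!r}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Schedule":
        return cls(**_parse_kv(path, {f.name for f in fields(cls)}))


def _parse_kv(path: str | Path, allowed: set[str]) -> dict:
    """Parse a flat ``key = value`` config file; unknown keys are an error."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in allowed:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key in out:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        val = val.strip()
        out[key] = None if val == "None" else float(val) if "." in val or "e" in val.lower() or "inf" in val else int(val)
    return out


def load_config(path: str | Path) -> tuple[ModelParams, Schedule]:
    """Load a config file that may mix ModelParams and Schedule keys."""
    pnames = {f.name for f in fields(ModelParams)}
    snames = {f.name for f in fields(Schedule)}
    raw = _parse_kv(path, pnames | snames)
    p = {k: v for k, v in raw.items() if k in pnames}
    s = {k: v for k, v in raw.items() if k in snames}
    s = {k: int(v) for k, v in s.items()}
    return ModelParams(**p), Schedule(**s) if s else Schedule()
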