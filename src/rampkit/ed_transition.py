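"""Essential-dynamics driven transition on a toy elastic-network engine.

The driving protocol is the defined computation: at every integration
step the projection of the structure onto a fixed collective eigenvector
is advanced by a constant increment, steering the system from one
endpoint conformation to the other; the run is repeated over several
replicates and the replicates are merged frame-by-frame by best score.
The underlying force field is deliberately simple — harmonic springs
between all Cα pairs within a cutoff of a reference structure, evolved
with overdamped Langevin dynamics (kB = 1, energies in spring-constant
units, lengths in Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from rampkit.structure_io import Structure

__all__ = ["ToyPotential", "MorphPotential", "EDConfig", "EDTrajectory",
           "build_toy_potential", "ed_drive", "ed_drive_replicates",
           "combine_best_score"]


@dataclass
class ToyPotential:
    """Elastic network: harmonic springs on reference pair distances.

    Energy is zero at the reference structure by construction.
    """

    reference: np.ndarray   # (n_atoms, 3)
    pairs: np.ndarray       # (n_pairs, 2) int, i < j
    k: float                # spring constant, energy / Å²
    rest_lengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        d = self.reference[self.pairs[:, 0]] - self.reference[self.pairs[:, 1]]
        self.rest_lengths = np.linalg.norm(d, axis=1)

    def energy(self, coords: np.ndarray) -> float:
        d = coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        return float(0.5 * self.k * np.sum((dist - self.rest_lengths) ** 2))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        d = coords[self.pairs[:, 0]] - coords[self.pairs[:, 1]]
        dist = np.linalg.norm(d, axis=1)
        # springs at exactly zero length have no defined direction; skip them
        safe = np.where(dist > 1e-12, dist, 1.0)
        f = (self.k * (dist - self.rest_lengths) / safe)[:, None] * d
        grad = np.zeros_like(coords)
        np.add.at(grad, self.pairs[:, 0], f)
        np.add.at(grad, self.pairs[:, 1], -f)
        return grad


class MorphPotential:
    """Two-state elastic network whose rest lengths track the driving.

    Springs connect every Cα pair within ``cutoff`` of *either* endpoint;
    their rest lengths interpolate linearly between the inactive and
    active pair distances as the driving progress goes 0 → 1 (the
    integrator calls :meth:`set_progress` once per step).  At progress 1
    the active structure is the exact energy minimum, so the driven run
    has a genuine well to land in; at fixed progress the surface is an
    ordinary harmonic network.
    """

    def __init__(self, inactive: np.ndarray, active: np.ndarray,
                 cutoff: float = 10.0, k: float = 1.0):
        inactive = np.asarray(inactive, dtype=float)
        active = np.asarray(active, dtype=float)
        if inactive.shape != active.shape:
            raise ValueError("endpoint structures must have matching shapes")
        iu, ju = np.triu_indices(len(inactive), k=1)
        da = np.linalg.norm(inactive[iu] - inactive[ju], axis=1)
        db = np.linalg.norm(active[iu] - active[ju], axis=1)
        within = (da < cutoff) | (db < cutoff)
        if not np.any(within):
            raise ValueError("no atom pairs within cutoff")
        self.pairs = np.column_stack([iu[within], ju[within]])
        self._d_inactive = da[within]
        self._d_active = db[within]
        self.k = k
        self._pot = ToyPotential(inactive, self.pairs, k)
        self.set_progress(0.0)

    def set_progress(self, lam: float) -> None:
        lam = float(np.clip(lam, 0.0, 1.0))
        self._pot.rest_lengths = ((1.0 - lam) * self._d_inactive
                                  + lam * self._d_active)

    def energy(self, coords: np.ndarray) -> float:
        return self._pot.energy(coords)

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self._pot.gradient(coords)


def build_toy_potential(structure, cutoff: float = 10.0,
                        k: float = 1.0) -> ToyPotential:
    """Springs between every Cα pair within ``cutoff`` Å of the reference."""
    coords = (structure.coords if isinstance(structure, Structure)
              else np.asarray(structure, dtype=float))
    if len(coords) < 2:
        raise ValueError("need at least 2 atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    iu, ju = np.triu_indices(len(coords), k=1)
    within = dist[iu, ju] < cutoff
    if not np.any(within):
        raise ValueError("no atom pairs within cutoff")
    pairs = np.column_stack([iu[within], ju[within]])
    return ToyPotential(coords, pairs, k)


@dataclass
class EDConfig:
    """Configuration of one essential-dynamics driving run.

    ``increment`` is the projection advance per step in Å (negative for
    reverse driving).  ``temperature`` is in kB = 1 units; ``friction``
    and ``dt`` set the overdamped mobility dt/friction.  ``constraint``
    selects the hard per-step projection reset (default) or a harmonic
    restraint toward the moving target.
    """

    eigenvector: np.ndarray
    increment: float
    n_steps: int
    temperature: float = 0.0
    friction: float = 1.0
    dt: float = 0.01
    n_replicates: int = 10
    seed: int = 0
    stride: int = 1000
    constraint: str = "reset"
    restraint_k: float = 100.0

    def __post_init__(self) -> None:
        self.eigenvector = np.asarray(self.eigenvector, dtype=float).ravel()
        norm = np.linalg.norm(self.eigenvector)
        if not math.isclose(norm, 1.0, abs_tol=1e-8):
            raise ValueError("eigenvector must have unit norm")
        if not math.isfinite(self.increment):
            raise ValueError("increment must be finite")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.constraint not in ("reset", "restraint"):
            raise ValueError("constraint must be 'reset' or 'restraint'")


@dataclass
class EDTrajectory:
    """Recorded frames of a driven run (always includes first and last step)."""

    frames: np.ndarray       # (n_recorded, n_atoms, 3)
    steps: np.ndarray        # (n_recorded,) integration step of each frame
    projections: np.ndarray  # (n_recorded,) projection relative to the start
    energies: np.ndarray     # (n_recorded,) toy-potential energies

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def ed_drive(start: np.ndarray, config: EDConfig,
             potential: ToyPotential, replicate: int = 0) -> EDTrajectory:
    """Drive ``start`` along the eigenvector in fixed per-step increments.

    Each step applies an overdamped Langevin update under the toy
    potential, then corrects the coordinates along the eigenvector so the
    projection equals ``step × increment`` exactly (reset mode).  The
    same seed yields bit-identical trajectories.
    """
    start = (start.coords if isinstance(start, Structure)
             else np.asarray(start, dtype=float)).copy()
    v = config.eigenvector
    if v.size != start.size:
        raise ValueError("eigenvector dimension does not match structure")
    rng = np.random.default_rng([config.seed, replicate])
    mob = config.dt / config.friction
    kick = math.sqrt(2.0 * config.temperature * mob)
    x = start.copy()
    x0 = start.ravel()

    rec_frames = [x.copy()]
    rec_steps = [0]
    rec_proj = [0.0]
    rec_energy = [potential.energy(x)]
    for s in range(1, config.n_steps + 1):
        target = s * config.increment
        if hasattr(potential, "set_progress"):
            potential.set_progress(s / config.n_steps)
        grad = potential.gradient(x)
        if config.constraint == "restraint":
            p = float((x.ravel() - x0) @ v)
            grad = grad + (config.restraint_k * (p - target)
                           ) * v.reshape(x.shape)
        x = x - mob * grad
        if config.temperature > 0:
            x = x + kick * rng.standard_normal(x.shape)
        if config.constraint == "reset":
            p = float((x.ravel() - x0) @ v)
            x = x + (target - p) * v.reshape(x.shape)
        if s % config.stride == 0 or s == config.n_steps:
            rec_frames.append(x.copy())
            rec_steps.append(s)
            rec_proj.append(float((x.ravel() - x0) @ v))
            rec_energy.append(potential.energy(x))
    return EDTrajectory(np.stack(rec_frames), np.asarray(rec_steps),
                        np.asarray(rec_proj), np.asarray(rec_energy))


def ed_drive_replicates(start, config: EDConfig,
                        potential: ToyPotential) -> list[EDTrajectory]:
    """Run the configured number of independently seeded replicates."""
    return [ed_drive(start, config, potential, replicate=r)
            for r in range(config.n_replicates)]


def combine_best_score(replicates: list[EDTrajectory],
                       scorer=None) -> EDTrajectory:
    """Merge replicates frame-by-frame, keeping the best-scoring snapshot.

    ``scorer`` maps a coordinate frame to a scalar (lower is better);
    by default the recorded toy-potential energy is used.  Ties go to the
    lowest replicate index.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    n = replicates[0].n_frames
    for r in replicates[1:]:
        if r.n_frames != n or r.frames.shape != replicates[0].frames.shape:
            raise ValueError("replicates must have equal frame counts and atoms")
    if scorer is None:
        scores = np.stack([r.energies for r in replicates])
    else:
        scores = np.stack([[scorer(f) for f in r.frames] for r in replicates])
    best = np.argmin(scores, axis=0)  # ties -> lowest replicate index
    frames = np.stack([replicates[b].frames[t] for t, b in enumerate(best)])
    energies = np.array([scores[b, t] for t, b in enumerate(best)])
    proj = np.array([replicates[b].projections[t]
                     for t, b in enumerate(best)])
    return EDTrajectory(frames, replicates[0].steps.copy(), proj, energies)
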