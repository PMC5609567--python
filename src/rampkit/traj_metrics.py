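"""Trajectory-derived observables: interhelical distances, persistent
contacts, contact rearrangements on activation, helix bend angles and
representative frames.

Contacts are Cα–Cα by default: a residue pair counts as a persistent
contact when its distance is below the cutoff (5 Å) in more than the
persistence fraction (80%) of frames in *every* supplied simulation, and
the pair is at least 3 residues apart in sequence (nearest backbone
neighbours are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rampkit.ensemble_pca import ConformationEnsemble, _align_frames, superpose

__all__ = ["ResiduePair", "ContactTimeline", "distance_series",
           "contact_timeline", "persistent_contacts", "rearrangement_table",
           "helix_bend_angle", "representative_frame"]

DEFAULT_CUTOFF = 5.0       # Å, Cα–Cα
DEFAULT_PERSISTENCE = 0.8  # fraction of frames, strict
MIN_SEQ_SEP = 3            # |i − j| ≤ 2 excluded


@dataclass(frozen=True)
class ResiduePair:
    """An unordered residue pair (1-based primary-sequence indices)."""

    residue_a: int
    residue_b: int
    label_a: str = ""
    label_b: str = ""

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("a residue cannot pair with itself")

    def sorted(self) -> tuple[int, int]:
        return (min(self.residue_a, self.residue_b),
                max(self.residue_a, self.residue_b))


@dataclass
class ContactTimeline:
    """Per-frame distances of one pair across one or more simulations."""

    pair: ResiduePair
    distances: list          # one (n_frames,) array per simulation
    cutoff: float = DEFAULT_CUTOFF

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([float(np.mean(d < self.cutoff))
                         for d in self.distances])


def distance_series(ensemble: ConformationEnsemble,
                    pair: ResiduePair) -> np.ndarray:
    """Euclidean Cα–Cα distance of a residue pair per frame (Å)."""
    ia = ensemble.atom_index(pair.residue_a)
    ib = ensemble.atom_index(pair.residue_b)
    return np.linalg.norm(ensemble.frames[:, ia] - ensemble.frames[:, ib],
                          axis=1)


def contact_timeline(ensembles, pair: ResiduePair,
                     cutoff: float = DEFAULT_CUTOFF) -> ContactTimeline:
    """Distance record of one pair over several simulations."""
    ensembles = _as_list(ensembles)
    return ContactTimeline(pair, [distance_series(e, pair)
                                  for e in ensembles], cutoff)


def _as_list(ensembles):
    if isinstance(ensembles, ConformationEnsemble):
        return [ensembles]
    if not ensembles:
        raise ValueError("need at least one simulation")
    return list(ensembles)


def _check_consistent(ensembles) -> np.ndarray:
    res = ensembles[0].annotations["residue_index"].to_numpy()
    for e in ensembles[1:]:
        other = e.annotations["residue_index"].to_numpy()
        if len(other) != len(res) or np.any(other != res):
            raise ValueError("simulations have inconsistent atom tables")
    return res


def persistent_contacts(ensembles, cutoff: float = DEFAULT_CUTOFF,
                        persistence: float = DEFAULT_PERSISTENCE,
                        min_seq_sep: int = MIN_SEQ_SEP) -> list[ResiduePair]:
    """Residue pairs within ``cutoff`` in > ``persistence`` of frames in
    every supplied simulation (strict inequality), sequence-neighbour
    pairs excluded."""
    ensembles = _as_list(ensembles)
    if cutoff <= 0 or not 0.0 < persistence <= 1.0:
        raise ValueError("need cutoff > 0 and 0 < persistence <= 1")
    res = _check_consistent(ensembles)
    n = len(res)
    iu, ju = np.triu_indices(n, k=1)
    keep = np.abs(res[iu] - res[ju]) >= min_seq_sep
    iu, ju = iu[keep], ju[keep]
    persistent = np.ones(len(iu), dtype=bool)
    for e in ensembles:
        d = np.linalg.norm(e.frames[:, iu] - e.frames[:, ju], axis=2)
        occupancy = np.mean(d < cutoff, axis=0)
        # strict "more than" rule; persistence=1 degenerates to "in every
        # frame", which a strict inequality could never satisfy
        if persistence >= 1.0:
            persistent &= occupancy >= 1.0
        else:
            persistent &= occupancy > persistence
    ann = ensembles[0].annotations
    label = (dict(zip(ann["residue_index"], ann["wootten"]))
             if "wootten" in ann.columns else {})
    pairs = []
    for i, j in zip(iu[persistent], ju[persistent]):
        a, b = int(res[i]), int(res[j])
        pairs.append(ResiduePair(a, b, label.get(a, ""), label.get(b, "")))
    return pairs


def rearrangement_table(inactive, active, cutoff: float = DEFAULT_CUTOFF,
                        persistence: float = DEFAULT_PERSISTENCE,
                        min_seq_sep: int = MIN_SEQ_SEP) -> pd.DataFrame:
    """Contact rearrangements between inactive and active ensembles.

    Returns a DataFrame with columns ``residue_1``, ``residue_2``,
    ``label_1``, ``label_2``, ``conformation`` where conformation is
    ``Inactive`` (persistent in the inactive state only), ``Active``
    (active only) or ``Shared``; rows ordered by helix then residue index.
    """
    inactive_list = _as_list(inactive)
    active_list = _as_list(active)
    _check_consistent(inactive_list + active_list)
    pi = {p.sorted(): p for p in persistent_contacts(
        inactive_list, cutoff, persistence, min_seq_sep)}
    pa = {p.sorted(): p for p in persistent_contacts(
        active_list, cutoff, persistence, min_seq_sep)}
    ann = inactive_list[0].annotations
    helix_rank = {r: h for r, h in zip(ann["residue_index"], ann["helix"])}
    rows = []
    for key in sorted(set(pi) | set(pa)):
        pair = pi.get(key) or pa.get(key)
        state = ("Shared" if key in pi and key in pa
                 else "Inactive" if key in pi else "Active")
        rows.append({"residue_1": key[0], "residue_2": key[1],
                     "label_1": pair.label_a, "label_2": pair.label_b,
                     "helix_1": helix_rank.get(key[0], ""),
                     "helix_2": helix_rank.get(key[1], ""),
                     "conformation": state})
    df = pd.DataFrame(rows, columns=["residue_1", "residue_2", "label_1",
                                     "label_2", "helix_1", "helix_2",
                                     "conformation"])
    if len(df):
        df = df.sort_values(["helix_1", "residue_1", "residue_2"],
                            kind="stable").reset_index(drop=True)
    return df


def _axis_direction(coords: np.ndarray) -> np.ndarray:
    """Axis of a helix segment, oriented N→C.

    Uses the second-difference (radial) vectors of the Cα trace, which
    for a helix are perpendicular to its axis: the axis is their common
    normal (smallest right singular vector).  This is exact for ideal
    helices regardless of segment length; for a degenerate (collinear)
    trace it falls back to a least-squares line fit.
    """
    second = coords[2:] - 2.0 * coords[1:-1] + coords[:-2]
    if np.linalg.norm(second) > 1e-9:
        _, _, vt = np.linalg.svd(second)
        axis = vt[-1]
    else:
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def helix_bend_angle(helix_frames: np.ndarray, split: int) -> dict:
    """Bend angle between the two halves of a helix, per frame.

    ``helix_frames`` has shape ``(n_frames, n_res, 3)`` (a single frame
    may be passed as ``(n_res, 3)``); ``split`` is the 0-based residue
    position where the helix is divided — each side needs ≥ 4 residues.
    Returns per-frame angles in degrees plus mean ± SD and max, the
    reporting convention used for TM6 bending.
    """
    helix_frames = np.asarray(helix_frames, dtype=float)
    if helix_frames.ndim == 2:
        helix_frames = helix_frames[None]
    n_res = helix_frames.shape[1]
    if split < 4 or n_res - split < 4:
        raise ValueError("need at least 4 residues on each side of the split")
    angles = np.empty(helix_frames.shape[0])
    for f, frame in enumerate(helix_frames):
        a1 = _axis_direction(frame[:split])
        a2 = _axis_direction(frame[split:])
        angles[f] = np.degrees(np.arccos(np.clip(a1 @ a2, -1.0, 1.0)))
    return {"angles": angles, "mean": float(np.mean(angles)),
            "sd": float(np.std(angles)), "max": float(np.max(angles))}


def representative_frame(ensemble: ConformationEnsemble) -> int:
    """Index of the frame with the lowest RMSD to the average structure.

    Frames are first superposed onto the iteratively converged ensemble
    mean; ties break to the lowest index.
    """
    if ensemble.n_frames == 1:
        return 0
    aligned, mean = _align_frames(ensemble.frames)
    rmsd = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=1))
    return int(np.argmin(rmsd))
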