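"""Idealised 7-helix Cα bundle with a parameterised activation pivot.

The fixture stands in for a class B GPCR transmembrane bundle: seven
ideal α-helices (1.5 Å rise, 2.3 Å helical radius, 100° twist per
residue) on a ring, with activation modelled as a rigid pivot of TM5 and
TM6 about the TM3 axis plus an optional kink of the cytoplasmic half of
TM6.  Residue numbering mimics the CLR primary sequence so that named
positions (V190, Y227, N305, L345, H374, ...) land on the right helices
and metric outputs read like receptor tables.  The generator also
records the ground-truth contact changes its own geometry creates, which
downstream contact analyses must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rampkit.ensemble_pca import ConformationEnsemble
from rampkit.structure_io import Structure

__all__ = ["BundleSpec", "PivotResult", "build_bundle",
           "apply_activation_pivot", "sample_ensemble", "CLR_HELIX_STARTS",
           "WOOTTEN_LABELS"]

# First primary-sequence residue index of each toy helix (CLR-like ranges).
CLR_HELIX_STARTS = {"TM1": 145, "TM2": 177, "TM3": 215, "TM4": 250,
                    "TM5": 290, "TM6": 332, "TM7": 365}

# Class B (Wootten) labels for the study's named residues.
WOOTTEN_LABELS = {
    148: "1.50b", 183: "2.56b", 184: "2.57b", 190: "2.63b", 218: "3.35b",
    226: "3.43b", 227: "3.44b", 230: "3.47b", 233: "3.50b", 295: "5.40b",
    298: "5.43b", 302: "5.47b", 305: "5.50b", 339: "6.43b", 341: "6.45b",
    345: "6.49b", 348: "6.52b", 349: "6.53b", 370: "7.43b", 371: "7.44b",
    373: "7.46b", 374: "7.47b", 376: "7.49b", 383: "7.56b", 384: "7.57b",
}

_RESIDUE_NAMES = {
    148: "GLY", 183: "SER", 184: "PHE", 190: "VAL", 194: "HIS", 218: "ILE",
    226: "ASN", 227: "TYR", 230: "MET", 233: "GLU", 295: "HIS", 298: "ILE",
    302: "LEU", 305: "ASN", 339: "LEU", 341: "LEU", 345: "LEU", 348: "GLU",
    349: "PHE", 370: "HIS", 371: "ILE", 373: "MET", 374: "HIS", 376: "GLN",
    383: "ILE", 384: "PHE",
}


@dataclass
class BundleSpec:
    """Geometry of the toy bundle and its activation pivot.

    Angles in degrees, lengths in Å.  ``residues_per_helix`` applies to
    every helix.  ``pivot_angle`` rotates TM5 and TM6 rigidly about the
    TM3 axis; ``kink_angle`` additionally bends the cytoplasmic half of
    TM6 at ``kink_residue`` (defaults to the TM6 midpoint).
    """

    residues_per_helix: int = 20
    ring_radius: float = 10.0
    rise: float = 1.5
    helix_radius: float = 2.3
    twist: float = 100.0
    pivot_helix: str = "TM3"
    moving_helices: tuple = ("TM5", "TM6")
    pivot_angle: float = 25.0
    kink_angle: float = 0.0
    kink_residue: int | None = None
    sigma: float = 0.0
    n_frames: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residues_per_helix < 8:
            raise ValueError("need at least 8 residues per helix")
        if not 0.0 <= self.pivot_angle <= 90.0:
            raise ValueError("pivot angle must be in [0, 90] degrees")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        # adjacent helix axes on the ring must stay separated
        sep = 2.0 * self.ring_radius * math.sin(math.pi / 7.0)
        if sep < 4.0:
            raise ValueError("helix axes closer than 4 Å; enlarge ring_radius")


def _ideal_helix(n: int, origin: np.ndarray, direction: float,
                 rise: float, radius: float, twist_deg: float) -> np.ndarray:
    """Cα trace of an ideal helix along ±z, centred at z = 0."""
    i = np.arange(n)
    theta = np.deg2rad(twist_deg) * i
    z = direction * (i - (n - 1) / 2.0) * rise
    return np.column_stack([
        origin[0] + radius * np.cos(theta),
        origin[1] + radius * np.sin(theta),
        z,
    ])


def build_bundle(spec: BundleSpec) -> Structure:
    """Deterministic inactive-state bundle with CLR-like residue labels.

    Helices alternate direction around the ring (antiparallel packing);
    the membrane normal is z, with the cytoplasmic side at negative z.
    """
    coords, rows = [], []
    for k, helix in enumerate(sorted(CLR_HELIX_STARTS, key=lambda h: int(h[2]))):
        azimuth = 2.0 * math.pi * k / 7.0
        origin = np.array([spec.ring_radius * math.cos(azimuth),
                           spec.ring_radius * math.sin(azimuth), 0.0])
        direction = -1.0 if k % 2 == 0 else 1.0
        xyz = _ideal_helix(spec.residues_per_helix, origin, direction,
                           spec.rise, spec.helix_radius, spec.twist)
        start = CLR_HELIX_STARTS[helix]
        for j in range(spec.residues_per_helix):
            idx = start + j
            rows.append({"residue_index": idx,
                         "residue_name": _RESIDUE_NAMES.get(idx, "ALA"),
                         "helix": helix,
                         "wootten": WOOTTEN_LABELS.get(idx, "")})
        coords.append(xyz)
    return Structure(np.concatenate(coords), pd.DataFrame(rows))


def _helix_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Helix axis (unit direction, centroid) from the Cα trace.

    The second differences of an ideal helix trace are radial, so their
    common normal is the axis; this stays exact for short segments where
    a straight line fit of the positions would tilt.
    """
    centroid = coords.mean(axis=0)
    second = coords[2:] - 2.0 * coords[1:-1] + coords[:-2]
    _, _, vt = np.linalg.svd(second)
    axis = vt[-1]
    # orient from first to last residue
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis, centroid


def _rotate_about_axis(coords: np.ndarray, point: np.ndarray,
                       axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)
    return (coords - point) @ R.T + point


@dataclass
class PivotResult:
    """Active structure plus the ground-truth contact changes it creates."""

    active: Structure
    broken_contacts: list  # present (inactive only), as (res_i, res_j) i<j
    formed_contacts: list  # present (active only)


def _contact_set(coords: np.ndarray, residue_indices: np.ndarray,
                 cutoff: float, min_seq_sep: int = 3) -> set:
    """Brute-force Cα contact scan (the generator's own ground truth)."""
    contacts = set()
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = int(residue_indices[i]), int(residue_indices[j])
            if abs(ri - rj) < min_seq_sep:
                continue
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                contacts.add((min(ri, rj), max(ri, rj)))
    return contacts


def apply_activation_pivot(bundle: Structure, spec: BundleSpec,
                           contact_cutoff: float = 5.0) -> PivotResult:
    """Pivot TM5/TM6 about the TM3 axis (+ optional TM6 kink).

    The moving helices rotate rigidly about the least-squares axis of the
    pivot helix by ``spec.pivot_angle``; the cytoplasmic (negative-z)
    half of TM6 is then bent by ``spec.kink_angle`` about an in-membrane
    axis through the kink residue's Cα.  Contacts (Cα < cutoff, sequence
    separation ≥ 3) are scanned in both endpoints and the designed
    broken/formed lists are returned with the active structure.
    """
    helices = bundle.annotations["helix"].to_numpy()
    res_idx = bundle.annotations["residue_index"].to_numpy()
    coords = bundle.coords.copy()

    pivot_mask = helices == spec.pivot_helix
    axis, point = _helix_axis(bundle.coords[pivot_mask])
    moving = np.isin(helices, list(spec.moving_helices))
    if spec.pivot_angle != 0.0:
        coords[moving] = _rotate_about_axis(coords[moving], point, axis,
                                            spec.pivot_angle)

    if spec.kink_angle != 0.0:
        tm6 = np.flatnonzero(helices == "TM6")
        kink_res = (spec.kink_residue if spec.kink_residue is not None
                    else int(res_idx[tm6[len(tm6) // 2]]))
        kink_pos = np.flatnonzero(res_idx == kink_res)
        if len(kink_pos) == 0 or helices[kink_pos[0]] != "TM6":
            raise ValueError(f"kink residue {kink_res} is not on TM6")
        hinge = coords[kink_pos[0]]
        h_axis, _ = _helix_axis(coords[tm6])
        # bend about an axis perpendicular to the helix axis, through the hinge
        ref = np.array([1.0, 0.0, 0.0])
        if abs(h_axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        bend_axis = np.cross(h_axis, ref)
        lower = tm6[coords[tm6][:, 2] < hinge[2]]
        coords[lower] = _rotate_about_axis(coords[lower], hinge, bend_axis,
                                           spec.kink_angle)

    active = Structure(coords, bundle.annotations.copy())
    inactive_contacts = _contact_set(bundle.coords, res_idx, contact_cutoff)
    active_contacts = _contact_set(coords, res_idx, contact_cutoff)
    return PivotResult(
        active=active,
        broken_contacts=sorted(inactive_contacts - active_contacts),
        formed_contacts=sorted(active_contacts - inactive_contacts))


def sample_ensemble(structure: Structure, sigma: float, n_frames: int,
                    seed: int, provenance: str = "synthetic"
                    ) -> ConformationEnsemble:
    """Thermal-like ensemble: i.i.d. isotropic Gaussian Cα displacements."""
    if sigma < 0 or n_frames < 1:
        raise ValueError("need sigma >= 0 and n_frames >= 1")
    rng = np.random.default_rng(seed)
    frames = np.repeat(structure.coords[None], n_frames, axis=0)
    if sigma > 0:
        frames = frames + rng.normal(0.0, sigma, size=frames.shape)
    return ConformationEnsemble(frames, structure.annotations, provenance)
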