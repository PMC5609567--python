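"""Positional-fluctuation PCA over Cα conformational ensembles.

Frames are iteratively superposed onto their running mean (Kabsch), the
3N x 3N covariance of Cα coordinates about the mean is diagonalised, and
the leading eigenvector serves as a collective reaction coordinate.  For
a concatenated two-state (inactive + active) ensemble a single non-zero
eigenvalue results, pointing along the inter-state displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SVDSuperimposer import SVDSuperimposer

__all__ = ["ConformationEnsemble", "SuperpositionResult", "EssentialSubspace",
           "superpose", "essential_subspace"]


@dataclass
class ConformationEnsemble:
    """Ordered Cα coordinate frames with per-atom annotations.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, n_atoms, 3)
        Cα coordinates in Å.
    annotations : DataFrame
        Per-atom table with at least ``residue_index`` (1-based primary
        sequence); typically also ``residue_name``, ``helix`` (TM1..TM7
        or ``loop``) and ``wootten`` (class B label such as ``6.49b``).
    provenance : str or sequence of str
        ``inactive`` / ``active`` / ``transition`` / ``synthetic``; either
        one tag for the whole ensemble or one per frame.
    """

    frames: np.ndarray
    annotations: pd.DataFrame
    provenance: object = "synthetic"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("coordinates must be finite")
        if len(self.annotations) != self.frames.shape[1]:
            raise ValueError("annotation rows must match atom count")
        if not isinstance(self.provenance, str):
            self.provenance = np.asarray(self.provenance)
            if len(self.provenance) != self.n_frames:
                raise ValueError("need one provenance tag per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_tags(self) -> np.ndarray:
        if isinstance(self.provenance, str):
            return np.full(self.n_frames, self.provenance)
        return self.provenance

    def atom_index(self, residue_index: int) -> int:
        """Row position of a residue (1-based primary-sequence index)."""
        rows = np.flatnonzero(
            self.annotations["residue_index"].to_numpy() == residue_index)
        if len(rows) == 0:
            raise KeyError(f"residue {residue_index} not in structure")
        return int(rows[0])

    @classmethod
    def concatenate(cls, *ensembles: "ConformationEnsemble"
                    ) -> "ConformationEnsemble":
        """Join ensembles frame-wise; atom tables must match exactly."""
        first = ensembles[0]
        for e in ensembles[1:]:
            if e.n_atoms != first.n_atoms or not e.annotations[
                    "residue_index"].equals(first.annotations["residue_index"]):
                raise ValueError("ensembles have inconsistent atom tables")
        frames = np.concatenate([e.frames for e in ensembles])
        tags = np.concatenate([e.frame_tags() for e in ensembles])
        return cls(frames, first.annotations, tags)


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition (rotation has determinant +1)."""

    rotation: np.ndarray     # (3, 3), applied as coords @ rotation
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("coordinate sets must have identical (n, 3) shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms to superpose")
    sup = SVDSuperimposer()
    sup.set(reference, mobile)
    sup.run()
    rot, tran = sup.get_rotran()
    return SuperpositionResult(rotation=rot, translation=tran,
                               rmsd=float(sup.get_rms()))


def _align_frames(frames: np.ndarray, tol: float = 1e-6,
                  max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose all frames onto the running mean structure."""
    aligned = frames.copy()
    mean = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(aligned.shape[0]):
            aligned[i] = superpose(aligned[i], mean).apply(aligned[i])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return aligned, mean


@dataclass
class EssentialSubspace:
    """Mean structure plus eigendecomposition of the positional covariance.

    Eigenvalues are in Å², sorted descending; eigenvector columns are
    orthonormal 3N-vectors.  ``project`` gives the scalar coordinate of a
    conformation along one eigenvector after superposing it on the mean.
    """

    mean: np.ndarray          # (n_atoms, 3)
    eigenvectors: np.ndarray  # (3N, k) columns
    eigenvalues: np.ndarray   # (k,) descending
    total_variance: float

    def n_nonzero(self, rel_threshold: float = 1e-8) -> int:
        if self.eigenvalues[0] <= 0:
            return 0
        return int(np.sum(self.eigenvalues > rel_threshold
                          * self.eigenvalues[0]))

    def align(self, coords: np.ndarray) -> np.ndarray:
        """Superpose a conformation onto the subspace mean structure.

        Coordinates handed to :func:`rampkit.ed_transition.ed_drive`
        should be aligned this way first, so that the eigenvector and the
        structure share one frame of reference.
        """
        coords = np.asarray(coords, dtype=float)
        return superpose(coords, self.mean).apply(coords)

    def project(self, coords: np.ndarray, component: int = 0,
                align: bool = True) -> float:
        coords = np.asarray(coords, dtype=float)
        if align:
            coords = superpose(coords, self.mean).apply(coords)
        delta = (coords - self.mean).ravel()
        return float(delta @ self.eigenvectors[:, component])


def essential_subspace(ensemble: ConformationEnsemble,
                       align_tol: float = 1e-6) -> EssentialSubspace:
    """PCA of Cα positional fluctuations about the aligned ensemble mean.

    The covariance is non-mass-weighted and normalised by the number of
    frames, so the eigenvalue sum equals the total mean-square
    fluctuation.  The sign of each eigenvector is fixed so that frames
    tagged ``active`` project positively on it (falling back to making
    the first non-zero component positive).
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames to compute fluctuations")
    aligned, mean = _align_frames(ensemble.frames, tol=align_tol)
    X = aligned.reshape(ensemble.n_frames, -1) - mean.ravel()
    cov = (X.T @ X) / ensemble.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    tags = ensemble.frame_tags()
    active = tags == "active"
    for k in range(evecs.shape[1]):
        v = evecs[:, k]
        if active.any():
            sign = np.sign(np.mean(X[active] @ v))
        else:
            nz = np.flatnonzero(np.abs(v) > 1e-12)
            sign = np.sign(v[nz[0]]) if len(nz) else 1.0
        if sign < 0:
            evecs[:, k] = -v
    return EssentialSubspace(mean=mean, eigenvectors=evecs,
                             eigenvalues=evals,
                             total_variance=float(np.sum(evals)))
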