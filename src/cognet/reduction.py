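"""Two-stage PCA reduction and MDL model-order selection.

Group spatial ICA reduces each subject's voxels x time matrix to its leading
temporal principal directions, concatenates the reduced matrices across
subjects along the (reduced) time axis, and whitens the top-K group subspace.
The number of latent sources K can be chosen by the minimum-description-length
criterion evaluated on the group eigenvalue spectrum.

Conventions
-----------
* Subject reduction keeps the top ``n_keep`` right-singular directions of the
  voxel-centred data; the stored transform reconstructs the data up to the
  discarded variance.
* The whitened group matrix is ``K x voxels`` with zero-mean, unit-variance
  rows — spatial ICA treats voxels as the i.i.d. sample dimension, so this is
  the matrix handed to the ICA engine.
* Eigenvalues are those of the pooled temporal covariance estimated over the
  mask voxels; the MDL sample count therefore defaults to the number of
  voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import RankError, ShapeError, ValidationError

__all__ = ["EigSpectrum", "ReducedData", "reduce_subject", "concat_group_pca",
           "estimate_order_mdl"]

EIG_CLAMP = 1e-12


@dataclass
class EigSpectrum:
    """Descending nonnegative eigenvalue spectrum with its sample count."""

    eigenvalues: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9 * max(1.0, abs(ev[0]) if len(ev) else 1.0)):
            raise ValidationError("eigenvalues must be sorted descending")
        ev = np.where(ev < EIG_CLAMP, 0.0, ev)
        if np.any(ev < 0):
            raise ValidationError("eigenvalues must be nonnegative")
        self.eigenvalues = ev


@dataclass
class ReducedData:
    """Whitened K-dimensional group data plus the transforms to undo it."""

    whitened: np.ndarray          # (K, V) zero-mean unit-variance rows
    whitening: np.ndarray         # (K, L): whitened = whitening @ concatenated.T
    dewhitening: np.ndarray       # (L, K): dewhitening @ whitening = I on subspace
    spectrum: EigSpectrum         # full group spectrum (length min(V, L))
    subject_transforms: list = field(default_factory=list)  # per-subject (T, n_keep)
    n_voxels: int = 0

    @property
    def k(self) -> int:
        return self.whitened.shape[0]


def _centered(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ShapeError("expected a 2-D voxels x time matrix")
    return data - data.mean(axis=1, keepdims=True)


def reduce_subject(data, n_keep: int) -> tuple[np.ndarray, np.ndarray]:
    """Project a subject's series onto its top temporal principal directions.

    Parameters
    ----------
    data:
        A :class:`~cognet.bold.MaskedBold` or a raw voxels x time array.  Each
        voxel's series is mean-centred first.
    n_keep:
        Number of principal time-directions to retain; must not exceed the
        numerical rank.

    Returns
    -------
    (reduced, transform):
        ``reduced`` is voxels x n_keep; ``transform`` the (T, n_keep) matrix
        of right singular vectors, so ``reduced @ transform.T`` reconstructs
        the centred data up to the discarded variance.
    """
    X = _centered(getattr(data, "data", data))
    n_vox, n_t = X.shape
    if n_keep > min(n_vox, n_t):
        raise RankError(f"n_keep={n_keep} exceeds min(voxels, timepoints)={min(n_vox, n_t)}")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if n_keep > rank:
        raise RankError(f"n_keep={n_keep} exceeds numerical rank {rank}")
    V = vt[:n_keep].T
    return X @ V, V


def concat_group_pca(subject_matrices: list[np.ndarray], k: int) -> ReducedData:
    """Temporally concatenated group PCA with whitening to K dimensions.

    ``subject_matrices`` are the per-subject reduced (voxels x n_keep)
    matrices from :func:`reduce_subject`; all must share the voxel dimension.
    A single unreduced subject is the degenerate case and reduces to plain
    subject PCA.
    """
    if not subject_matrices:
        raise ValidationError("no subject matrices given")
    n_vox = subject_matrices[0].shape[0]
    for i, m in enumerate(subject_matrices):
        if m.ndim != 2 or m.shape[0] != n_vox:
            raise ShapeError(f"subject {i} has {m.shape[0]} voxels, expected {n_vox}")
    G = np.concatenate([np.asarray(m, dtype=float) for m in subject_matrices], axis=1)
    G = G - G.mean(axis=0, keepdims=True)       # zero-mean columns over voxels
    u, s, vt = np.linalg.svd(G, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        raise RankError(f"K={k} exceeds pooled rank {rank}")
    eigenvalues = s**2 / n_vox
    sqrt_v = np.sqrt(n_vox)
    whitened = sqrt_v * u[:, :k].T              # (K, V): unit variance rows
    whitening = sqrt_v * (vt[:k] / s[:k, None]).conj()     # (K, L)
    dewhitening = vt[:k].T * (s[:k] / sqrt_v)   # (L, K)
    return ReducedData(
        whitened=whitened,
        whitening=whitening,
        dewhitening=dewhitening,
        spectrum=EigSpectrum(eigenvalues=eigenvalues, n_samples=n_vox),
        n_voxels=n_vox,
    )


def estimate_order_mdl(spectrum: EigSpectrum) -> int:
    """Number of latent sources by minimum description length.

    Uses the classical signal-array form: for each candidate order ``k`` the
    description length is

    ``MDL(k) = -(p - k) N log(gm(l_{k+1..p}) / am(l_{k+1..p}))
               + k (2p - k + 1)/2 log N``

    with ``gm``/``am`` the geometric/arithmetic means of the trailing
    eigenvalues and ``N`` the number of samples behind the covariance
    estimate.  Returns the argmin over ``k = 0..p-1``; an (all-equal)
    structureless spectrum returns 0 with a warning.  The estimate is
    invariant to a global rescaling of the spectrum.
    """
    ev = np.asarray(spectrum.eigenvalues, dtype=float)
    p = len(ev)
    n = int(spectrum.n_samples)
    if p < 3 or len(np.unique(ev)) < 3:
        if np.allclose(ev, ev[0] if p else 0.0):
            warnings.warn("degenerate (flat) eigenvalue spectrum: no detectable sources")
            return 0
        raise ValidationError("need at least 3 distinct eigenvalues for MDL")
    if n <= p:
        raise ValidationError(f"n_samples={n} must exceed the number of eigenvalues p={p}")
    if np.allclose(ev, ev[0]):
        warnings.warn("degenerate (flat) eigenvalue spectrum: no detectable sources")
        return 0
    positive = ev[ev > 0]
    scale = positive.mean()                      # scale invariance + stability
    ev = ev / scale
    mdl = np.full(p, np.inf)
    logn = np.log(n)
    for k in range(p):
        tail = ev[k:]
        if np.all(tail <= 1e-12):
            # numerically-zero noise floor: k sources describe the data perfectly
            mdl[k] = -np.inf
            break
        if np.any(tail <= 1e-12):
            continue
        log_gm = np.mean(np.log(tail))
        am = np.mean(tail)
        mdl[k] = -(p - k) * n * (log_gm - np.log(am)) + 0.5 * k * (2 * p - k + 1) * logn
    return int(np.argmin(mdl))
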