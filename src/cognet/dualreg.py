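"""Dual (spatial-temporal) regression back-reconstruction.

Given the group component maps, each subject's data are reduced to
subject-specific time courses (stage 1: regress every time point's volume on
the group maps) and subject-specific spatial maps (stage 2: regress every
voxel's series on the stage-1 time courses).  Stage-1 design columns are the
group maps demeaned over voxels; stage-2 time courses are variance-normalised
by default so the stage-2 betas carry the amplitude information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bold import MaskedBold
from .errors import RankError, ShapeError

__all__ = ["SubjectNetworks", "dual_regression"]

COND_MAX = 1e8


@dataclass
class SubjectNetworks:
    """Subject-level time courses and spatial maps, ordered like the group set."""

    subject_id: str
    timecourses: np.ndarray     # (K, T)
    spatial_maps: np.ndarray    # (K, V)


def _check_rank(design: np.ndarray, ids: list[str] | None) -> None:
    cond = np.linalg.cond(design)
    if cond > COND_MAX:
        # name the culprits: pairs of near-collinear columns
        X = design / np.linalg.norm(design, axis=0, keepdims=True)
        corr = np.abs(X.T @ X)
        np.fill_diagonal(corr, 0.0)
        pairs = np.argwhere(corr > 0.999)
        names = ids or [f"IC{i + 1}" for i in range(design.shape[1])]
        culprits = sorted({names[i] for i, j in pairs} | {names[j] for i, j in pairs})
        raise RankError(
            f"group maps are rank deficient (condition {cond:.2e}); "
            f"collinear components: {culprits or 'undetermined'}"
        )


def dual_regression(bold: MaskedBold | np.ndarray, group_maps: np.ndarray,
                    subject_id: str = "", normalize_timecourses: bool = True,
                    component_ids: list[str] | None = None) -> SubjectNetworks:
    """Back-reconstruct one subject's networks from the group maps.

    Parameters
    ----------
    bold:
        The subject's voxels x time data (``MaskedBold`` or raw array); each
        voxel's series is demeaned before both stages.
    group_maps:
        (K, V) group spatial maps over the same mask, full row rank.
    normalize_timecourses:
        Variance-normalise the stage-1 time courses before stage 2 (the
        default), so stage-2 maps are invariant to any rescaling of the group
        maps and the betas carry amplitude.
    """
    X = np.asarray(getattr(bold, "data", bold), dtype=float)
    maps = np.asarray(group_maps, dtype=float)
    if maps.ndim != 2 or X.ndim != 2 or maps.shape[1] != X.shape[0]:
        raise ShapeError(
            f"group maps cover {maps.shape[-1] if maps.ndim == 2 else '?'} voxels, "
            f"data has {X.shape[0]}"
        )
    X = X - X.mean(axis=1, keepdims=True)

    design = (maps - maps.mean(axis=1, keepdims=True)).T       # (V, K)
    _check_rank(design, component_ids)
    timecourses, *_ = np.linalg.lstsq(design, X, rcond=None)   # (K, T)

    tc = timecourses
    if normalize_timecourses:
        sd = tc.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise RankError("a stage-1 time course has zero variance")
        tc = tc / sd
    betas, *_ = np.linalg.lstsq(tc.T, X.T, rcond=None)          # (K, V)
    return SubjectNetworks(subject_id=subject_id, timecourses=timecourses,
                           spatial_maps=betas)
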