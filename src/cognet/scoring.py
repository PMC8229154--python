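"""Network expression scoring by the scaled-subprofile-model projection.

Each subject's back-reconstructed spatial map is projected onto the fixed
group topography after double centering: the subject map first loses its own
voxel mean, then the across-subjects mean profile, and the residual is
projected onto the group z-map (inner product divided by the topography's
squared norm).  Scores are finally z-transformed against the reference
(control) group, so control columns have mean 0 and sd 1 and a patient's
score reads as "standard deviations of network expression away from
controls".

Classical SSM log-transforms strictly positive images before centering; ICA
maps are signed, so the log step is omitted here and the subtractive double
centering retained (``ssm_log=False`` is the only supported setting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dualreg import SubjectNetworks
from .errors import DegenerateError, ShapeError, ValidationError

__all__ = ["NetworkScoreMatrix", "compute_network_scores"]


@dataclass
class NetworkScoreMatrix:
    """Subjects x components expression scores, optionally control-referenced."""

    scores: pd.DataFrame            # index: subject ids, columns: ic ids
    groups: pd.Series               # aligned to scores.index
    reference_group: str | None
    mean_profile: np.ndarray        # (K, V) across-subject mean of centred maps
    topography_norms: np.ndarray    # (K,)

    def group_scores(self, group: str) -> pd.DataFrame:
        return self.scores.loc[self.groups.to_numpy() == group]


def compute_network_scores(subject_maps, group_z_maps: np.ndarray,
                           groups, subject_ids=None, component_ids=None,
                           reference_group: str | None = "Ctr",
                           ssm_log: bool = False) -> NetworkScoreMatrix:
    """Score every subject's expression of every retained group network.

    Parameters
    ----------
    subject_maps:
        List of per-subject (K, V) spatial maps (or ``SubjectNetworks``),
        component order aligned with ``group_z_maps``.
    group_z_maps:
        (K, V) z-scored group topographies.
    groups:
        Per-subject group labels; the ``reference_group`` needs >= 2 members
        when referencing is enabled (``reference_group=None`` disables the
        z step).
    """
    if ssm_log:
        raise ValidationError("log-transform SSM is not supported for signed ICA maps")
    stacked = []
    ids = []
    for i, sm in enumerate(subject_maps):
        if isinstance(sm, SubjectNetworks):
            stacked.append(np.asarray(sm.spatial_maps, dtype=float))
            ids.append(sm.subject_id or f"sub-{i + 1:03d}")
        else:
            stacked.append(np.asarray(sm, dtype=float))
            ids.append(f"sub-{i + 1:03d}")
    if subject_ids is not None:
        ids = list(subject_ids)
    M = np.stack(stacked)                          # (S, K, V)
    Zg = np.asarray(group_z_maps, dtype=float)     # (K, V)
    if M.shape[1:] != Zg.shape:
        raise ShapeError(f"subject maps {M.shape[1:]} do not match group maps {Zg.shape}")
    groups = pd.Series(np.asarray(groups), index=ids, name="group")
    if reference_group is not None and (groups == reference_group).sum() < 2:
        raise ValidationError(
            f"need >= 2 subjects in reference group {reference_group!r}")

    norms = np.einsum("kv,kv->k", Zg, Zg)
    if np.any(norms == 0):
        raise DegenerateError("zero-norm group topography")

    # (b) row centering: remove each subject map's own voxel mean
    M = M - M.mean(axis=2, keepdims=True)
    # (c) double centering: remove the across-subjects mean profile
    mean_profile = M.mean(axis=0)
    R = M - mean_profile[None]
    # (d) projection onto the topography, normalised by its squared norm
    raw = np.einsum("skv,kv->sk", R, Zg) / norms[None, :]
    # (e) z-transform against the reference group
    if reference_group is not None:
        ref = raw[groups.to_numpy() == reference_group]
        mu, sd = ref.mean(axis=0), ref.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise DegenerateError("zero variance in reference-group scores")
        raw = (raw - mu) / sd
    cols = list(component_ids) if component_ids is not None else [
        f"IC{k + 1}" for k in range(Zg.shape[0])]
    scores = pd.DataFrame(raw, index=ids, columns=cols)
    return NetworkScoreMatrix(scores=scores, groups=groups,
                              reference_group=reference_group,
                              mean_profile=mean_profile, topography_norms=norms)
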