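"""End-to-end orchestration: BOLD -> ICA -> QC -> scores -> domain models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bold import MaskedBold
from .dualreg import dual_regression
from .errors import ValidationError
from .ica import IcassoResult, run_icasso
from .metadata import MOCA_DOMAINS
from .modeling import DomainModel, compare_groups, compose_domain_network, \
    count_generated, find_hubs, fit_all_domains
from .qc import ComponentSet, Exclusion, assemble_component_set
from .reduction import ReducedData, concat_group_pca, estimate_order_mdl, reduce_subject
from .scoring import NetworkScoreMatrix, compute_network_scores

__all__ = ["PipelineResult", "analyze_cohort"]


@dataclass
class PipelineResult:
    k: int
    reduced: ReducedData
    icasso: IcassoResult
    components: ComponentSet
    exclusions: list[Exclusion]
    scores: NetworkScoreMatrix
    models: dict[str, DomainModel]
    group_tests: pd.DataFrame | None
    hubs: list = field(default_factory=list)
    composites: dict = field(default_factory=dict)

    @property
    def n_generated(self) -> int:
        return count_generated(self.models)


def analyze_cohort(bolds: list[MaskedBold], metadata: pd.DataFrame,
                   k: int | None = None, subject_keep_factor: float = 1.5,
                   n_runs: int = 20, resample: str = "bootstrap",
                   iq_min: float = 0.8, cutoff: float = 1.0, min_voxels: int = 50,
                   labels: dict[str, str] | None = None,
                   domains=None, alpha_enter: float = 0.05,
                   alpha_remove: float = 0.10, reference_group: str = "Ctr",
                   patient_group: str = "PD", seed: int = 0) -> PipelineResult:
    """Run the full analysis on an in-memory cohort.

    ``k=None`` selects the model order by MDL on the group eigenspectrum;
    otherwise the given order is used (studies commonly fix it).  Subject-level
    PCA keeps ``ceil(subject_keep_factor * k)`` directions, capped at each
    subject's numerical rank.
    """
    if len(bolds) != len(metadata):
        raise ValidationError("metadata rows must match the number of BOLD series")
    groups = metadata["group"].to_numpy()
    subject_ids = metadata["id"].astype(str).tolist()

    if k is None:
        # provisional generous reduction, then MDL on the pooled spectrum
        provisional = min(bolds[0].n_timepoints - 1, 30)
        mats = [reduce_subject(b, _cap_keep(b, provisional))[0] for b in bolds]
        reduced_full = concat_group_pca(mats, k=min(m.shape[1] for m in mats))
        k = estimate_order_mdl(reduced_full.spectrum)
        if k < 1:
            raise ValidationError("MDL found no detectable sources")
    n_keep = int(np.ceil(subject_keep_factor * k))
    mats = [reduce_subject(b, _cap_keep(b, n_keep))[0] for b in bolds]
    reduced = concat_group_pca(mats, k=k)

    icasso = run_icasso(reduced, n_runs=n_runs, resample=resample, seed=seed)
    components, exclusions = assemble_component_set(
        icasso, labels=labels, iq_min=iq_min, cutoff=cutoff, min_voxels=min_voxels)
    if len(components) == 0:
        raise ValidationError("no components survived QC")

    subject_nets = [
        dual_regression(b, components.z_maps, subject_id=sid,
                        component_ids=components.ids)
        for b, sid in zip(bolds, subject_ids)
    ]
    # attach mean low-frequency dominance of back-reconstructed time courses
    from .qc import low_freq_ratio
    for i, comp in enumerate(components):
        ratios = [low_freq_ratio(sn.timecourses[i], b.tr_seconds)
                  for sn, b in zip(subject_nets, bolds)]
        comp.low_freq = float(np.mean(ratios))

    scores = compute_network_scores(subject_nets, components.z_maps, groups,
                                    subject_ids=subject_ids,
                                    component_ids=components.ids,
                                    reference_group=reference_group)
    models = fit_all_domains(scores, metadata, domains=domains,
                             alpha_enter=alpha_enter, alpha_remove=alpha_remove,
                             group=patient_group)
    group_tests = compare_groups(scores)
    generated = [m for m in models.values() if m.generated]
    hubs = find_hubs(models.values()) if len(generated) >= 2 else []
    composites = {d: compose_domain_network(m, components.z_maps,
                                            component_ids=components.ids)
                  for d, m in models.items() if m.generated}
    return PipelineResult(k=k, reduced=reduced, icasso=icasso,
                          components=components, exclusions=exclusions,
                          scores=scores, models=models, group_tests=group_tests,
                          hubs=hubs, composites=composites)


def _cap_keep(bold: MaskedBold, n_keep: int) -> int:
    X = bold.data - bold.data.mean(axis=1, keepdims=True)
    s = np.linalg.svd(X, compute_uv=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    return max(1, min(n_keep, rank))
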