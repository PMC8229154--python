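"""Component quality control and labelling.

Group components are z-scored over the mask, screened on stability (Iq),
user-supplied artifact labels and spatial extent, and tagged with canonical
resting-state network classes.  Artifact identification and network
classification are expert judgements consumed from a two-column label file —
they are not inferred automatically.  Low-frequency dominance of the time
course is computed and reported; by default it is informational only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .errors import DegenerateError, ParameterError, ValidationError

__all__ = [
    "ComponentRecord", "ComponentSet", "Exclusion", "CANONICAL_LABELS",
    "zscore_map", "voxel_extent_filter", "low_freq_ratio",
    "read_labels", "assemble_component_set",
]

#: canonical resting-state network classes plus the artifact / unlabeled tags
CANONICAL_LABELS = ("artifact", "AUD", "CCN", "DMN", "SMN", "VIS", "CBL", "SCN",
                    "unlabeled")

DEFAULT_IQ_MIN = 0.8
DEFAULT_Z_CUTOFF = 1.0
DEFAULT_MIN_VOXELS = 50
DEFAULT_BAND_EDGE_HZ = 0.10


def zscore_map(raw: np.ndarray) -> np.ndarray:
    """Z-score a spatial map over the mask (population sd; mean 0, sd 1)."""
    v = np.asarray(raw, dtype=float)
    sd = v.std()
    if sd == 0:
        raise DegenerateError("constant map cannot be z-scored")
    return (v - v.mean()) / sd


def voxel_extent_filter(z_map: np.ndarray, cutoff: float = DEFAULT_Z_CUTOFF,
                        min_voxels: int = DEFAULT_MIN_VOXELS) -> tuple[bool, int]:
    """Extent rule: fail iff fewer than ``min_voxels`` voxels reach ``|z| >= cutoff``.

    Exactly ``min_voxels`` suprathreshold voxels passes (the rule excludes
    strictly-smaller volumes).  Returns ``(passed, count)``.
    """
    count = int((np.abs(np.asarray(z_map, dtype=float)) >= cutoff).sum())
    return count >= min_voxels, count


def low_freq_ratio(timecourse: np.ndarray, tr_seconds: float,
                   band_edge_hz: float = DEFAULT_BAND_EDGE_HZ) -> float:
    """Fraction of spectral power at frequencies in ``(0, band_edge_hz]``.

    Computed from the periodogram, excluding the zero-frequency (mean) term.
    A value near 1 indicates the low-frequency-dominated fluctuation expected
    of a genuine resting-state component; white noise gives roughly
    ``band_edge / nyquist``.
    """
    tc = np.asarray(timecourse, dtype=float)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 < band_edge_hz < nyquist:
        raise ParameterError(f"band edge must lie in (0, {nyquist}) Hz")
    if tc.std() == 0:
        raise DegenerateError("constant time course has no defined spectrum")
    freqs, power = periodogram(tc, fs=1.0 / tr_seconds)
    nonzero = freqs > 0
    total = power[nonzero].sum()
    in_band = nonzero & (freqs <= band_edge_hz)
    return float(power[in_band].sum() / total)


@dataclass
class ComponentRecord:
    """One group component with its QC metrics and label."""

    ic_id: str
    z_map: np.ndarray
    iq: float
    timecourse: np.ndarray | None = None
    low_freq: float | None = None
    label: str = "unlabeled"
    suprathreshold_count: int = 0

    def __post_init__(self) -> None:
        if self.label not in CANONICAL_LABELS:
            raise ValidationError(f"unknown label {self.label!r} for {self.ic_id}")


@dataclass
class Exclusion:
    ic_id: str
    reason: str          # machine-readable: low_iq | artifact | small_extent | low_freq
    detail: str


@dataclass
class ComponentSet:
    """Retained components in a fixed order."""

    components: list[ComponentRecord] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [c.ic_id for c in self.components]

    @property
    def z_maps(self) -> np.ndarray:
        return np.array([c.z_map for c in self.components])

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)


def read_labels(path) -> dict[str, str]:
    """Read a two-column (ic_id, label) whitespace-separated label file."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"label file line {line_no}: expected 2 columns")
            ic_id, label = parts
            if ic_id in labels:
                raise ValidationError(f"duplicate label for {ic_id}")
            if label not in CANONICAL_LABELS:
                raise ValidationError(f"unknown label {label!r} on line {line_no}")
            labels[ic_id] = label
    return labels


def assemble_component_set(icasso, labels: dict[str, str] | None = None,
                           iq_min: float = DEFAULT_IQ_MIN,
                           cutoff: float = DEFAULT_Z_CUTOFF,
                           min_voxels: int = DEFAULT_MIN_VOXELS,
                           timecourses: np.ndarray | None = None,
                           tr_seconds: float | None = None,
                           enforce_lowfreq: float | None = None,
                           ) -> tuple[ComponentSet, list[Exclusion]]:
    """Screen ICASSO components into a retained set plus a reasoned report.

    Components are named IC1..ICK in the ICASSO output order.  Exclusions are
    applied in a fixed order — stability (``iq < iq_min``), then the artifact
    label, then the voxel-extent rule, then (only if ``enforce_lowfreq`` is
    set) low-frequency dominance.  Retained and excluded sets partition the
    input, and re-running the screen on the retained set is a no-op.
    """
    maps = np.asarray(getattr(icasso, "centrotypes", icasso), dtype=float)
    iqs = np.asarray(getattr(icasso, "iq", np.ones(maps.shape[0])), dtype=float)
    labels = dict(labels or {})
    ids = [f"IC{i + 1}" for i in range(maps.shape[0])]
    unknown = set(labels) - set(ids)
    if unknown:
        raise ValidationError(f"label file references unknown components: {sorted(unknown)}")

    retained = ComponentSet()
    report: list[Exclusion] = []
    for i, ic_id in enumerate(ids):
        z = zscore_map(maps[i])
        passed, count = voxel_extent_filter(z, cutoff=cutoff, min_voxels=min_voxels)
        label = labels.get(ic_id, "unlabeled")
        tc = timecourses[i] if timecourses is not None else None
        lf = (low_freq_ratio(tc, tr_seconds) if tc is not None and tr_seconds else None)
        if iqs[i] < iq_min:
            report.append(Exclusion(ic_id, "low_iq", f"Iq={iqs[i]:.3f} < {iq_min}"))
            continue
        if label == "artifact":
            report.append(Exclusion(ic_id, "artifact", "labelled artifact"))
            continue
        if not passed:
            report.append(Exclusion(
                ic_id, "small_extent",
                f"{count} voxels at |z|>={cutoff} < {min_voxels}"))
            continue
        if enforce_lowfreq is not None and lf is not None and lf < enforce_lowfreq:
            report.append(Exclusion(ic_id, "low_freq",
                                    f"low-frequency ratio {lf:.3f} < {enforce_lowfreq}"))
            continue
        retained.components.append(ComponentRecord(
            ic_id=ic_id, z_map=z, iq=float(iqs[i]), timecourse=tc,
            low_freq=lf, label=label, suprathreshold_count=count))
    return retained, report


def format_exclusion_report(report: list[Exclusion]) -> str:
    lines = ["ic_id\treason\tdetail"]
    lines += [f"{e.ic_id}\t{e.reason}\t{e.detail}" for e in report]
    return "\n".join(lines) + "\n"
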