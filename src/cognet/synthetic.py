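"""Synthetic resting-state fMRI cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, not anatomy: spatially compact Gaussian-blob source maps inside an
ellipsoidal brain mask, mixed linearly into voxels x time matrices by
band-limited (default 0.01-0.08 Hz, TR = 2 s) time courses, with additive
white Gaussian noise.  Each subject expresses every source with its own
loading, and the cognitive domain scores of the patient group are generated
by planted sparse linear models on those loadings — so every downstream stage
(ICA recovery, QC survival, dual regression, expression scoring, stepwise
selection) has a quantitative recovery test against known truth.

Cohort sizes default to 40 patients (PD) and 15 controls (Ctr); controls get
an MMSE but no MoCA domain scores, patients get both, mirroring the study
design the pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bold import MaskedBold, mask_coordinates, save_bold, save_map
from .errors import ParameterError, SizingError, ValidationError
from .metadata import MOCA_DOMAINS, write_subject_table

__all__ = [
    "GroundTruth",
    "PlantedModel",
    "CohortConfig",
    "simulate_sources",
    "simulate_timecourses",
    "simulate_subject_bold",
    "simulate_cohort",
    "calibrate_residual_sd",
    "match_components",
]

#: Variance of the round-to-integer discretisation step, treated as part of
#: the non-signal variance when calibrating a planted model to a target R².
ROUNDING_VAR = 1.0 / 12.0


@dataclass
class PlantedModel:
    """A sparse linear model generating one domain's score from loadings.

    ``score = intercept + sum_k beta_k * (loading_k - loading_mean) + eps``
    with ``eps ~ N(0, residual_sd^2)``, then rounded and clipped to the
    domain's integer range.  ``residual_sd=None`` means "calibrate from
    ``r2_target`` at generation time".  An empty component list is a null
    model: the score is pure noise around the intercept (the pipeline should
    then fail to generate a domain network).
    """

    components: tuple[int, ...]
    betas: tuple[float, ...]
    r2_target: float | None = 0.6
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if len(self.components) != len(self.betas):
            raise ValidationError("components and betas must have equal length")


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    source_maps: np.ndarray          # (K, V), unit-norm rows
    subject_loadings: np.ndarray     # (S, K)
    groups: np.ndarray               # (S,) of "PD"/"Ctr"
    mask: np.ndarray                 # 3-D boolean
    mask_index: np.ndarray           # (V, 3)
    affine: np.ndarray
    grid_shape: tuple[int, int, int]
    band_hz: tuple[float, float]
    amplitudes: np.ndarray           # (K,) time-course amplitude per source
    noise_sd: float
    tr_seconds: float
    n_timepoints: int
    planted_models: dict[str, PlantedModel]
    domain_ranges: Mapping[str, tuple[int, int]]
    residual_sds: dict[str, float] = field(default_factory=dict)
    loading_mean: float = 1.0

    @property
    def n_components(self) -> int:
        return self.source_maps.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.subject_loadings.shape[0]


def _ellipsoid_mask(grid_shape: tuple[int, int, int], fill: float = 0.95) -> np.ndarray:
    center = (np.asarray(grid_shape) - 1) / 2.0
    radii = np.maximum((np.asarray(grid_shape) - 1) / 2.0 * fill, 1e-9)
    gx, gy, gz = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    coords = np.stack([gx, gy, gz], axis=-1)
    d2 = (((coords - center) / radii) ** 2).sum(axis=-1)
    return d2 <= 1.0


def _pick_centers(mask: np.ndarray, n: int, min_sep: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point placement of blob centres inside the mask core."""
    grid_shape = mask.shape
    center = (np.asarray(grid_shape) - 1) / 2.0
    radii = (np.asarray(grid_shape) - 1) / 2.0 * 0.95
    coords = mask_coordinates(mask).astype(float)
    core = coords[(((coords - center) / (radii * 0.72)) ** 2).sum(axis=1) <= 1.0]
    if len(core) < n:
        raise SizingError(f"grid {grid_shape} too small for {n} sources")

    def min_dist(pts: np.ndarray) -> float:
        if len(pts) < 2:
            return np.inf
        pair = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return float(pair[~np.eye(len(pts), dtype=bool)].min())

    best, best_d = None, -np.inf
    for _ in range(16):                     # restarts over the random first point
        chosen = [core[rng.integers(len(core))]]
        for _ in range(n - 1):
            dists = np.min(
                np.linalg.norm(core[:, None, :] - np.asarray(chosen)[None, :, :],
                               axis=-1), axis=1)
            chosen.append(core[int(np.argmax(dists))])
        pts = np.asarray(chosen, dtype=float)
        for _ in range(4):                  # local sweeps: re-seat each point
            for i in range(n):
                others = np.delete(pts, i, axis=0)
                d_to_others = np.min(
                    np.linalg.norm(core[:, None, :] - others[None, :, :], axis=-1),
                    axis=1)
                pts[i] = core[int(np.argmax(d_to_others))]
        d = min_dist(pts)
        if d > best_d:
            best, best_d = pts, d
        if best_d >= min_sep * 1.2:
            break
    if n > 1 and best_d < min_sep:
        raise SizingError(
            f"grid {grid_shape} too small: blob centres closer than {min_sep:.1f} voxels"
        )
    return best


def simulate_sources(grid_shape: tuple[int, int, int], n_components: int,
                     seed: int, blob_sigma: float = 1.5,
                     min_extent: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Generate compact, near-orthogonal Gaussian-blob source maps.

    Returns ``(source_maps, mask)`` with ``source_maps`` of shape
    ``(n_components, n_mask_voxels)``, unit L2 norm per row, pairwise
    ``|cosine| < 0.2``, and every map having at least ``min_extent`` voxels at
    ``|z| >= 1`` after z-scoring over the mask — so every true source survives
    the pipeline's voxel-extent filter by construction.  Deterministic for a
    given seed.
    """
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(grid_shape)
    coords = mask_coordinates(mask).astype(float)
    # |cos| between two isotropic Gaussians at distance d is exp(-d^2/(4 sigma^2));
    # aim for 0.05 so the maps are near-orthogonal (contract: < 0.2) and ICA's
    # uncorrelatedness constraint costs almost nothing in recovery fidelity.
    min_sep = 2.0 * blob_sigma * np.sqrt(np.log(20.0))
    centers = _pick_centers(mask, n_components, min_sep, rng)
    maps = np.empty((n_components, len(coords)))
    for k, c in enumerate(centers):
        d2 = ((coords - c) ** 2).sum(axis=1)
        v = np.exp(-d2 / (2.0 * blob_sigma**2))
        maps[k] = v / np.linalg.norm(v)
    if n_components > 1:
        cos = maps @ maps.T
        off = np.abs(cos[~np.eye(n_components, dtype=bool)])
        if off.max() >= 0.2:
            raise SizingError(
                f"grid {grid_shape} too small: source overlap |cos|={off.max():.2f} >= 0.2"
            )
    for k in range(n_components):
        z = (maps[k] - maps[k].mean()) / maps[k].std()
        if int((np.abs(z) >= 1.0).sum()) < min_extent:
            raise SizingError(
                f"source {k} has fewer than {min_extent} voxels at |z|>=1; "
                "increase the grid or blob_sigma"
            )
    return maps, mask


def simulate_timecourses(n_components: int, n_timepoints: int, tr_seconds: float,
                         band_hz: tuple[float, float],
                         rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian time courses, standardised to mean 0 / sd 1.

    Built in the frequency domain: independent complex-Gaussian coefficients
    on the discrete frequencies inside ``band_hz``, zero elsewhere, so all
    spectral power lies inside the band by construction.
    """
    if tr_seconds <= 0:
        raise ParameterError("tr_seconds must be positive")
    nyquist = 1.0 / (2.0 * tr_seconds)
    lo, hi = band_hz
    if not 0 <= lo < hi:
        raise ParameterError(f"invalid band {band_hz}")
    if hi >= nyquist:
        raise ParameterError(
            f"band edge {hi} Hz is at or above the Nyquist frequency {nyquist} Hz"
        )
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    in_band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if not in_band.any():
        raise ParameterError(f"no discrete frequencies inside band {band_hz}")
    spec = np.zeros((n_components, len(freqs)), dtype=complex)
    n_bins = int(in_band.sum())
    spec[:, in_band] = rng.normal(size=(n_components, n_bins)) + 1j * rng.normal(
        size=(n_components, n_bins)
    )
    tc = np.fft.irfft(spec, n=n_timepoints, axis=1)
    tc -= tc.mean(axis=1, keepdims=True)
    sd = tc.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ParameterError("degenerate time course (zero variance)")
    return tc / sd


def simulate_subject_bold(truth: GroundTruth, subject_index: int,
                          n_timepoints: int | None = None,
                          tr_seconds: float | None = None,
                          seed: int = 0) -> MaskedBold:
    """One subject's voxels x time BOLD matrix from the ground truth.

    ``data = sum_k loading_k * amplitude_k * map_k (x) timecourse_k + noise``.
    The random stream is derived from ``(seed, subject_index)`` so a cohort is
    reproducible subject by subject.
    """
    n_timepoints = truth.n_timepoints if n_timepoints is None else n_timepoints
    tr_seconds = truth.tr_seconds if tr_seconds is None else tr_seconds
    if n_timepoints < 30:
        raise ParameterError("n_timepoints must be >= 30")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))
    tc = simulate_timecourses(truth.n_components, n_timepoints, tr_seconds,
                              truth.band_hz, rng)
    weights = truth.subject_loadings[subject_index] * truth.amplitudes
    data = truth.source_maps.T @ (weights[:, None] * tc)
    if truth.noise_sd > 0:
        data = data + truth.noise_sd * rng.normal(size=data.shape)
    return MaskedBold(data=data, mask_index=truth.mask_index, affine=truth.affine,
                      tr_seconds=tr_seconds)


def calibrate_residual_sd(betas: Sequence[float], loading_sd: float,
                          r2_target: float, rounding_var: float = ROUNDING_VAR) -> float:
    """Residual sd giving a planted model its target generating R².

    Signal variance is ``sum(beta^2) * loading_sd^2`` (loadings are
    independent across components); the integer rounding of the final score
    contributes ``rounding_var`` of additional non-signal variance, which is
    subtracted from the noise budget so the realised R² matches the target.
    """
    if not 0 < r2_target < 1:
        raise ParameterError("r2_target must lie strictly between 0 and 1")
    signal_var = float(np.sum(np.square(betas))) * loading_sd**2
    noise_var = signal_var * (1.0 - r2_target) / r2_target - rounding_var
    return float(np.sqrt(max(noise_var, 0.0)))


def _default_planted_models(loading_sd: float,
                            n_components: int = 6) -> dict[str, PlantedModel]:
    """Default planted domain models on six components.

    Per-domain signal sd is scaled to (range width)/6 so scores occupy their
    integer range with little clipping at the range edges (clipping would
    erode the calibrated R²); delayed recall is a null model so the pipeline
    reproduces the "no network generated" outcome class.
    """
    def scaled(comps, signs, width, r2):
        # fold component indices into the available range, drop duplicates
        comps = tuple(dict.fromkeys(c % n_components for c in comps))
        signs = signs[:len(comps)]
        sd_target = width / 6.0
        c = sd_target / (loading_sd * np.sqrt(len(comps)))
        return PlantedModel(components=comps,
                            betas=tuple(c * s for s in signs), r2_target=r2)

    return {
        "visuospatial_executive": scaled((0, 3), (+1, -1), 5, 0.6),
        "naming": scaled((1,), (+1,), 3, 0.6),
        "attention": scaled((0, 1, 2), (+1, -1, +1), 6, 0.6),
        "language": scaled((2, 4), (+1, -1), 3, 0.6),
        "abstraction": scaled((5,), (-1,), 2, 0.3),
        "delayed_recall": PlantedModel(components=(), betas=(), r2_target=None,
                                       residual_sd=1.0),
        "orientation": scaled((1, 4), (-1, +1), 6, 0.6),
    }


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort (defaults are the study conditions)."""

    grid_shape: tuple[int, int, int] = (20, 20, 10)
    n_components: int = 6
    n_pd: int = 40
    n_ctr: int = 15
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    noise_sd: float = 0.1
    blob_sigma: float = 1.5
    loading_mean: float = 1.0
    loading_sd: float = 0.3
    #: additive shift of the PD group's mean loading, per component index;
    #: None -> mild expression loss on the last two components
    group_effect: dict | None = None
    planted_models: dict[str, PlantedModel] | None = None
    ar1_noise: float = 0.0   # optional AR(1) coefficient for temporally correlated noise
    round_scores: bool = True  # integer rounding/clipping of domain scores

    def resolved_models(self) -> dict[str, PlantedModel]:
        models = self.planted_models
        if models is None:
            models = _default_planted_models(self.loading_sd, self.n_components)
        for name, pm in models.items():
            if name not in MOCA_DOMAINS:
                raise ValidationError(f"unknown MoCA domain {name!r}")
            for c in pm.components:
                if not 0 <= c < self.n_components:
                    raise ValidationError(
                        f"planted model {name!r} references unknown component {c}"
                    )
        return models


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: per-subject BOLD, metadata and truth."""

    truth: GroundTruth
    bolds: list[MaskedBold]
    metadata: pd.DataFrame
    paths: dict | None = None


def _generate_metadata(cfg: CohortConfig, truth: GroundTruth,
                       rng: np.random.Generator) -> pd.DataFrame:
    n = truth.n_subjects
    groups = truth.groups
    is_pd = groups == "PD"
    age = np.where(is_pd, rng.normal(69, 9.0, n), rng.normal(66, 13.9, n))
    age = np.clip(np.round(age), 40, 90).astype(int)
    sex = np.where(rng.random(n) < np.where(is_pd, 22 / 40, 7 / 15), "M", "F")
    handed = np.where(rng.random(n) < np.where(is_pd, 36 / 40, 14 / 15), "R", "L")
    mmse = np.where(is_pd, rng.normal(26.5, 2.67, n), rng.normal(28.6, 1.55, n))
    mmse = np.clip(np.round(mmse), np.where(is_pd, 0, 24), 30).astype(int)
    duration = np.where(is_pd, np.abs(rng.normal(5.1, 5.84, n)).round(1), np.nan)
    hy = np.where(is_pd, np.clip(np.round(rng.normal(2.1, 0.97, n)), 1, 5), np.nan)
    led = np.where(is_pd, np.clip(rng.normal(201, 274.7, n), 0, None).round(0), np.nan)
    disp = rng.uniform(0.2, 2.0, n).round(2)

    table = pd.DataFrame({
        "id": [f"sub-{i + 1:03d}" for i in range(n)],
        "group": groups,
        "age": age,
        "sex": sex,
        "handedness": handed,
        "disease_duration": duration,
        "hoehn_yahr": hy,
        "mmse": mmse,
        "dose_levodopa_carbidopa": np.where(is_pd, led, 0.0),
        "led": np.where(is_pd, led, np.nan),
        "max_displacement_mm": disp,
    })

    centered = truth.subject_loadings - truth.loading_mean
    for name, pm in truth.planted_models.items():
        lo, hi = truth.domain_ranges[name]
        intercept = (lo + hi) / 2.0
        lin = np.full(n, intercept)
        for c, b in zip(pm.components, pm.betas):
            lin = lin + b * centered[:, c]
        resid_sd = truth.residual_sds[name]
        y = lin + rng.normal(0.0, resid_sd, n)
        if cfg.round_scores:
            y = np.clip(np.round(y), lo, hi)
        table[f"moca_{name}"] = np.where(is_pd, y, np.nan)
    moca_cols = [f"moca_{d}" for d in truth.planted_models]
    table["moca_total"] = table[moca_cols].sum(axis=1).where(is_pd)
    return table


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    out_dir=None) -> CohortBundle:
    """Generate a full synthetic cohort (BOLD series + metadata + truth).

    With ``out_dir`` given, also writes one 4D NIfTI per subject, the 3D
    mask, the metadata table (``participants.tsv``) and the config
    (``config.yaml``); outputs are deterministic for a given config + seed.
    """
    cfg = config or CohortConfig()
    if cfg.n_pd < 2 or cfg.n_ctr < 2:
        raise ValidationError("each group needs at least 2 subjects")
    models = cfg.resolved_models()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 987654321]))

    maps, mask = simulate_sources(cfg.grid_shape, cfg.n_components, seed=seed,
                                  blob_sigma=cfg.blob_sigma)
    n = cfg.n_pd + cfg.n_ctr
    groups = np.array(["PD"] * cfg.n_pd + ["Ctr"] * cfg.n_ctr)
    loadings = rng.normal(cfg.loading_mean, cfg.loading_sd,
                          size=(n, cfg.n_components))
    group_effect = cfg.group_effect
    if group_effect is None:
        group_effect = {c: -0.15 for c in range(max(cfg.n_components - 2, 0),
                                                cfg.n_components)}
    for comp, shift in group_effect.items():
        if not 0 <= int(comp) < cfg.n_components:
            raise ValidationError(f"group_effect references unknown component {comp}")
        loadings[groups == "PD", int(comp)] += float(shift)

    residual_sds = {}
    for name, pm in models.items():
        if pm.residual_sd is not None:
            residual_sds[name] = float(pm.residual_sd)
        elif pm.components:
            residual_sds[name] = calibrate_residual_sd(pm.betas, cfg.loading_sd,
                                                       pm.r2_target)
        else:
            residual_sds[name] = 1.0

    truth = GroundTruth(
        source_maps=maps,
        subject_loadings=loadings,
        groups=groups,
        mask=mask,
        mask_index=mask_coordinates(mask),
        affine=np.diag([3.0, 3.0, 3.0, 1.0]),
        grid_shape=tuple(cfg.grid_shape),
        band_hz=tuple(cfg.band_hz),
        amplitudes=np.ones(cfg.n_components),
        noise_sd=cfg.noise_sd,
        tr_seconds=cfg.tr_seconds,
        n_timepoints=cfg.n_timepoints,
        planted_models=models,
        domain_ranges=MOCA_DOMAINS,
        residual_sds=residual_sds,
        loading_mean=cfg.loading_mean,
    )

    bolds = [simulate_subject_bold(truth, i, seed=seed) for i in range(n)]
    if cfg.ar1_noise:
        # replace white noise with AR(1) noise of matched marginal sd
        phi = float(cfg.ar1_noise)
        for i, b in enumerate(bolds):
            r = np.random.default_rng(np.random.SeedSequence([int(seed), i, 7]))
            clean = truth.source_maps.T @ (
                (truth.subject_loadings[i] * truth.amplitudes)[:, None]
                * simulate_timecourses(truth.n_components, cfg.n_timepoints,
                                       cfg.tr_seconds, cfg.band_hz,
                                       np.random.default_rng(
                                           np.random.SeedSequence([int(seed), i])))
            )
            eps = r.normal(size=clean.shape)
            for t in range(1, eps.shape[1]):
                eps[:, t] = phi * eps[:, t - 1] + np.sqrt(1 - phi**2) * eps[:, t]
            b.data = clean + truth.noise_sd * eps

    metadata = _generate_metadata(cfg, truth, rng)
    paths = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"bold": [], "mask": out / "mask.nii",
                 "metadata": out / "participants.tsv", "config": out / "config.yaml"}
        save_map(mask[mask].astype(np.float32), truth.mask_index, truth.affine,
                 paths["mask"], grid_shape=truth.grid_shape)
        for i, b in enumerate(bolds):
            p = out / f"{metadata['id'].iloc[i]}_bold.nii"
            save_bold(b.data, b.mask_index, b.affine, b.tr_seconds, p,
                      grid_shape=truth.grid_shape)
            paths["bold"].append(p)
        write_subject_table(metadata, paths["metadata"])
        with open(paths["config"], "w") as fh:
            cfg_dict = asdict(cfg)
            cfg_dict["grid_shape"] = [int(g) for g in cfg.grid_shape]
            cfg_dict["band_hz"] = [float(x) for x in cfg.band_hz]
            cfg_dict["group_effect"] = (
                None if cfg.group_effect is None
                else {int(k): float(v) for k, v in cfg.group_effect.items()})
            cfg_dict["planted_models"] = {
                k: {"components": [int(c) for c in v.components],
                    "betas": [float(b) for b in v.betas],
                    "r2_target": None if v.r2_target is None else float(v.r2_target),
                    "residual_sd": (None if v.residual_sd is None
                                    else float(v.residual_sd))}
                for k, v in models.items()
            }
            cfg_dict["seed"] = int(seed)
            yaml.safe_dump(cfg_dict, fh)
    return CohortBundle(truth=truth, bolds=bolds, metadata=metadata, paths=paths)


def load_cohort_config(path) -> tuple[CohortConfig, int]:
    """Read a cohort config written by :func:`simulate_cohort` (or by hand)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seed = int(raw.pop("seed", 0))
    if raw.get("planted_models"):
        raw["planted_models"] = {
            k: PlantedModel(components=tuple(v["components"]), betas=tuple(v["betas"]),
                            r2_target=v.get("r2_target"),
                            residual_sd=v.get("residual_sd"))
            for k, v in raw["planted_models"].items()
        }
    for key in ("grid_shape", "band_hz"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if raw.get("group_effect"):
        raw["group_effect"] = {int(k): float(v) for k, v in raw["group_effect"].items()}
    return CohortConfig(**raw), seed


def match_components(estimated: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one matching of estimated to true maps by |correlation|.

    Returns ``(permutation, correlations)`` where ``permutation[j]`` is the
    estimated row matched to true row ``j`` and ``correlations[j]`` the
    achieved ``|corr|`` (Hungarian assignment).
    """
    from scipy.optimize import linear_sum_assignment

    est = estimated - estimated.mean(axis=1, keepdims=True)
    tru = truth - truth.mean(axis=1, keepdims=True)
    est /= np.linalg.norm(est, axis=1, keepdims=True)
    tru /= np.linalg.norm(tru, axis=1, keepdims=True)
    corr = np.abs(tru @ est.T)   # (n_true, n_est)
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(len(rows), dtype=int)
    cc = np.empty(len(rows))
    for r, c in zip(rows, cols):
        perm[r] = c
        cc[r] = corr[r, c]
    return perm, cc
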