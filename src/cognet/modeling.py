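"""Cognitive-domain models: stepwise regression, composites, hubs, group tests.

Each MoCA domain score (patients only) is regressed on the network expression
scores by bidirectional stepwise selection: the candidate with the smallest
partial-F p-value enters while that p-value is at most ``alpha_enter``
(default 0.05), and any included predictor whose p-value rises to
``alpha_remove`` (default 0.10) or above is removed, iterating to a fixed
point with a cycle guard.  A domain whose selection ends empty has no
generated network — the expected outcome when the score carries no network
signal.  The generated model's coefficients weight the group z-maps into a
voxelwise composite, the "domain-related network"; components selected by two
or more domains are reported as hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateError, ValidationError
from .metadata import MOCA_DOMAINS
from .scoring import NetworkScoreMatrix

__all__ = [
    "DomainModel", "CompositeMap", "stepwise_fit", "fit_all_domains",
    "compose_domain_network", "find_hubs", "compare_groups",
    "ttest_from_summary", "model_report",
]

COND_MAX = 1e8


@dataclass
class DomainModel:
    """A stepwise model for one cognitive domain."""

    domain: str
    ic_ids: list[str]                       # in order of entry
    table: pd.DataFrame                     # index ic_ids; columns B, ci_low, ci_high, p
    intercept: float
    r2: float
    model_p: float
    generated: bool
    n_obs: int = 0
    notes: list = field(default_factory=list)

    def coefficient(self, ic_id: str) -> float:
        return float(self.table.loc[ic_id, "B"])


@dataclass
class CompositeMap:
    """Voxelwise linear combination of group maps weighted by model coefficients."""

    domain: str
    values: np.ndarray
    ic_ids: list[str]


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_fit(scores: pd.DataFrame | NetworkScoreMatrix, y,
                 alpha_enter: float = 0.05, alpha_remove: float = 0.10,
                 domain: str = "") -> DomainModel:
    """Bidirectional stepwise OLS of a domain score on network scores.

    Entry is by smallest coefficient p-value among candidates (enter iff
    p <= ``alpha_enter``); removal drops the worst included predictor when its
    p-value reaches ``alpha_remove``.  Iterates to a fixed point, guarding
    against entry/removal cycles (at most ``2 * n_candidates`` sweeps; a
    revisited state terminates at the best-R² state seen).  Candidates whose
    entry would make the design ill-conditioned (condition number > 1e8) are
    refused with a note.  An empty final selection yields
    ``generated=False``.
    """
    X = scores.scores if isinstance(scores, NetworkScoreMatrix) else scores
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(X):
        raise ValidationError(f"{n} responses for {len(X)} subjects")
    if n <= 2:
        raise ValidationError("need more than 2 observations")
    if np.any(~np.isfinite(y)):
        raise ValidationError("missing values in the response")
    if not alpha_enter < alpha_remove:
        raise ValidationError("alpha_enter must be smaller than alpha_remove")

    notes: list[str] = []
    selected: list[str] = []
    visited: set[tuple[str, ...]] = set()
    best_state: tuple[float, tuple[str, ...]] = (-np.inf, ())
    max_sweeps = max(2 * X.shape[1], 4)
    cycled = False

    for _ in range(max_sweeps):
        changed = False
        # forward step
        candidates = [c for c in X.columns if c not in selected]
        best_p, best_c = np.inf, None
        for c in candidates:
            trial = X[selected + [c]]
            design = sm.add_constant(trial, has_constant="add").to_numpy()
            if np.linalg.cond(design) > COND_MAX:
                notes.append(f"refused {c}: ill-conditioned with {selected}")
                continue
            fit = _ols(y, trial)
            p = fit.pvalues.get(c, np.inf)
            if p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p <= alpha_enter:
            selected.append(best_c)
            changed = True
        # backward step(s)
        while len(selected) > 0:
            fit = _ols(y, X[selected])
            pvals = fit.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals[worst] >= alpha_remove:
                selected.remove(worst)
                changed = True
            else:
                break
        if selected:
            r2 = _ols(y, X[selected]).rsquared
            if r2 > best_state[0]:
                best_state = (r2, tuple(selected))
        state = tuple(sorted(selected))
        if state in visited and changed:
            cycled = True
            notes.append("selection cycle detected; stopping at best-R² state")
            selected = list(best_state[1])
            break
        visited.add(state)
        if not changed:
            break

    if not selected:
        empty = pd.DataFrame(columns=["B", "ci_low", "ci_high", "p"])
        return DomainModel(domain=domain, ic_ids=[], table=empty, intercept=np.nan,
                           r2=0.0, model_p=np.nan, generated=False, n_obs=n,
                           notes=notes)

    fit = _ols(y, X[selected])
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame({
        "B": fit.params.drop("const"),
        "ci_low": ci[0].drop("const"),
        "ci_high": ci[1].drop("const"),
        "p": fit.pvalues.drop("const"),
    }).loc[selected]
    if cycled:
        notes.append("terminated by cycle guard")
    return DomainModel(domain=domain, ic_ids=list(selected), table=table,
                       intercept=float(fit.params["const"]), r2=float(fit.rsquared),
                       model_p=float(fit.f_pvalue), generated=True, n_obs=n,
                       notes=notes)


def fit_all_domains(scores: NetworkScoreMatrix, metadata: pd.DataFrame,
                    domains: Iterable[str] | None = None,
                    alpha_enter: float = 0.05, alpha_remove: float = 0.10,
                    group: str = "PD") -> dict[str, DomainModel]:
    """Stepwise-fit every MoCA domain on the patient group's scores."""
    domains = list(domains) if domains is not None else list(MOCA_DOMAINS)
    meta = metadata.set_index("id") if "id" in metadata.columns else metadata
    mask = scores.groups.to_numpy() == group
    X = scores.scores.loc[mask]
    models = {}
    for d in domains:
        col = f"moca_{d}" if f"moca_{d}" in meta.columns else d
        if col not in meta.columns:
            raise ValidationError(f"no score column for domain {d!r}")
        y = pd.to_numeric(meta.loc[X.index, col], errors="coerce")
        if y.isna().any():
            raise ValidationError(f"missing {d} scores for some {group} subjects")
        models[d] = stepwise_fit(X, y.to_numpy(), alpha_enter=alpha_enter,
                                 alpha_remove=alpha_remove, domain=d)
    return models


def compose_domain_network(model: DomainModel, group_maps,
                           component_ids: Sequence[str] | None = None) -> CompositeMap:
    """Weighted sum of group z-maps with the model coefficients as weights.

    ``group_maps`` is either a mapping ``ic_id -> map`` or a (K, V) array with
    ``component_ids`` giving row names.  Negative coefficients contribute
    negatively — the composite keeps the sign of each association.
    """
    if not model.generated:
        raise ValidationError(f"no generated model for domain {model.domain!r}")
    if isinstance(group_maps, dict):
        lookup = group_maps
    else:
        arr = np.asarray(group_maps, dtype=float)
        ids = list(component_ids) if component_ids is not None else [
            f"IC{i + 1}" for i in range(arr.shape[0])]
        lookup = dict(zip(ids, arr))
    missing = [ic for ic in model.ic_ids if ic not in lookup]
    if missing:
        raise ValidationError(f"missing component maps: {missing}")
    values = sum(model.coefficient(ic) * np.asarray(lookup[ic], dtype=float)
                 for ic in model.ic_ids)
    return CompositeMap(domain=model.domain, values=values, ic_ids=list(model.ic_ids))


def _ic_sort_key(ic_id: str):
    digits = "".join(ch for ch in ic_id if ch.isdigit())
    return (int(digits) if digits else np.inf, ic_id)


def find_hubs(models: Iterable[DomainModel],
              min_membership: int = 2) -> list[tuple[str, list[str]]]:
    """Components selected in at least ``min_membership`` generated models.

    Returns ``(ic_id, [domains])`` pairs sorted by descending membership
    count, ties broken by component number.
    """
    generated = [m for m in models if m.generated]
    if len(generated) < 2:
        raise ValidationError("need at least 2 generated models to find hubs")
    membership: dict[str, list[str]] = {}
    for m in generated:
        for ic in m.ic_ids:
            membership.setdefault(ic, []).append(m.domain)
    hubs = [(ic, doms) for ic, doms in membership.items() if len(doms) >= min_membership]
    hubs.sort(key=lambda item: (-len(item[1]), _ic_sort_key(item[0])))
    return hubs


def compare_groups(scores: NetworkScoreMatrix | pd.DataFrame, groups=None,
                   alpha: float = 0.05, variant: str = "student") -> pd.DataFrame:
    """Per-component two-tailed t-test of expression scores between groups.

    ``variant='student'`` is the pooled-variance test; ``'welch'`` drops the
    equal-variance assumption.  No multiplicity correction is applied.
    Returns a frame with ``t``, ``df``, ``p`` and ``significant`` per
    component.
    """
    if isinstance(scores, NetworkScoreMatrix):
        X, g = scores.scores, scores.groups.to_numpy()
    else:
        if groups is None:
            raise ValidationError("groups required with a raw score frame")
        X, g = pd.DataFrame(scores), np.asarray(groups)
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {list(labels)}")
    a = X.loc[g == labels[0]].to_numpy(dtype=float)
    b = X.loc[g == labels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need at least 2 subjects")
    rows = []
    for j, comp in enumerate(X.columns):
        if a[:, j].var(ddof=1) == 0 and b[:, j].var(ddof=1) == 0:
            raise DegenerateError(f"zero pooled variance for {comp}")
        res = stats.ttest_ind(a[:, j], b[:, j], equal_var=(variant == "student"))
        rows.append({"component": comp, "t": float(res.statistic),
                     "df": float(res.df), "p": float(res.pvalue),
                     "significant": bool(res.pvalue < alpha)})
    return pd.DataFrame(rows).set_index("component")


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int,
                       variant: str = "student") -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; returns ``(t, df, p)``."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=(variant == "student"))
    if variant == "student":
        df = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def model_report(models: dict[str, DomainModel]) -> pd.DataFrame:
    """Structured report of all domain models (one row per predictor).

    Domains without a generated model appear once with NA entries; the number
    of generated domain networks is ``report['generated'].sum()`` over the
    deduplicated domain column.
    """
    rows = []
    for d, m in models.items():
        if not m.generated:
            rows.append({"domain": d, "r2": np.nan, "ic_id": "NA", "B": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "generated": False})
            continue
        for ic in m.ic_ids:
            row = m.table.loc[ic]
            rows.append({"domain": d, "r2": m.r2, "ic_id": ic, "B": row["B"],
                         "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                         "p": row["p"], "generated": True})
    return pd.DataFrame(rows)


def count_generated(models: dict[str, DomainModel]) -> int:
    return sum(1 for m in models.values() if m.generated)
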