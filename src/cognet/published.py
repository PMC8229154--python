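"""Reference results of the source study, encoded as data.

The study this pipeline operationalises reported a stepwise model per MoCA
domain (Parkinson cohort, 72-component group ICA): per selected component the
regression weight B with its 95% CI and p-value, plus the model R².  The
delayed-recall domain produced no model.  These tables are inputs for
structural computations — counting generated domain networks and identifying
hub components shared between domains — and for regression tests of the
report logic; they are not produced by this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .modeling import DomainModel

__all__ = ["PUBLISHED_DOMAIN_MODELS", "published_domain_models"]

#: domain -> (R^2, [(ic_id, B, ci_low, ci_high, p), ...]); None -> no model
PUBLISHED_DOMAIN_MODELS = {
    "visuospatial_executive": (0.54, [
        ("IC31", 0.063, 0.024, 0.101, 0.002),
        ("IC49", -0.060, -0.112, -0.009, 0.024),
        ("IC54", 0.050, 0.019, 0.082, 0.003),
        ("IC47", 0.070, 0.009, 0.132, 0.026),
        ("IC56", -0.058, -0.112, -0.005, 0.034),
    ]),
    "naming": (0.39, [
        ("IC25", -0.026, -0.043, -0.010, 0.003),
        ("IC48", 0.030, 0.008, 0.052, 0.008),
        ("IC14", -0.012, -0.023, -0.002, 0.019),
    ]),
    "attention": (0.86, [
        ("IC49", -0.059, -0.078, -0.039, 0.001),
        ("IC71", 0.056, 0.036, 0.075, 0.001),
        ("IC66", 0.043, 0.026, 0.059, 0.001),
        ("IC36", -0.027, -0.043, -0.011, 0.002),
        ("IC42", 0.028, 0.016, 0.040, 0.001),
        ("IC15", -0.031, -0.042, -0.020, 0.005),
        ("IC1", 0.012, 0.004, 0.020, 0.005),
        ("IC54", 0.020, 0.008, 0.032, 0.002),
        ("IC7", -0.025, -0.042, -0.008, 0.005),
        ("IC22", -0.017, -0.032, -0.002, 0.029),
    ]),
    "language": (0.64, [
        ("IC24", -0.119, -0.159, -0.079, 0.001),
        ("IC3", 0.035, 0.017, 0.054, 0.001),
        ("IC17", -0.046, -0.067, -0.024, 0.001),
        ("IC23", -0.036, -0.057, -0.015, 0.001),
        ("IC62", 0.054, 0.009, 0.098, 0.020),
        ("IC35", 0.023, 0.002, 0.044, 0.034),
        ("IC48", 0.033, 0.001, 0.065, 0.043),
    ]),
    "abstraction": (0.10, [
        ("IC61", -0.025, -0.049, 0.000, 0.047),
    ]),
    "delayed_recall": None,
    "orientation": (0.64, [
        ("IC49", -0.050, -0.068, -0.031, 0.001),
        ("IC4", -0.010, -0.016, -0.004, 0.001),
        ("IC50", 0.034, 0.016, 0.052, 0.001),
        ("IC14", 0.011, 0.002, 0.021, 0.024),
        ("IC40", -0.044, -0.083, -0.005, 0.027),
    ]),
}


def published_domain_models() -> dict[str, DomainModel]:
    """The reference tables as :class:`DomainModel` objects."""
    models = {}
    for domain, entry in PUBLISHED_DOMAIN_MODELS.items():
        if entry is None:
            models[domain] = DomainModel(
                domain=domain, ic_ids=[], table=pd.DataFrame(), intercept=np.nan,
                r2=0.0, model_p=np.nan, generated=False)
            continue
        r2, rows = entry
        table = pd.DataFrame(
            [{"B": b, "ci_low": lo, "ci_high": hi, "p": p}
             for _, b, lo, hi, p in rows],
            index=[ic for ic, *_ in rows])
        models[domain] = DomainModel(
            domain=domain, ic_ids=list(table.index), table=table,
            intercept=np.nan, r2=r2, model_p=np.nan, generated=True)
    return models
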