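"""Worked-example coefficient tables.

Standardized regression coefficients from a published serial mediation
analysis of gratitude and sleep disturbance in German primary-care
patients (N = 869): three model topologies with health self-efficacy
(``hse``) and/or health behaviors (``hb``) as first-order mediators and
stress, anxiety and depression as second-order parallel mediators, ending
in a partial proportional-odds cumulative logit for a 4-level sleep item.
These tables exercise the path-arithmetic routines (enumeration, products,
decomposition, odds-ratio conversion) without the original respondent
data, which are not public.

Each model is a dict of per-equation coefficient maps keyed by equation
target; the outcome equation maps predictor -> slope (a 3-tuple of per-cut
slopes for the non-parallel predictor). Only the focal coefficients enter
mediation products; covariate rows are omitted here.
"""

from __future__ import annotations

import numpy as np

from .mediation import MediationSpec

__all__ = ["MODEL1", "MODEL2", "MODEL3", "worked_example",
           "OUTCOME_CATEGORY_COUNTS", "OUTCOME_MOMENTS"]

# observed frequency of the 4 outcome categories in the source sample
OUTCOME_CATEGORY_COUNTS = (212, 396, 131, 123)

# sample skewness / excess kurtosis of the outcome item (n = 862)
OUTCOME_MOMENTS = {"n": 862, "skewness": 0.56, "kurtosis": -0.60}

MODEL1 = {
    "spec": dict(exposure="gratitude", first_order=("hse",),
                 second_order=("stress", "anxiety", "depression"),
                 outcome="sleep", model_label="model1"),
    "nonparallel": ("hse",),
    "equations": {
        "hse": {"gratitude": 0.273},
        "stress": {"hse": -0.320, "gratitude": -0.154},
        "anxiety": {"hse": -0.218, "gratitude": -0.068},
        "depression": {"hse": -0.255, "gratitude": -0.122},
        "sleep": {"hse": np.array([-0.100, -0.365, -0.206]),
                  "stress": 0.217, "anxiety": 0.440, "depression": 0.291,
                  "gratitude": 0.086},
    },
    # outcome-equation Wald CIs used by the odds-ratio conversion example
    "outcome_ci": {"stress": (0.087, 0.346)},
}

MODEL2 = {
    "spec": dict(exposure="gratitude", first_order=("hb",),
                 second_order=("stress", "anxiety", "depression"),
                 outcome="sleep", model_label="model2"),
    "nonparallel": ("hb",),
    "equations": {
        "hb": {"gratitude": 0.173},
        "stress": {"hb": -0.209, "gratitude": -0.221},
        "anxiety": {"hb": -0.113, "gratitude": -0.114},
        "depression": {"hb": -0.143, "gratitude": -0.175},
        "sleep": {"hb": np.array([-0.390, -0.654, -0.536]),
                  "stress": 0.156, "anxiety": 0.471, "depression": 0.295,
                  "gratitude": 0.062},
    },
    "outcome_ci": {"anxiety": (0.332, 0.610)},
}

MODEL3 = {
    "spec": dict(exposure="gratitude", first_order=("hse", "hb"),
                 second_order=("stress", "anxiety", "depression"),
                 outcome="sleep", model_label="model3"),
    "nonparallel": ("hse",),
    "equations": {
        "hse": {"gratitude": 0.273},
        "hb": {"gratitude": 0.173},
        "stress": {"hse": -0.276, "hb": -0.107, "gratitude": -0.156},
        "anxiety": {"hse": -0.202, "hb": -0.056, "gratitude": -0.062},
        "depression": {"hse": -0.230, "hb": -0.060, "gratitude": -0.121},
        "sleep": {"hse": np.array([0.074, -0.183, -0.017]),
                  "hb": -0.496, "stress": 0.155, "anxiety": 0.471,
                  "depression": 0.295, "gratitude": 0.076},
    },
    "outcome_ci": {},
}

_MODELS = {1: MODEL1, 2: MODEL2, 3: MODEL3}


def worked_example(model: int = 1):
    """Return ``(spec, nonparallel, fits)`` for one worked-example model.

    ``fits`` maps each equation target to its plain coefficient dict, the
    form :func:`~ordmediate.mediation.product_of_coefficients` accepts, so

    >>> spec, nonpar, fits = worked_example(1)
    >>> paths = enumerate_paths(spec, nonparallel=nonpar)
    >>> product_of_coefficients(paths[0], fits)    # doctest: +SKIP

    reproduces the published pathway effects from the published
    coefficient tables.
    """
    m = _MODELS[model]
    spec = MediationSpec(**m["spec"])
    return spec, tuple(m["nonparallel"]), dict(m["equations"])
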