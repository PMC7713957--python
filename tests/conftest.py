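"""Shared fixtures: noise-free preset datasets and their (expensive) fits.

The full-pipeline fits are session-scoped so closure/recovery properties and
acceptance checks share one optimizer run per preset.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvfit import PRESETS, fit_lv, generate, preset

#: preset name -> treatment to fit (None = single-treatment table)
FIT_TREATMENT = {name: ("mixture" if name == "paramecium_competition" else None)
                 for name in PRESETS}


def free_parameter_vectors(truth, result):
    """Ground-truth vs fitted values of every optimized parameter."""
    mask = result.mask
    true_v = np.concatenate([truth.r[mask.r_free], truth.A[mask.A_free],
                             truth.N0])
    fit_v = np.concatenate([result.params.r[mask.r_free],
                            result.params.A[mask.A_free], result.params.N0])
    return true_v, fit_v


@pytest.fixture(scope="session", params=sorted(PRESETS))
def preset_closure(request):
    """(name, truth, observations, fit) for a noise-free preset."""
    name = request.param
    spec = preset(name, noise_sd=0.0)
    table, truth = generate(spec)
    result = fit_lv(table, user_mask=spec.mask,
                    treatment=FIT_TREATMENT[name], compute_se=False)
    return name, truth, table, result


@pytest.fixture(scope="session")
def logistic_closure():
    spec = preset("logistic_monoculture", noise_sd=0.0)
    table, truth = generate(spec)
    return truth, table, fit_lv(table)


@pytest.fixture(scope="session")
def competition_closure():
    spec = preset("paramecium_competition", noise_sd=0.0)
    table, truth = generate(spec)
    result = fit_lv(table, treatment="mixture", compute_se=False)
    return truth, table, result
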