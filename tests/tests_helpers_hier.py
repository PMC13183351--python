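"""Shared helper: an analytic PosteriorDraws with hand-set coefficients."""

import numpy as np
import pandas as pd

from roleprobe.hier import (HierModelSpec, PosteriorDraws, _Posterior,
                            build_model_data, simulate_records)


def manual_fixed_logit_fit(intercept: float = 0.0, register: float = 0.0,
                           n_sentences: int = 40) -> PosteriorDraws:
    """A PosteriorDraws whose every draw has the given fixed effects and
    negligible random-effect scales — the analytic oracle for DeltaP."""
    records = simulate_records(n_sentences=n_sentences, per_cell=1, seed=0)
    spec = HierModelSpec()
    data = build_model_data(records, spec)
    post = _Posterior(data, spec)
    theta = np.zeros((2, 10, post.dim))
    theta[:, :, data.coef_names.index("intercept")] = intercept
    theta[:, :, data.coef_names.index("register")] = register
    theta[:, :, post.k: post.k + post.n_scales] = -30.0
    diag = pd.DataFrame({"parameter": data.coef_names, "rhat": 1.0,
                         "ess": 20.0})
    return PosteriorDraws(theta=theta, posterior_=post, data=data,
                          spec=spec, diagnostics=diag)
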