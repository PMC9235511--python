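"""Calibration diagnostics for the region deviance test.

The empirical type-I error of the region test must be estimated over
*independent* replicates: with a single severity draw shared by thousands
of regions, the rejection fraction converges to the type-I error
conditional on that draw's realized dispersion (which fluctuates with
standard deviation about sqrt(2/n)), not to the marginal level.  The
routine here therefore redraws the Poisson severity score for every
simulated null region, keeping the cohort covariates and confounder design
fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .region_ewas import fit_poisson_glm, region_deviance_test
from .simulate import GroundTruth, SimConfig, simulate_severity

__all__ = ["region_null_calibration"]


def region_null_calibration(
    samples: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    confounders: pd.DataFrame,
    mvalues: pd.DataFrame,
    n_replicates: int = 2000,
    sites_per_region: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Null p-values over independent (severity, region) replicates.

    Each replicate draws a fresh severity score from the generator's null
    model (given the fixed cohort covariates), takes the next block of
    ``sites_per_region`` methylation profiles as the candidate region, and
    runs the two-step deviance test against the fixed confounder design.
    Returns the vector of p-values.
    """
    C = confounders.loc[samples.index].to_numpy(float)
    values = mvalues.loc[:, samples.index].to_numpy()
    n_sites = values.shape[0]
    if n_replicates * sites_per_region > n_sites:
        raise ValueError(
            f"need {n_replicates * sites_per_region} site profiles, "
            f"have {n_sites}"
        )
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg_r = config.replace(seed=int(seed + 1_000_003 * (r + 1)) % (2**31))
        y = simulate_severity(samples, truth, cfg_r).to_numpy(float)
        block = values[
            r * sites_per_region: (r + 1) * sites_per_region, :
        ].T
        step1 = fit_poisson_glm(y, C)
        res = region_deviance_test(y, C, block, step1=step1)
        ps[r] = res["p"]
    return ps
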