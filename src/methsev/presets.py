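"""Canonical simulation configurations for calibration and power studies.

Two study conditions are used throughout the test suite and the
reproduction script:

* the *global null* — no causal sites and no methylation-severity liability
  coupling, so severity is (conditionally) Poisson given the modelled
  covariates and every association test should be calibrated;
* the *planted-signal* condition — the generator defaults (1% causal sites
  at 0.05 M-units per severity point, about half of them grouped into whole
  causal islands), the synthetic analogue of a cohort with real effects.

The cohort size matches the clinical study the pipeline is designed for
(n = 232, discovery/validation halves of 116).
"""

from __future__ import annotations

from .simulate import SimConfig

__all__ = ["null_config", "planted_config"]


def null_config(seed: int, n_sites: int = 20_000, n_samples: int = 232) -> SimConfig:
    """Global-null cohort: calibrated tests should see uniform p-values."""
    return SimConfig(
        n_samples=n_samples,
        n_sites=n_sites,
        n_islands=max(n_sites // 13, 1),
        n_genes=max(n_sites // 3, 10),
        frac_causal_sites=0.0,
        liability_weight=0.0,
        seed=seed,
    )


def planted_config(seed: int, n_sites: int = 4_000, n_samples: int = 232) -> SimConfig:
    """Planted-signal cohort at the generator's default effect sizes."""
    return SimConfig(
        n_samples=n_samples,
        n_sites=n_sites,
        n_islands=max(n_sites // 13, 1),
        n_genes=max(n_sites // 3, 10),
        seed=seed,
    )
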