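"""Synthetic 450K-style cohorts with known ground truth.

Generates everything the downstream stages consume — a probe manifest with
island/promoter/gene-body structure, a sample table with confounders and
blood cell-type mixtures, an M-value matrix with island-correlated noise and
planted severity effects, an integer severity score, and clinical features
that reconstruct that score — so the whole pipeline can be exercised and
calibrated without access to patient data.

The generative model is additive on the M-value scale.  A standard-normal
per-sample liability drives the Poisson log-rate of the severity score;
causal CpG sites are shifted by ``causal_effect_size`` M-units per point of
the *observed* severity score, so the planted effect is exactly the estimand
of the site-level regression, while the shared liability guarantees that the
reversed (severity-on-methylation) region model also sees the signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "HOUSEMAN_CELL_TYPES",
    "simulate_manifest",
    "simulate_cohort",
    "simulate_methylation",
    "simulate_intensities",
    "simulate_severity",
    "simulate_clinical_features",
    "simulate_dataset",
]

#: The eight blood cell types of the reference-based deconvolution panel.
HOUSEMAN_CELL_TYPES = (
    "CD14_Mono",
    "CD19_B",
    "CD4_T",
    "CD56_NK",
    "CD8_T",
    "Eos",
    "Gran",
    "Neu",
)

# Dirichlet concentration: whole-blood realism, neutrophil-dominated.
_CELL_ALPHA = np.array([4.8, 2.4, 9.0, 3.0, 4.8, 1.8, 3.0, 31.2])

# Fixed per-operation stream codes: adding an operation never perturbs the
# draws of an existing one.
_STREAMS = {
    "manifest": 11,
    "cohort": 23,
    "severity": 37,
    "methylation": 41,
    "causal": 43,
    "clinical": 53,
}


def _rng(config: "SimConfig", op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STREAMS[op])))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator.

    Effect sizes are simulator parameters (free choices, documented in the
    methods note), not estimates from any cohort.

    Parameters
    ----------
    n_samples, n_sites, n_islands, n_genes
        Cohort and array dimensions.
    sites_per_island
        Inclusive (min, max) of island sizes.
    frac_causal_sites
        Fraction of sites carrying a severity effect; about half of them are
        planted as whole causal islands (>=4 sites) so region-level power is
        testable, the rest are scattered non-island sites.
    causal_effect_size
        M-value shift per point of observed severity at causal sites.
    island_correlation
        Within-island correlation of the residual noise, in [0, 1).
    confounder_effects
        Map covariate group -> SD of per-site coefficients (M-value units per
        SD of the covariate).  Recognised groups: age, sex, batch, cell,
        latent.
    severity_mean
        Expected severity score (Poisson rate scale) before the floor at 2.
    severity_covariate_effects
        Log-rate shift per SD of covariate for the severity score.
    liability_weight
        Coefficient of the shared standard-normal liability in the Poisson
        log-rate.
    noise_sd
        Residual M-value standard deviation.
    n_latent
        Number of unmeasured latent factors (batch-like structure that only
        surrogate-variable estimation can recover).
    """

    n_samples: int = 232
    n_sites: int = 20_000
    n_islands: int = 1_500
    sites_per_island: tuple[int, int] = (3, 12)
    n_genes: int = 6_000
    frac_causal_sites: float = 0.01
    causal_effect_size: float = 0.05
    island_correlation: float = 0.6
    confounder_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "age": 0.10,
            "sex": 0.10,
            "batch": 0.15,
            "cell": 0.20,
            "latent": 0.30,
        }
    )
    severity_mean: float = 6.6
    severity_covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.03, "sex": 0.05}
    )
    liability_weight: float = 0.25
    noise_sd: float = 0.25
    n_latent: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_sites", "n_islands", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        lo, hi = self.sites_per_island
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid sites_per_island range {self.sites_per_island}")
        if not 0.0 <= self.frac_causal_sites <= 1.0:
            raise ValueError("frac_causal_sites must be in [0, 1]")
        if not 0.0 <= self.island_correlation < 1.0:
            raise ValueError("island_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.severity_mean <= 0:
            raise ValueError("severity_mean must be > 0")
        if self.n_latent < 0:
            raise ValueError("n_latent must be >= 0")
        if self.n_islands * lo > self.n_sites:
            raise ValueError(
                f"sites_per_island={self.sites_per_island} needs at least "
                f"{self.n_islands * lo} sites for {self.n_islands} islands, "
                f"but n_sites={self.n_sites}"
            )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery and calibration testing."""

    causal_site_ids: list[str] = field(default_factory=list)
    causal_region_ids: list[str] = field(default_factory=list)
    true_effects: dict[str, float] = field(default_factory=dict)
    true_cell_props: pd.DataFrame | None = None
    true_latent: pd.DataFrame | None = None
    liability: pd.Series | None = None

    def to_json(self, path) -> None:
        payload = {
            "causal_site_ids": self.causal_site_ids,
            "causal_region_ids": self.causal_region_ids,
            "true_effects": self.true_effects,
            "true_cell_props": None
            if self.true_cell_props is None
            else self.true_cell_props.to_dict(orient="index"),
            "true_latent": None
            if self.true_latent is None
            else self.true_latent.to_dict(orient="index"),
            "liability": None if self.liability is None else self.liability.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# manifest


def simulate_manifest(config: SimConfig) -> pd.DataFrame:
    """Generate a 450K-style manifest.

    Returns a DataFrame with columns ``probe_id, chr, pos, island_id, gene,
    location_class``; chromosomes 1-22, 1-based strictly increasing positions
    per chromosome.  Every site carries exactly one region assignment: an
    island id, or (non-island) a TSS-mapped promoter site, or an intragenic
    gene-body site.  Gene labels are unique per locus so each site maps to at
    most one gene.
    """
    rng = _rng(config, "manifest")
    lo, hi = config.sites_per_island

    island_sizes = rng.integers(lo, hi + 1, size=config.n_islands)
    overshoot = int(island_sizes.sum()) - config.n_sites
    if overshoot > 0:
        # Trim islands back toward the minimum size until the budget fits.
        for i in np.argsort(-island_sizes):
            take = min(overshoot, int(island_sizes[i]) - lo)
            island_sizes[i] -= take
            overshoot -= take
            if overshoot == 0:
                break
        if overshoot > 0:  # pragma: no cover - guarded by __post_init__
            raise ValueError("island sizes inconsistent with n_sites")

    gene_pool = iter(f"GENE{i:05d}" for i in range(config.n_genes))

    def next_gene() -> str:
        return next(gene_pool, "")

    # A unit is a contiguous block of sites: an island, or a gene locus with
    # promoter and/or body sites.
    units: list[list[tuple[str, str, str]]] = []  # (island_id, gene, class)
    for k, size in enumerate(island_sizes):
        island_id = f"isl_{k:05d}"
        gene = next_gene() if rng.random() < 0.7 else ""
        units.append([(island_id, gene, "Island")] * int(size))

    remaining = config.n_sites - int(island_sizes.sum())
    while remaining > 0:
        gene = next_gene()
        unit: list[tuple[str, str, str]] = []
        if rng.random() < 0.5:  # promoter cluster
            for _ in range(min(remaining, int(rng.integers(1, 5)))):
                cls = "TSS200" if rng.random() < 0.5 else "TSS1500"
                unit.append(("", gene, cls))
        else:  # gene-body cluster
            for _ in range(min(remaining, int(rng.integers(1, 7)))):
                cls = str(rng.choice(["Body", "Body", "Body", "5'UTR", "3'UTR"]))
                unit.append(("", gene, cls))
        units.append(unit)
        remaining -= len(unit)

    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # Spread units over chromosomes 1..22 in contiguous chunks.
    n_units = len(units)
    bounds = np.linspace(0, n_units, 23).astype(int)
    rows: list[tuple[str, str, int, str, str, str]] = []
    probe_codes = rng.permutation(max(5 * config.n_sites, 1000))[: config.n_sites]
    idx = 0
    for c in range(22):
        pos = int(rng.integers(100_000, 1_000_000))
        for unit in units[bounds[c] : bounds[c + 1]]:
            for island_id, gene, cls in unit:
                rows.append(
                    (f"cg{probe_codes[idx]:08d}", str(c + 1), pos, island_id, gene, cls)
                )
                idx += 1
                pos += int(rng.integers(20, 800))
            pos += int(rng.integers(5_000, 200_000))

    manifest = pd.DataFrame(
        rows, columns=["probe_id", "chr", "pos", "island_id", "gene", "location_class"]
    )
    return manifest


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-sample covariates plus the unmeasured structure, recorded as truth.

    The sample table carries age (truncated normal, 50-95 y), sex (0/1),
    three categorical batch labels (array, bisulfite conversion, scan) and
    the eight blood cell-type proportions; the latent factors and the
    severity liability live only in :class:`GroundTruth`.
    """
    if config.n_samples < 4:
        raise ValueError("n_samples must be >= 4 (downstream models unfittable)")
    rng = _rng(config, "cohort")
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    age = np.clip(rng.normal(72.0, 8.0, size=n), 50.0, 95.0).round(1)
    sex = rng.binomial(1, 124 / 232, size=n)  # 1 = male
    batch_array = rng.choice([f"A{i}" for i in range(1, 5)], size=n)
    batch_bisulfite = rng.choice(["B1", "B2"], size=n)
    batch_scan = rng.choice(["C1", "C2", "C3"], size=n)
    cells = rng.dirichlet(_CELL_ALPHA, size=n)
    latent = rng.standard_normal((n, config.n_latent))
    liability = rng.standard_normal(n)

    samples = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "batch_array": batch_array,
            "batch_bisulfite": batch_bisulfite,
            "batch_scan": batch_scan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for j, ct in enumerate(HOUSEMAN_CELL_TYPES):
        samples[f"cell_{ct}"] = cells[:, j]

    truth = GroundTruth(
        true_cell_props=pd.DataFrame(
            cells, index=samples.index, columns=list(HOUSEMAN_CELL_TYPES)
        ),
        true_latent=pd.DataFrame(
            latent,
            index=samples.index,
            columns=[f"latent_{i + 1}" for i in range(config.n_latent)],
        ),
        liability=pd.Series(liability, index=samples.index, name="liability"),
    )
    return samples, truth


# ---------------------------------------------------------------------------
# severity


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def simulate_severity(
    samples: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    floor: int | None = 2,
    ceiling: int | None = 18,
) -> pd.Series:
    """Integer severity scores, Poisson with a log-link liability model.

    ``log lam_i = log(severity_mean) - v/2 + sum_c beta_c z_ic + w * L_i``
    where z are standardized covariates, L is the shared liability, and v is
    the total coefficient variance so that ``E[lam] = severity_mean``.
    Scores are floored at 2, mirroring the observed clinical minimum, and
    capped at the composite rubric's attainable ceiling of 18; pass
    ``floor=None``/``ceiling=None`` for the raw Poisson draw.
    """
    if config.severity_mean <= 0:
        raise ValueError("severity_mean must be > 0")
    rng = _rng(config, "severity")
    n = len(samples)
    eta = np.zeros(n)
    total_var = 0.0
    for cov, beta in config.severity_covariate_effects.items():
        if beta == 0:
            continue
        if cov not in samples.columns:
            raise KeyError(f"severity covariate {cov!r} not in sample table")
        eta += beta * _standardize(samples[cov].to_numpy(dtype=float))
        total_var += beta**2
    w = config.liability_weight
    if w != 0:
        eta += w * truth.liability.loc[samples.index].to_numpy()
        total_var += w**2
    lam = config.severity_mean * np.exp(eta - total_var / 2.0)
    y = rng.poisson(lam)
    if floor is not None:
        y = np.maximum(y, floor)
    if ceiling is not None:
        y = np.minimum(y, ceiling)
    return pd.Series(y, index=samples.index, name="severity")


# ---------------------------------------------------------------------------
# methylation


def _assign_causal(
    manifest: pd.DataFrame, config: SimConfig
) -> tuple[pd.Index, list[str], pd.Series]:
    """Pick causal sites: ~half as whole islands (>=4 sites), half scattered."""
    rng = _rng(config, "causal")
    n_causal = int(round(config.frac_causal_sites * config.n_sites))
    if n_causal == 0:
        return pd.Index([]), [], pd.Series(dtype=float)

    island_sizes = (
        manifest.loc[manifest["island_id"] != "", "island_id"].value_counts()
    )
    big_islands = island_sizes[island_sizes >= 4].index.to_numpy()
    rng.shuffle(big_islands)

    causal_regions: list[str] = []
    causal_sites: list[str] = []
    budget = n_causal // 2
    for isl in big_islands:
        if budget <= 0:
            break
        members = manifest.loc[manifest["island_id"] == isl, "probe_id"].tolist()
        causal_regions.append(str(isl))
        causal_sites.extend(members)
        budget -= len(members)

    scattered_pool = manifest.loc[manifest["island_id"] == "", "probe_id"].to_numpy()
    n_scatter = max(n_causal - len(causal_sites), 0)
    n_scatter = min(n_scatter, len(scattered_pool))
    if n_scatter:
        causal_sites.extend(rng.choice(scattered_pool, size=n_scatter, replace=False))

    signs = rng.choice([-1.0, 1.0], size=len(causal_sites))
    effects = pd.Series(
        signs * config.causal_effect_size, index=pd.Index(causal_sites), dtype=float
    )
    return pd.Index(causal_sites), causal_regions, effects


def simulate_methylation(
    manifest: pd.DataFrame,
    samples: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
) -> pd.DataFrame:
    """M-value matrix (sites x samples) with planted structure.

    value = site baseline + confounder effects + island-shared noise
    component (within-island correlation = ``island_correlation``) + causal
    severity term + independent noise.  The causal term for a causal site is
    ``effect * (severity_i - mean(severity))`` so the planted effect equals
    the site-model regression coefficient.  Updates ``truth`` in place with
    the causal assignment.
    """
    if len(samples) != config.n_samples or len(manifest) != config.n_sites:
        raise ValueError("manifest/sample dimensions inconsistent with config")
    if "severity" not in samples.columns and config.frac_causal_sites > 0:
        raise ValueError("samples must contain 'severity' before methylation "
                         "when causal sites are requested")
    rng = _rng(config, "methylation")
    n_sites, n = config.n_sites, config.n_samples
    site_ids = manifest["probe_id"].to_numpy()
    is_island = (manifest["island_id"] != "").to_numpy()

    # Baselines: islands hypomethylated, the rest bimodal.
    baseline = np.where(
        is_island,
        rng.normal(-2.5, 0.8, size=n_sites),
        np.where(
            rng.random(n_sites) < 0.5,
            rng.normal(2.5, 1.0, size=n_sites),
            rng.normal(-1.0, 1.2, size=n_sites),
        ),
    )
    M = np.tile(baseline[:, None], (1, n))

    # Confounder effects: per-site coefficients on standardized covariates.
    groups: dict[str, np.ndarray] = {}
    groups["age"] = _standardize(samples["age"].to_numpy(float))[:, None]
    groups["sex"] = _standardize(samples["sex"].to_numpy(float))[:, None]
    batch_cols = []
    for col in ("batch_array", "batch_bisulfite", "batch_scan"):
        d = pd.get_dummies(samples[col], drop_first=True).to_numpy(float)
        batch_cols.append(d)
    groups["batch"] = np.apply_along_axis(
        _standardize, 0, np.hstack(batch_cols)
    )
    cell = truth.true_cell_props.to_numpy()[:, :-1]  # drop one: sum-to-one
    groups["cell"] = np.apply_along_axis(_standardize, 0, cell)
    if config.n_latent:
        groups["latent"] = truth.true_latent.to_numpy()

    # Sites within an island respond coherently: per-site coefficients are a
    # sqrt(rho)/sqrt(1-rho) mixture of an island-level and a site-level draw,
    # so the within-island correlation of the full residual structure
    # (confounders + noise) is island_correlation.
    rho = config.island_correlation
    island_codes, islands_uniq = pd.factorize(manifest["island_id"])

    def _island_mixed(n_cols: int) -> np.ndarray:
        site_draw = rng.standard_normal((n_sites, n_cols))
        if rho == 0:
            return site_draw
        island_draw = rng.standard_normal((len(islands_uniq), n_cols))
        mixed = np.sqrt(1.0 - rho) * site_draw
        mixed[is_island] += np.sqrt(rho) * island_draw[island_codes[is_island]]
        mixed[~is_island] = site_draw[~is_island]
        return mixed

    for name, Z in groups.items():
        e = float(config.confounder_effects.get(name, 0.0))
        if e == 0.0 or Z.size == 0:
            continue
        coefs = e * _island_mixed(Z.shape[1])
        M += coefs @ Z.T

    # Causal severity effects.
    causal_sites, causal_regions, effects = _assign_causal(manifest, config)
    truth.causal_site_ids = list(causal_sites)
    truth.causal_region_ids = list(causal_regions)
    truth.true_effects = effects.to_dict()
    if len(causal_sites):
        sev = samples["severity"].to_numpy(float)
        sev_c = sev - sev.mean()
        pos = pd.Index(site_ids).get_indexer(causal_sites)
        M[pos, :] += effects.to_numpy()[:, None] * sev_c[None, :]

    # Island-correlated residual noise: total variance noise_sd^2, pairwise
    # within-island correlation = island_correlation.
    sd = config.noise_sd
    M += sd * _island_mixed(n)

    return pd.DataFrame(M, index=pd.Index(site_ids, name="probe_id"),
                        columns=samples.index)


def simulate_intensities(
    mvalues: pd.DataFrame, scale: float = 12.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired methylated/unmethylated intensities consistent with M-values.

    meth = 2^(scale + M/2) - 1 and unmeth = 2^(scale - M/2) - 1, so the
    M-transform log2((meth+1)/(unmeth+1)) recovers the input up to floating
    rounding; feed the recomputed matrix downstream for exact agreement.
    """
    meth = np.exp2(scale + mvalues / 2.0) - 1.0
    unmeth = np.exp2(scale - mvalues / 2.0) - 1.0
    return meth, unmeth


# ---------------------------------------------------------------------------
# clinical features

DEFORMITY_LEVELS = (0, 1, 2, 3)

# Capacities of the default rubric's point-bearing features (see severity
# module): 5 one-point bone increments, 3 deformity grades, four one-point
# flags, and two two-point flags; floor 2, ceiling 18.
_ONE_POINT_SLOTS = (
    ["bones"] * 5 + ["deformity"] * 3 + ["hearing", "bisphosphonate", "osteosarcoma",
                                         "onset"]
)


def simulate_clinical_features(
    scores: Sequence[int] | pd.Series, config: SimConfig
) -> pd.DataFrame:
    """Clinical feature table whose composite score reconstructs ``scores``.

    Constructed inverse of the default rubric: for a target score s, points
    p = s - 2 are randomly allocated across fracture/surgery (2 points each)
    and the twelve one-point increments (extra affected bones, deformity
    grades, hearing aid, bisphosphonate history, osteosarcoma, early onset).
    The hearing-aid flag implies skull involvement.
    """
    rng = _rng(config, "clinical")
    scores = pd.Series(scores)
    if ((scores < 2) | (scores > 18)).any():
        raise ValueError("scores must lie in the attainable range 2..18")
    rows = []
    for s in scores.astype(int):
        p = int(s) - 2
        # two-point features first, under the constraint the rest can absorb
        choices = [
            (f, g)
            for f in (0, 2)
            for g in (0, 2)
            if 0 <= p - f - g <= len(_ONE_POINT_SLOTS)
        ]
        f, g = choices[rng.integers(len(choices))]
        r = p - f - g
        picked = rng.choice(len(_ONE_POINT_SLOTS), size=r, replace=False)
        slots = [_ONE_POINT_SLOTS[i] for i in picked]
        bones = 1 + slots.count("bones")
        deformity = slots.count("deformity")
        hearing = "hearing" in slots
        skull = bool(hearing or rng.random() < 0.3)
        onset_early = "onset" in slots
        rows.append(
            {
                "bones_affected": bones,
                "fracture": f > 0,
                "surgery": g > 0,
                "osteosarcoma": "osteosarcoma" in slots,
                "deformity_grade": deformity,
                "skull_involved": skull,
                "hearing_aid": hearing,
                "prior_bisphosphonate": "bisphosphonate" in slots,
                "age_at_onset": float(
                    rng.integers(35, 55) if onset_early else rng.integers(55, 76)
                ),
            }
        )
    out = pd.DataFrame(rows)
    if isinstance(scores.index, pd.Index):
        out.index = scores.index
    return out


# ---------------------------------------------------------------------------
# convenience bundle


@dataclass
class SimulatedDataset:
    config: SimConfig
    manifest: pd.DataFrame
    samples: pd.DataFrame          # includes the 'severity' column
    mvalues: pd.DataFrame          # sites x samples
    clinical: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generative chain with one master seed."""
    manifest = simulate_manifest(config)
    samples, truth = simulate_cohort(config)
    severity = simulate_severity(samples, truth, config)
    samples = samples.assign(severity=severity)
    mvalues = simulate_methylation(manifest, samples, truth, config)
    clinical = simulate_clinical_features(samples["severity"], config)
    return SimulatedDataset(config, manifest, samples, mvalues, clinical, truth)
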