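"""Readers and writers for the pipeline's plain-text formats.

Matrices are TSV/CSV with the site id in the first column and sample ids in
the header; the manifest is CSV with Illumina-style columns; exclusion
lists are one probe id per line; gene sets are GMT; genomic windows are BED
(converted internally to 1-based inclusive coordinates).  All report tables
use the manifest's 1-based inclusive coordinates; BED exports are 0-based
half-open.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .enrichment import GenomicWindow
from .preprocess import ExclusionLists

__all__ = [
    "PipelineConfig",
    "read_methylation_matrix",
    "write_matrix",
    "read_manifest",
    "read_sample_table",
    "read_exclusion_lists",
    "read_gmt",
    "read_bed_windows",
    "write_sites_bed",
    "write_regions_bed",
]

MANIFEST_COLUMNS = ["probe_id", "chr", "pos", "island_id", "gene", "location_class"]
_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_methylation_matrix(path) -> pd.DataFrame:
    """Sites x samples numeric matrix; duplicate site ids are an error."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate site id(s): {sorted(set(dup))[:5]}")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        for col in bad:
            rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(rows):
                raise ValueError(
                    f"non-numeric value at row {rows[0]!r}, column {col!r}"
                )
        df = df.apply(pd.to_numeric)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep(path), float_format="%.12g")


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV; chromosome labels normalized ('chr10' -> '10')."""
    df = pd.read_csv(path, sep=_sep(path), dtype={"chr": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required column(s): {missing}")
    df["chr"] = (
        df["chr"].astype(str).str.replace("^chr", "", regex=True).str.upper()
        .str.replace("23", "X").str.replace("24", "Y")
    )
    bad_chr = set(df["chr"]) - _VALID_CHROMS
    if bad_chr:
        raise ValueError(f"unrecognized chromosome label(s): {sorted(bad_chr)}")
    df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(int)
    if (df["pos"] < 1).any():
        raise ValueError("positions must be 1-based positive integers")
    for col in ("island_id", "gene", "location_class"):
        df[col] = df[col].fillna("").astype(str)
    return df[MANIFEST_COLUMNS]


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def read_exclusion_lists(directory) -> ExclusionLists:
    """Load probe blacklists from ``<dir>/<reason>.txt`` (one id per line)."""
    directory = Path(directory)
    kw = {}
    for reason in ("cross_reactive", "snp_overlap", "sex_chromosome",
                   "smoking_associated"):
        f = directory / f"{reason}.txt"
        kw[reason] = (
            {line.strip() for line in f.read_text().splitlines() if line.strip()}
            if f.exists()
            else set()
        )
    return ExclusionLists(**kw)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3 and parts[0]:
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_bed_windows(path) -> list[GenomicWindow]:
    """BED windows (0-based half-open) -> 1-based inclusive intervals."""
    windows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom = parts[0].removeprefix("chr")
        label = parts[3] if len(parts) > 3 else f"window_{i + 1}"
        windows.append(
            GenomicWindow(label=label, chr=chrom,
                          start=int(parts[1]) + 1, end=int(parts[2]))
        )
    return windows


def write_sites_bed(table: pd.DataFrame, path) -> None:
    """Significant-site BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for row in table.itertuples():
            fh.write(f"chr{row.chr}\t{int(row.pos) - 1}\t{int(row.pos)}\t"
                     f"{row.site_id}\n")


def write_regions_bed(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in table.itertuples():
            fh.write(f"chr{row.chr}\t{int(row.start) - 1}\t{int(row.end)}\t"
                     f"{row.region_id}\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """End-to-end run configuration, serialized verbatim next to the outputs."""

    out_dir: str = "methsev_out"
    seed: int = 0

    # inputs; when mvalues/manifest/samples are all None a synthetic cohort
    # is generated with the sim_* settings below
    mvalues: str | None = None
    intensities_meth: str | None = None
    intensities_unmeth: str | None = None
    manifest: str | None = None
    samples: str | None = None
    clinical: str | None = None
    exclude_dir: str | None = None
    cell_reference: str | None = None
    gene_sets: str | None = None
    windows: str | None = None

    # synthetic-cohort settings (used only when simulating)
    sim_n_samples: int = 232
    sim_n_sites: int = 20_000
    sim_frac_causal: float = 0.01

    # thresholds
    fdr: float = 0.05
    bonferroni: float = 0.05
    qc_threshold: float = 11.0
    n_sv: int = 10
    split_seed: int = 1
    dichotomize_threshold: float | str = "median"
    df_guard: int = 10

    # stage toggles
    run_site: bool = True
    run_region: bool = True
    run_enrichment: bool = True
    run_predictor: bool = True
    make_plots: bool = False

    def validate(self) -> None:
        for thr in ("fdr", "bonferroni"):
            v = getattr(self, thr)
            if not 0 < v <= 1:
                raise ValueError(f"{thr} must be in (0, 1]")
        if self.n_sv < 0:
            raise ValueError("n_sv must be >= 0")
        for attr in ("mvalues", "manifest", "samples", "clinical", "gene_sets",
                     "windows", "cell_reference", "exclude_dir",
                     "intensities_meth", "intensities_unmeth"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
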