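"""Core data containers and table I/O.

The pipeline operates on two joined tables: a sample x OTU read-count
matrix with per-OTU taxonomy, and a per-sample metadata record carrying
patient identity, sampling time, qPCR-derived bacterial load
(16S rRNA gene copies per ml of lavage fluid), a host-gene expression
panel (log2 fold change versus a reference gene), anellovirus loads
(log10 genome copies) and categorical clinical flags.

All tables are read and written as plain TSV/CSV with a one-line header
so intermediate artefacts stay inspectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Default month boundaries of the five post-transplant sampling windows:
#: (0, 1.5], (1.5, 6], (6, 12], (12, 24], (24, inf).
DEFAULT_WINDOW_BOUNDARIES = (1.5, 6.0, 12.0, 24.0)


class ValidationError(ValueError):
    """A table violated a structural invariant."""


@dataclass
class CountTable:
    """Samples x OTUs non-negative integer read counts with taxonomy.

    ``counts`` is a DataFrame indexed by sample_id with OTU-id columns.
    ``taxonomy`` maps otu_id -> {rank: name}; phylum may be missing (None).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, dict[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index.name = None
        self.counts.columns.name = None
        validate_count_frame(self.counts)
        extra = set(self.taxonomy) - set(self.otu_ids)
        if extra:
            raise ValidationError(
                f"taxonomy keyed by unknown OTU ids: {sorted(extra)[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    def subset_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        keep = list(otu_ids)
        tax = {o: self.taxonomy[o] for o in keep if o in self.taxonomy}
        return CountTable(self.counts[keep], tax)


def validate_count_frame(frame: pd.DataFrame) -> None:
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    if frame.columns.duplicated().any():
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate OTU ids: {dups}")
    arr = frame.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("counts must be numeric")
    if arr.size:
        bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                "counts must be non-negative integers; offending cell "
                f"(sample={frame.index[i]!r}, otu={frame.columns[j]!r}, "
                f"value={arr[i, j]!r})"
            )


@dataclass
class SampleInfo:
    """Per-sample metadata record."""

    sample_id: str
    patient_id: str
    months_post_tx: float
    time_window: int | None = None
    bacterial_load: float | None = None
    gene_expr: dict[str, float] = field(default_factory=dict)
    viral_loads: dict[str, float] = field(default_factory=dict)
    clinical_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.months_post_tx < 0:
            raise ValidationError(
                f"months_post_tx must be non-negative for {self.sample_id!r}"
            )
        if self.bacterial_load is not None and not np.isfinite(self.bacterial_load):
            self.bacterial_load = None


@dataclass
class AnalysisConfig:
    """Tunable parameters of a full pipeline run.

    Every source of randomness flows from a named seed so a run is a
    pure function of (inputs, config).
    """

    min_reads_per_sample: int = 10_000
    rarefaction_seed: int = 7_001
    window_boundaries: tuple[float, ...] = DEFAULT_WINDOW_BOUNDARIES
    k_range: tuple[int, int] = (2, 10)
    n_permutations: int = 10_000
    bootstrap_reps: int = 100
    ntrees: int = 500
    mtry_grid: tuple[int, ...] = ()
    cv_folds: int = 10
    cv_repeats: int = 3
    boruta_alpha: float = 0.01
    boruta_max_iter: int = 100
    fdr_method: str = "fdr_bh"
    importance_ci_level: float = 0.99
    n_top_taxa: int = 30
    permanova_seed: int = 7_002
    boruta_seed: int = 7_003
    markov_seed: int = 7_004
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "min_reads_per_sample",
            "n_permutations",
            "bootstrap_reps",
            "ntrees",
            "cv_folds",
            "cv_repeats",
            "boruta_max_iter",
            "n_top_taxa",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("importance_ci_level", "ci_level", "boruta_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValidationError("k_range must satisfy 2 <= kmin <= kmax")
        self.window_boundaries = tuple(sorted(self.window_boundaries))


def assign_time_window(
    months: float, boundaries: Sequence[float] = DEFAULT_WINDOW_BOUNDARIES
) -> int:
    """Ordinal window (1-based) of a sampling time under right-closed bins.

    With boundaries (b1 < b2 < ... < bm) the windows are
    (0, b1], (b1, b2], ..., (bm, inf) -> 1 .. m+1.
    """
    if months < 0:
        raise ValidationError("months must be non-negative")
    return int(np.searchsorted(np.asarray(boundaries), months, side="left")) + 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SEPS = {"tsv": "\t", "csv": ","}


def read_count_table(
    path,
    format: str = "tsv",
    orientation: str = "samples_by_otus",
    taxonomy_path=None,
) -> CountTable:
    """Read a count matrix (first column = row ids) plus optional taxonomy sidecar.

    ``orientation`` declares whether rows are samples or OTUs; the result
    is always normalized to samples x OTUs.
    """
    sep = _SEPS[format]
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if orientation == "otus_by_samples":
        frame = frame.T
    elif orientation != "samples_by_otus":
        raise ValueError(f"unknown orientation {orientation!r}")
    taxonomy: dict[str, dict[str, str | None]] = {}
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path, sep=sep)
    return CountTable(frame, taxonomy)


def read_taxonomy(path, sep: str = "\t") -> dict[str, dict[str, str | None]]:
    tx = pd.read_csv(path, sep=sep, index_col=0)
    tx.index = tx.index.astype(str)
    out: dict[str, dict[str, str | None]] = {}
    for otu, row in tx.iterrows():
        out[otu] = {
            rank: (None if pd.isna(row.get(rank)) else str(row.get(rank)))
            for rank in TAXONOMY_RANKS
            if rank in tx.columns
        }
    return out


def write_count_table(table: CountTable, path, taxonomy_path=None) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")
    if taxonomy_path is not None and table.taxonomy:
        tx = pd.DataFrame.from_dict(table.taxonomy, orient="index")
        tx.to_csv(taxonomy_path, sep="\t", index_label="otu_id")


def read_sample_info(
    path,
    config: AnalysisConfig | None = None,
    count_table: CountTable | None = None,
    format: str = "tsv",
) -> list[SampleInfo]:
    """Read per-sample metadata.

    Columns ``sample_id``, ``patient_id`` and ``months_post_tx`` are
    required.  Gene-expression columns are prefixed ``gene_``, viral
    loads ``virus_`` and clinical flags ``flag_``.  ``time_window`` is
    computed from months when absent.  Missing covariates are stored as
    explicit missing (absent from the per-sample maps / None).
    """
    config = config or AnalysisConfig()
    frame = pd.read_csv(path, sep=_SEPS[format])
    return sample_info_from_frame(frame, config, count_table)


def sample_info_from_frame(
    frame: pd.DataFrame,
    config: AnalysisConfig | None = None,
    count_table: CountTable | None = None,
) -> list[SampleInfo]:
    config = config or AnalysisConfig()
    required = {"sample_id", "patient_id", "months_post_tx"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"sample metadata missing columns: {sorted(missing)}")
    if frame["sample_id"].duplicated().any():
        dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups}")
    gene_cols = [c for c in frame.columns if c.startswith("gene_")]
    virus_cols = [c for c in frame.columns if c.startswith("virus_")]
    flag_cols = [c for c in frame.columns if c.startswith("flag_")]
    records: list[SampleInfo] = []
    for _, row in frame.iterrows():
        months = float(row["months_post_tx"])
        if "time_window" in frame.columns and not pd.isna(row["time_window"]):
            window = int(row["time_window"])
        else:
            window = assign_time_window(months, config.window_boundaries)
        load = None
        if "bacterial_load" in frame.columns and not pd.isna(row["bacterial_load"]):
            load = float(row["bacterial_load"])
        records.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                months_post_tx=months,
                time_window=window,
                bacterial_load=load,
                gene_expr={
                    c[len("gene_"):]: float(row[c])
                    for c in gene_cols
                    if not pd.isna(row[c])
                },
                viral_loads={
                    c[len("virus_"):]: float(row[c])
                    for c in virus_cols
                    if not pd.isna(row[c])
                },
                clinical_flags={
                    c[len("flag_"):]: str(row[c])
                    for c in flag_cols
                    if not pd.isna(row[c])
                },
            )
        )
    if count_table is not None:
        unknown = {r.sample_id for r in records} - set(count_table.sample_ids)
        if unknown:
            warnings.warn(
                f"{len(unknown)} metadata samples absent from count table "
                f"(e.g. {sorted(unknown)[:3]})",
                stacklevel=2,
            )
    return records


def sample_info_to_frame(records: Sequence[SampleInfo]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "months_post_tx": r.months_post_tx,
            "time_window": r.time_window,
            "bacterial_load": r.bacterial_load,
        }
        row.update({f"gene_{g}": v for g, v in r.gene_expr.items()})
        row.update({f"virus_{g}": v for g, v in r.viral_loads.items()})
        row.update({f"flag_{g}": v for g, v in r.clinical_flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_sample_info(records: Sequence[SampleInfo], path) -> None:
    sample_info_to_frame(records).to_csv(path, sep="\t", index=False)


def info_by_sample(records: Sequence[SampleInfo]) -> dict[str, SampleInfo]:
    return {r.sample_id: r for r in records}


def config_from_yaml(path) -> AnalysisConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    tuple_fields = {"window_boundaries", "k_range", "mtry_grid"}
    kwargs = {
        k: tuple(v) if k in tuple_fields else v for k, v in raw.items()
    }
    return AnalysisConfig(**kwargs)


__all__ = [
    "AnalysisConfig",
    "CountTable",
    "SampleInfo",
    "ValidationError",
    "DEFAULT_WINDOW_BOUNDARIES",
    "TAXONOMY_RANKS",
    "assign_time_window",
    "config_from_yaml",
    "info_by_sample",
    "read_count_table",
    "read_sample_info",
    "read_taxonomy",
    "sample_info_from_frame",
    "sample_info_to_frame",
    "write_count_table",
    "write_sample_info",
]
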