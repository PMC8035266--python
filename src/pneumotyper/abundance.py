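"""Filtering, rarefaction and absolute-abundance transforms.

Low-biomass airway samples make relative abundances alone misleading:
a sample with 10^2 16S copies/ml and one with 10^6 copies/ml can share
identical proportions.  Scaling per-sample proportions by the qPCR load
("absolute abundance", copies/ml) restores the biomass axis and is the
basis of the prevalence/biomass core-taxon summaries here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import CountTable, SampleInfo, ValidationError, info_by_sample


@dataclass
class AbundanceMatrix:
    """Samples x OTUs real-valued abundances.

    ``mode`` is ``"relative"`` (per-sample simplex; empty samples all-zero)
    or ``"absolute"`` (relative x bacterial load; rows sum to the sample's
    16S copies/ml).
    """

    values: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValueError(f"unknown mode {self.mode!r}")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("abundances must be non-negative")
        if self.mode == "relative" and arr.size:
            sums = arr.sum(axis=1)
            ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0)
            if not ok.all():
                bad = self.values.index[~ok][0]
                raise ValidationError(f"relative rows must sum to 1 ({bad!r})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PrevalenceRecord:
    otu_id: str
    incidence_pct: float
    mean_rel_abundance: float
    total_absolute: float
    taxonomy: dict[str, str | None]


def filter_dataset(
    table: CountTable,
    info: Sequence[SampleInfo],
    min_reads: int = 10_000,
    blocklist: Iterable[str] = (),
) -> tuple[CountTable, list[SampleInfo], dict[str, list[str]]]:
    """Drop ambiguous-taxonomy OTUs, blocklisted OTUs, and thin/unquantified samples.

    OTUs with a missing phylum assignment are removed regardless of
    abundance, as are OTUs on the contaminant blocklist.  Samples with
    total reads below ``min_reads`` or without a bacterial-load
    measurement are removed.  Returns the filtered pair plus a report of
    dropped ids.
    """
    blockset = set(blocklist)
    dropped_otus: list[str] = []
    for otu in table.otu_ids:
        tax = table.taxonomy.get(otu, {})
        if tax.get("phylum") is None or otu in blockset:
            dropped_otus.append(otu)
    keep_otus = [o for o in table.otu_ids if o not in set(dropped_otus)]
    out = table.subset_otus(keep_otus)

    by_id = info_by_sample(info)
    totals = out.sample_totals()
    dropped_samples: list[str] = []
    keep_samples: list[str] = []
    for sid in out.sample_ids:
        rec = by_id.get(sid)
        if totals[sid] < min_reads or rec is None or rec.bacterial_load is None:
            dropped_samples.append(sid)
        else:
            keep_samples.append(sid)
    if not keep_samples:
        raise ValidationError("empty dataset after filtering")
    out = out.subset_samples(keep_samples)
    kept_info = [by_id[s] for s in keep_samples]
    report = {"dropped_otus": dropped_otus, "dropped_samples": dropped_samples}
    return out, kept_info, report


def derive_blocklist(
    table: CountTable, control_samples: Sequence[str], min_count: int = 1
) -> list[str]:
    """Contaminant OTUs: >= min_count reads in at least one negative control."""
    sub = table.counts.loc[list(control_samples)]
    mask = (sub >= min_count).any(axis=0)
    return list(sub.columns[mask])


def rarefy(table: CountTable, depth: int | None = None, seed: int = 0) -> CountTable:
    """Subsample every sample without replacement to a common depth.

    Defaults to the minimum per-sample total.  Each row is an exact
    multivariate-hypergeometric draw, so output rows sum to ``depth``.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    short = totals[totals < depth]
    if len(short):
        raise ValidationError(
            f"rarefaction depth {depth} exceeds total reads of sample "
            f"{short.index[0]!r} ({int(short.iloc[0])})"
        )
    rng = np.random.default_rng(seed)
    counts = table.matrix.astype(np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        if counts[i].sum() == depth:
            out[i] = counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    frame = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CountTable(frame, table.taxonomy)


def to_relative(table: CountTable | AbundanceMatrix) -> AbundanceMatrix:
    if isinstance(table, AbundanceMatrix):
        frame = table.values
    else:
        frame = table.counts
    arr = frame.to_numpy(dtype=float)
    sums = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(sums > 0, arr / sums, 0.0)
    return AbundanceMatrix(
        pd.DataFrame(rel, index=frame.index, columns=frame.columns), "relative"
    )


def to_absolute(rel: AbundanceMatrix, info: Sequence[SampleInfo]) -> AbundanceMatrix:
    """Scale relative abundances by each sample's 16S copies/ml."""
    if rel.mode != "relative":
        raise ValidationError("to_absolute requires a relative-mode matrix")
    by_id = info_by_sample(info)
    loads = []
    for sid in rel.sample_ids:
        rec = by_id.get(sid)
        if rec is None or rec.bacterial_load is None:
            raise ValidationError(f"missing bacterial load for sample {sid!r}")
        loads.append(rec.bacterial_load)
    arr = rel.values.to_numpy(dtype=float) * np.asarray(loads)[:, None]
    return AbundanceMatrix(
        pd.DataFrame(arr, index=rel.values.index, columns=rel.values.columns),
        "absolute",
    )


def prevalence_summary(
    table: CountTable, absolute: AbundanceMatrix
) -> list[PrevalenceRecord]:
    """Per-OTU incidence (% samples with count > 0), mean relative abundance
    and summed absolute abundance, sorted by incidence then biomass."""
    if list(table.otu_ids) != list(absolute.otu_ids) or list(
        table.sample_ids
    ) != list(absolute.sample_ids):
        raise ValidationError("count table and abundance matrix axes differ")
    rel = to_relative(table)
    n = len(table.sample_ids)
    incidence = (table.counts > 0).sum(axis=0) / n * 100.0
    mean_rel = rel.values.mean(axis=0)
    total_abs = absolute.values.sum(axis=0)
    records = [
        PrevalenceRecord(
            otu_id=o,
            incidence_pct=float(incidence[o]),
            mean_rel_abundance=float(mean_rel[o]),
            total_absolute=float(total_abs[o]),
            taxonomy=table.taxonomy.get(o, {}),
        )
        for o in table.otu_ids
    ]
    records.sort(key=lambda r: (-r.incidence_pct, -r.total_absolute, r.otu_id))
    return records


def prevalence_frame(records: Sequence[PrevalenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": [r.otu_id for r in records],
            "incidence_pct": [r.incidence_pct for r in records],
            "mean_rel_abundance": [r.mean_rel_abundance for r in records],
            "total_absolute": [r.total_absolute for r in records],
            "genus": [r.taxonomy.get("genus") for r in records],
            "phylum": [r.taxonomy.get("phylum") for r in records],
        }
    )


def core_taxa(
    records: Sequence[PrevalenceRecord], incidence_threshold: float = 50.0
) -> set[str]:
    """OTUs present in at least ``incidence_threshold`` % of samples."""
    if not records:
        raise ValidationError("empty prevalence records")
    return {r.otu_id for r in records if r.incidence_pct >= incidence_threshold}


def top_biomass_set(
    records: Sequence[PrevalenceRecord], fraction: float = 0.75
) -> set[str]:
    """Smallest prefix of OTUs (by total absolute abundance, descending,
    ties by otu_id) whose cumulative biomass share reaches ``fraction``."""
    if not records:
        raise ValidationError("empty prevalence records")
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-r.total_absolute, r.otu_id))
    total = sum(r.total_absolute for r in ordered)
    if total <= 0:
        return set()
    out: set[str] = set()
    cum = 0.0
    for r in ordered:
        if r.total_absolute <= 0:
            break
        out.add(r.otu_id)
        cum += r.total_absolute
        if cum / total >= fraction - 1e-12:
            break
    return out


def sample_dominance(rel: AbundanceMatrix) -> pd.Series:
    """Per-sample maximum relative abundance (Berger-Parker, 1/H_inf)."""
    if rel.mode != "relative":
        raise ValidationError("sample_dominance requires relative mode")
    arr = rel.values.to_numpy(dtype=float)
    sums = arr.sum(axis=1)
    out = arr.max(axis=1)
    if (sums == 0).any():
        warnings.warn("empty sample rows yield missing dominance", stacklevel=2)
        out = np.where(sums == 0, np.nan, out)
    return pd.Series(out, index=rel.values.index, name="dominance")


__all__ = [
    "AbundanceMatrix",
    "PrevalenceRecord",
    "core_taxa",
    "derive_blocklist",
    "filter_dataset",
    "prevalence_frame",
    "prevalence_summary",
    "rarefy",
    "sample_dominance",
    "to_absolute",
    "to_relative",
    "top_biomass_set",
]
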