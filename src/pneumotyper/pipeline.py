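"""End-to-end orchestration: filter -> rarefy -> diversity -> cluster ->
enrich -> host model -> Markov dynamics.

Every stage's randomness is tied to a named seed in ``AnalysisConfig``,
so a run is a pure function of (inputs, config) and reruns are
byte-identical.  Stage outputs are retained on the report object and,
when an output directory is given, written as TSV as each stage
completes (a failing stage aborts with its name but keeps partial
outputs on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, diversity, enrichment, host_model, markov, pneumotype
from .core_io import (
    AnalysisConfig,
    CountTable,
    SampleInfo,
    write_count_table,
)

STAGES = ("filter", "rarefy", "diversity", "cluster", "enrich", "hostmodel", "markov")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineReport:
    config: AnalysisConfig
    log: list[str] = field(default_factory=list)
    filtered: CountTable | None = None
    kept_info: list[SampleInfo] = field(default_factory=list)
    filter_report: dict = field(default_factory=dict)
    rarefied: CountTable | None = None
    relative: abundance.AbundanceMatrix | None = None
    absolute: abundance.AbundanceMatrix | None = None
    alpha: pd.DataFrame | None = None
    beta: diversity.DissimilarityMatrix | None = None
    permanova: pd.DataFrame | None = None
    clusters: pneumotype.ClusterSolution | None = None
    prevalence: pd.DataFrame | None = None
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    boruta: host_model.BorutaReport | None = None
    load_model: host_model.LinearModelReport | None = None
    markov_model: markov.MarkovModel | None = None
    memorylessness: markov.ChiSquareResult | None = None
    time_homogeneity: markov.ChiSquareResult | None = None


def _write(outdir: Path | None, name: str, frame: pd.DataFrame, index=True) -> None:
    if outdir is not None:
        frame.to_csv(outdir / name, sep="\t", index=index, float_format="%.10g")


def run_pipeline(
    config: AnalysisConfig,
    table: CountTable,
    info: list[SampleInfo],
    outdir=None,
    blocklist=(),
) -> PipelineReport:
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=config)
    log = report.log
    log.append(
        f"seeds: rarefaction={config.rarefaction_seed} "
        f"permanova={config.permanova_seed} boruta={config.boruta_seed} "
        f"markov={config.markov_seed}"
    )

    stage = "filter"
    try:
        filtered, kept, frep = abundance.filter_dataset(
            table, info, min_reads=config.min_reads_per_sample, blocklist=blocklist
        )
        report.filtered, report.kept_info, report.filter_report = filtered, kept, frep
        log.append(
            f"filter: kept {len(filtered.sample_ids)} samples / "
            f"{len(filtered.otu_ids)} OTUs; dropped "
            f"{len(frep['dropped_samples'])} samples, {len(frep['dropped_otus'])} OTUs"
        )
        if outdir is not None:
            write_count_table(filtered, outdir / "filtered_counts.tsv")

        stage = "rarefy"
        depth = int(filtered.sample_totals().min())
        rarefied = abundance.rarefy(filtered, depth, seed=config.rarefaction_seed)
        report.rarefied = rarefied
        log.append(f"rarefy: depth {depth}")
        if outdir is not None:
            write_count_table(rarefied, outdir / "rarefied_counts.tsv")
        rel = abundance.to_relative(rarefied)
        absolute = abundance.to_absolute(rel, kept)
        report.relative, report.absolute = rel, absolute
        prev = abundance.prevalence_frame(
            abundance.prevalence_summary(rarefied, absolute)
        )
        report.prevalence = prev
        _write(outdir, "prevalence.tsv", prev, index=False)

        stage = "diversity"
        alpha = diversity.alpha_table(rel.values)
        report.alpha = alpha
        _write(outdir, "alpha_diversity.tsv", alpha)
        beta = diversity.beta_matrix(rel, metric="bray_curtis")
        report.beta = beta
        _write(outdir, "beta_bray_curtis.tsv", beta.to_frame())

        stage = "cluster"
        clusters = pneumotype.select_k_and_assign(beta, k_range=config.k_range)
        report.clusters = clusters
        log.append(
            f"cluster: k={clusters.k} ASW={clusters.asw:.4f}"
            + (" [weak structure]" if clusters.weak_structure else "")
        )
        if outdir is not None:
            lab = clusters.labels.rename("pneumotype").rename_axis("sample_id")
            _write(outdir, "pneumotype_labels.tsv", lab.reset_index(), index=False)
            trace = pd.DataFrame(
                sorted(clusters.asw_trace.items()), columns=["k", "ASW"]
            )
            _write(outdir, "asw_trace.tsv", trace, index=False)
        groups = clusters.labels.astype(str)
        report.permanova = diversity.pairwise_permanova(
            beta, groups, n_perm=config.n_permutations, seed=config.permanova_seed
        )
        _write(outdir, "pairwise_permanova.tsv", report.permanova, index=False)

        stage = "enrich"
        for state in sorted(groups.unique()):
            if (groups == state).sum() < 2 or (groups != state).sum() < 2:
                log.append(f"enrich: skipped state {state} (too few samples)")
                continue
            recs = enrichment.pneumotype_enrichment(
                absolute, groups, state, n_top=config.n_top_taxa
            )
            frame = enrichment.enrichment_frame(recs)
            report.enrichment[state] = frame
            _write(outdir, f"enrichment_state{state}.tsv", frame, index=False)

        stage = "hostmodel"
        genes = sorted({g for r in kept for g in r.gene_expr})
        if genes:
            X = pd.DataFrame(
                {g: [r.gene_expr.get(g, np.nan) for r in kept] for g in genes},
                index=[r.sample_id for r in kept],
            )
            complete = X.dropna()
            dropped = len(X) - len(complete)
            if dropped:
                log.append(f"hostmodel: dropped {dropped} samples with missing genes")
            y = groups.loc[complete.index].to_numpy()
            spec = host_model.ForestSpec(
                task="classification",
                ntrees=config.ntrees,
                cv_folds=config.cv_folds,
                cv_repeats=config.cv_repeats,
                seed=config.boruta_seed,
            )
            report.boruta = host_model.boruta_select(
                complete,
                y,
                spec,
                alpha=config.boruta_alpha,
                max_iter=config.boruta_max_iter,
                seed=config.boruta_seed,
            )
            log.append(
                f"hostmodel: Boruta confirmed {sorted(report.boruta.confirmed())} "
                f"in {report.boruta.n_iter} iterations"
            )
            if outdir is not None:
                dec = pd.DataFrame(
                    sorted(report.boruta.decisions.items()),
                    columns=["gene", "decision"],
                )
                dec["hits"] = dec["gene"].map(report.boruta.hits)
                _write(outdir, "boruta_decisions.tsv", dec, index=False)
            confirmed = sorted(report.boruta.confirmed())
            if confirmed:
                loads = np.log10(
                    np.array(
                        [r.bacterial_load for r in kept if r.sample_id in complete.index]
                    )
                )
                report.load_model = host_model.stepwise_aic_fit(
                    complete[confirmed], loads
                )
                log.append(
                    "hostmodel: stepwise-AIC load model terms "
                    f"{report.load_model.selected} (AIC {report.load_model.aic:.2f})"
                )

        stage = "markov"
        seqs = markov.build_sequences(groups, kept)
        report.markov_model = markov.fit_markov(
            seqs,
            bootstrap_reps=config.bootstrap_reps,
            level=config.ci_level,
            seed=config.markov_seed,
        )
        for flag in report.markov_model.flags:
            log.append(f"markov: flag {flag}")
        _write(
            outdir,
            "transition_counts.tsv",
            pd.DataFrame(
                report.markov_model.counts,
                index=report.markov_model.states,
                columns=report.markov_model.states,
            ),
        )
        _write(outdir, "transition_matrix.tsv", report.markov_model.to_frame())
        try:
            report.memorylessness = markov.memorylessness_test(seqs)
        except Exception as exc:  # few triples in small cohorts
            log.append(f"markov: memorylessness test unavailable ({exc})")
        try:
            report.time_homogeneity = markov.time_homogeneity_test(seqs)
        except Exception as exc:
            log.append(f"markov: time-homogeneity test unavailable ({exc})")
    except StageError:
        raise
    except Exception as exc:
        if outdir is not None:
            (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
        raise StageError(stage, exc) from exc

    if outdir is not None:
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return report


__all__ = ["PipelineReport", "StageError", "run_pipeline", "STAGES"]
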