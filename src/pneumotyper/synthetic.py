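"""Synthetic longitudinal cohort generator with recoverable ground truth.

Emulates the statistical structure the analysis assumes: four latent
community states with distinct compositional archetypes —

* ``balanced``: a diverse community concentrated on a 22-OTU core with
  moderate between-sample dispersion and intermediate bacterial load;
* ``staphylococcus`` / ``pseudomonas``: communities dominated by a single
  designated taxon (~3/4 of the mass) with elevated loads;
* ``microbiota_depleted``: a near-uniform spread over the whole panel
  (core + rare background) with highly variable composition and loads
  roughly two orders of magnitude below the balanced state —

plus state-dependent viral loads and host-gene expression shifts, and
per-patient state sequences driven by a ground-truth first-order Markov
chain.  Compositions are Dirichlet-multinomial draws so within-state
overdispersion is tunable.  Fixing the seed fixes every emitted byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AnalysisConfig,
    CountTable,
    SampleInfo,
    ValidationError,
    assign_time_window,
)
from .markov import simulate_chain

STATE_NAMES = ("balanced", "staphylococcus", "microbiota_depleted", "pseudomonas")

#: Ground-truth transition matrix (rows follow STATE_NAMES).  Diagonals
#: encode high recurrence of the balanced state, intermediate recurrence
#: of the depleted state, and near-disconnection between the two
#: pathogen-dominated states.
DEFAULT_P_TRUE = np.array(
    [
        [0.63, 0.07, 0.22, 0.08],
        [0.50, 0.28, 0.17, 0.05],
        [0.42, 0.08, 0.42, 0.08],
        [0.45, 0.05, 0.20, 0.30],
    ]
)

DEFAULT_P0 = np.array([0.49, 0.08, 0.33, 0.10])

CORE_GENERA = (
    "Prevotella", "Streptococcus", "Veillonella", "Neisseria", "Alloprevotella",
    "Gemella", "Granulicatella", "Campylobacter", "Porphyromonas", "Rothia",
    "Fusobacterium",
)

#: 31-gene host panel; the first six carry state-dependent shifts.
GENE_PANEL = (
    "IFNLR1", "MRC1", "IL10", "IL1RN", "LY96", "PDGFD",
    "TLR3", "IDO1", "IGF1", "RSAD2", "IFITM2", "TNF", "IL1B", "IL6", "IL8",
    "IL17A", "IL22", "IL33", "TGFB1", "FOXP3", "CCL2", "CXCL10", "MMP9",
    "TIMP1", "COL1A1", "FN1", "MUC5AC", "MUC5B", "SFTPC", "CD68", "NKG7",
)

#: Additive log2-expression shifts per informative gene and state.
DEFAULT_GENE_SHIFTS: dict[str, dict[str, float]] = {
    "IFNLR1": {"balanced": 1.2, "microbiota_depleted": -1.0},
    "MRC1": {"staphylococcus": 1.2, "microbiota_depleted": 1.2, "pseudomonas": -1.0},
    "IL10": {"balanced": 1.2},
    "IL1RN": {"balanced": -1.2},
    "LY96": {"staphylococcus": 1.2, "pseudomonas": -1.2},
    "PDGFD": {"microbiota_depleted": 1.4},
}

#: log10 genome copies per virus genus and state.
DEFAULT_VIRAL_MU: dict[str, dict[str, float]] = {
    "alphatorquevirus": {
        "balanced": 3.5, "staphylococcus": 3.8,
        "microbiota_depleted": 2.2, "pseudomonas": 4.5,
    },
    "betatorquevirus": {
        "balanced": 3.2, "staphylococcus": 3.5,
        "microbiota_depleted": 2.0, "pseudomonas": 3.6,
    },
    "gammatorquevirus": {
        "balanced": 4.2, "staphylococcus": 4.4,
        "microbiota_depleted": 2.8, "pseudomonas": 4.5,
    },
}


@dataclass
class StateProfile:
    state_name: str
    composition: np.ndarray  # mean relative abundances (simplex)
    concentration: float  # Dirichlet concentration scalar
    load_mu: float  # mean of log10 bacterial load (copies/ml)
    load_sigma: float
    viral_mu: dict[str, float] = field(default_factory=dict)
    gene_shift: dict[str, float] = field(default_factory=dict)
    depth_range: tuple[int, int] = (30_000, 60_000)

    def __post_init__(self) -> None:
        self.composition = np.asarray(self.composition, dtype=float)
        if (self.composition < 0).any() or not np.isclose(
            self.composition.sum(), 1.0, atol=1e-9
        ):
            raise ValidationError(
                f"composition of {self.state_name!r} must be a simplex vector"
            )
        if self.concentration <= 0 or self.load_sigma <= 0:
            raise ValidationError("concentration and load_sigma must be positive")


@dataclass
class CohortTruth:
    states: list[StateProfile]
    P_true: np.ndarray
    p0: np.ndarray
    labels: pd.Series  # sample_id -> state name
    gene_panel: list[str]
    informative_genes: list[str]
    gene_noise_sd: float
    viral_noise_sd: float

    def __post_init__(self) -> None:
        P = np.asarray(self.P_true, dtype=float)
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("P_true rows must sum to 1")
        if not np.isclose(np.asarray(self.p0).sum(), 1.0, atol=1e-9):
            raise ValidationError("p0 must lie on the simplex")


@dataclass
class SyntheticConfig:
    n_patients: int = 64
    samples_per_patient: tuple[int, int] = (1, 8)
    n_core_otus: int = 22
    n_rare_otus: int = 33
    n_ambiguous_otus: int = 3  # rare OTUs with missing phylum (filter fodder)
    gene_noise_sd: float = 0.5
    viral_noise_sd: float = 0.5
    study_months: float = 49.0
    P_true: np.ndarray = field(default_factory=lambda: DEFAULT_P_TRUE.copy())
    p0: np.ndarray = field(default_factory=lambda: DEFAULT_P0.copy())
    gene_shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(s) for g, s in DEFAULT_GENE_SHIFTS.items()}
    )

    @property
    def n_otus(self) -> int:
        # core + two designated pathogens + rare background (incl. ambiguous)
        return self.n_core_otus + 2 + self.n_rare_otus + self.n_ambiguous_otus


def _otu_panel(cfg: SyntheticConfig):
    """OTU ids and taxonomy; pathogen OTUs are the dominated-state markers."""
    otus, tax = [], {}
    for i in range(cfg.n_core_otus):
        oid = f"OTU_core_{i + 1:02d}"
        genus = CORE_GENERA[i % len(CORE_GENERA)]
        otus.append(oid)
        tax[oid] = {
            "kingdom": "Bacteria",
            "phylum": "Bacteroidetes" if genus in ("Prevotella", "Alloprevotella",
                                                   "Porphyromonas") else "Firmicutes",
            "genus": genus,
        }
    otus.append("OTU_staph")
    tax["OTU_staph"] = {
        "kingdom": "Bacteria", "phylum": "Firmicutes", "genus": "Staphylococcus",
    }
    otus.append("OTU_pseudomonas")
    tax["OTU_pseudomonas"] = {
        "kingdom": "Bacteria", "phylum": "Proteobacteria", "genus": "Pseudomonas",
    }
    for i in range(cfg.n_rare_otus):
        oid = f"OTU_rare_{i + 1:02d}"
        otus.append(oid)
        tax[oid] = {
            "kingdom": "Bacteria",
            "phylum": ("Actinobacteria", "Proteobacteria", "Firmicutes")[i % 3],
            "genus": f"Rare_genus_{i + 1}",
        }
    for i in range(cfg.n_ambiguous_otus):
        oid = f"OTU_ambig_{i + 1:02d}"
        otus.append(oid)
        tax[oid] = {"kingdom": "Bacteria", "phylum": None, "genus": None}
    return otus, tax


def default_state_profiles(cfg: SyntheticConfig) -> list[StateProfile]:
    """The four compositional archetypes on the shared OTU panel."""
    n = cfg.n_otus
    n_core = cfg.n_core_otus
    i_staph = n_core
    i_pseudo = n_core + 1

    core_weights = 0.85 ** np.arange(n_core)  # geometric core ranking
    core = np.zeros(n)
    core[:n_core] = core_weights / core_weights.sum()

    rare = np.zeros(n)
    rare[i_pseudo + 1:] = 1.0
    rare /= rare.sum()

    balanced = 0.93 * core + 0.07 * rare

    def dominated(idx: int) -> np.ndarray:
        comp = 0.20 * core + 0.05 * rare
        comp[idx] += 0.75
        return comp / comp.sum()

    depleted = 0.08 * core + 0.92 * np.full(n, 1.0 / n)
    depleted /= depleted.sum()

    def viral(state: str) -> dict[str, float]:
        return {v: mus[state] for v, mus in DEFAULT_VIRAL_MU.items()}

    def shifts(state: str) -> dict[str, float]:
        return {
            g: per_state.get(state, 0.0)
            for g, per_state in cfg.gene_shifts.items()
            if per_state.get(state, 0.0) != 0.0
        }

    return [
        StateProfile("balanced", balanced, 80.0, 4.5, 0.35,
                     viral("balanced"), shifts("balanced"), (30_000, 60_000)),
        StateProfile("staphylococcus", dominated(i_staph), 60.0, 5.3, 0.40,
                     viral("staphylococcus"), shifts("staphylococcus"),
                     (30_000, 60_000)),
        StateProfile("microbiota_depleted", depleted, 40.0, 2.4, 0.45,
                     viral("microbiota_depleted"), shifts("microbiota_depleted"),
                     (12_000, 30_000)),
        StateProfile("pseudomonas", dominated(i_pseudo), 60.0, 5.3, 0.40,
                     viral("pseudomonas"), shifts("pseudomonas"), (30_000, 60_000)),
    ]


def sample_state_sequence(p0, P, n: int, seed: int = 0, rng=None) -> np.ndarray:
    """Latent state indices for one patient (first ~ p0, then rows of P)."""
    return simulate_chain(P, p0, n, seed=seed, rng=rng)


def draw_composition(
    profile: StateProfile, depth: int, seed: int = 0, rng=None
) -> np.ndarray:
    """Dirichlet-multinomial read counts for one sample of a state.

    p ~ Dirichlet(concentration * composition) restricted to the
    profile's support, counts ~ Multinomial(depth, p); the counts sum to
    ``depth`` exactly.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    comp = profile.composition
    if comp.sum() == 0:
        raise ValidationError("zero-vector composition")
    rng = rng if rng is not None else np.random.default_rng(seed)
    support = comp > 0
    alpha = profile.concentration * comp[support]
    p = rng.dirichlet(alpha)
    counts = np.zeros(len(comp), dtype=np.int64)
    counts[support] = rng.multinomial(depth, p)
    return counts


def generate_cohort(
    cfg: SyntheticConfig | None = None,
    seed: int = 0,
    profiles: list[StateProfile] | None = None,
) -> tuple[CountTable, list[SampleInfo], CohortTruth]:
    """Full synthetic cohort: counts, metadata, and ground truth.

    Per patient a latent state sequence of its sample count is drawn
    from the ground-truth chain; per sample a composition at a
    state-dependent depth, a bacterial load ~ 10^N(load_mu, load_sigma),
    viral loads and gene expression (state shift + Gaussian noise).
    """
    cfg = cfg or SyntheticConfig()
    profiles = profiles or default_state_profiles(cfg)
    sizes = {len(p.composition) for p in profiles}
    if sizes != {cfg.n_otus}:
        raise ValidationError(
            f"profile panel sizes {sizes} inconsistent with config ({cfg.n_otus})"
        )
    rng = np.random.default_rng(seed)
    otus, taxonomy = _otu_panel(cfg)
    analysis_cfg = AnalysisConfig()

    rows, infos, label_items = [], [], []
    sample_counter = 0
    lo, hi = cfg.samples_per_patient
    for pi in range(cfg.n_patients):
        pid = f"P{pi + 1:03d}"
        n_samples = int(rng.integers(lo, hi + 1))
        states = sample_state_sequence(cfg.p0, cfg.P_true, n_samples, rng=rng)
        months = np.sort(rng.uniform(0.25, cfg.study_months, size=n_samples))
        for t in range(n_samples):
            sample_counter += 1
            sid = f"S{sample_counter:04d}"
            prof = profiles[states[t]]
            depth = int(rng.integers(prof.depth_range[0], prof.depth_range[1] + 1))
            counts = draw_composition(prof, depth, rng=rng)
            load = 10.0 ** rng.normal(prof.load_mu, prof.load_sigma)
            gene_expr = {
                g: prof.gene_shift.get(g, 0.0) + rng.normal(0.0, cfg.gene_noise_sd)
                for g in GENE_PANEL
            }
            viral = {
                v: prof.viral_mu[v] + rng.normal(0.0, cfg.viral_noise_sd)
                for v in sorted(prof.viral_mu)
            }
            rows.append(pd.Series(counts, index=otus, name=sid))
            infos.append(
                SampleInfo(
                    sample_id=sid,
                    patient_id=pid,
                    months_post_tx=float(months[t]),
                    time_window=assign_time_window(
                        months[t], analysis_cfg.window_boundaries
                    ),
                    bacterial_load=float(load),
                    gene_expr=gene_expr,
                    viral_loads=viral,
                    clinical_flags={},
                )
            )
            label_items.append((sid, prof.state_name))

    counts_frame = pd.DataFrame(rows)
    table = CountTable(counts_frame, taxonomy)
    informative = sorted(
        g for g, per_state in cfg.gene_shifts.items()
        if any(v != 0.0 for v in per_state.values())
    )
    truth = CohortTruth(
        states=profiles,
        P_true=np.asarray(cfg.P_true, dtype=float),
        p0=np.asarray(cfg.p0, dtype=float),
        labels=pd.Series(dict(label_items), name="state"),
        gene_panel=list(GENE_PANEL),
        informative_genes=informative,
        gene_noise_sd=cfg.gene_noise_sd,
        viral_noise_sd=cfg.viral_noise_sd,
    )
    return table, infos, truth


def truth_frame(truth: CohortTruth) -> pd.DataFrame:
    """Ground-truth labels as a writable table."""
    return truth.labels.rename_axis("sample_id").reset_index()


__all__ = [
    "CohortTruth",
    "DEFAULT_GENE_SHIFTS",
    "DEFAULT_P0",
    "DEFAULT_P_TRUE",
    "DEFAULT_VIRAL_MU",
    "GENE_PANEL",
    "STATE_NAMES",
    "StateProfile",
    "SyntheticConfig",
    "default_state_profiles",
    "draw_composition",
    "generate_cohort",
    "sample_state_sequence",
    "truth_frame",
]
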