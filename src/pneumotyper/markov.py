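"""First-order Markov-chain modelling of community-state transitions.

Consecutive samples of a patient (ordered by time window, then months)
define observed state transitions.  Pooled transitions give the
maximum-likelihood row-stochastic transition matrix; uncertainty comes
from bootstrapping *patients* (sequences are the dependent unit, not
individual transitions).  Structural properties — communicating
classes, irreducibility, periodicity, recurrent/absorbing states,
stationary distribution — are derived from the support graph, and two
chi-square checks probe the first-order (memoryless) and
time-homogeneity assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import gcd
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import SampleInfo, ValidationError


@dataclass
class StateSequence:
    patient_id: str
    steps: list[tuple[int, str]]  # (time_window, state), time-sorted

    def states(self) -> list[str]:
        return [s for _, s in self.steps]

    def transitions(self) -> list[tuple[str, str]]:
        st = self.states()
        return list(zip(st[:-1], st[1:]))


@dataclass
class ChainProperties:
    classes: list[frozenset[int]]
    irreducible: bool
    periods: list[int | None]  # per class; None if no cycle through it
    aperiodic: bool
    recurrent_classes: list[frozenset[int]]
    absorbing_states: list[int]
    stationary: np.ndarray | None


@dataclass
class MarkovModel:
    states: list[str]
    counts: np.ndarray  # S x S transition counts
    P: np.ndarray  # MLE row-stochastic; nan rows where undefined
    undefined_rows: list[str]
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    ci_level: float
    bootstrap_reps: int
    p0: np.ndarray
    properties: ChainProperties | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def recurrence(self) -> pd.Series:
        """Self-transition (recurrence) probability per state."""
        return pd.Series(np.diag(self.P), index=self.states, name="recurrence")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.states, columns=self.states)


def _check_stochastic(P: np.ndarray) -> None:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("transition matrix must be square")
    rows = P.sum(axis=1)
    bad = np.where(~np.isclose(rows, 1.0, atol=1e-9))[0]
    if bad.size or (P < 0).any():
        raise ValidationError(f"matrix is not row-stochastic (row {bad[:1]})")


def simulate_chain(P, p0, n_steps: int, seed: int = 0, rng=None) -> np.ndarray:
    """Sample a state-index sequence: first state ~ p0, then rows of P."""
    P = np.asarray(P, dtype=float)
    _check_stochastic(P)
    p0 = np.asarray(p0, dtype=float)
    if not np.isclose(p0.sum(), 1.0, atol=1e-9) or (p0 < 0).any():
        raise ValidationError("p0 must be a probability distribution")
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    S = len(p0)
    seq = np.empty(n_steps, dtype=np.int64)
    # inverse-CDF draws keep the stream identical across platforms
    cum0 = np.cumsum(p0)
    cumP = np.cumsum(P, axis=1)
    seq[0] = np.searchsorted(cum0, rng.random(), side="right")
    for t in range(1, n_steps):
        seq[t] = np.searchsorted(cumP[seq[t - 1]], rng.random(), side="right")
    return np.minimum(seq, S - 1)


def build_sequences(
    labels: pd.Series, info: Sequence[SampleInfo]
) -> list[StateSequence]:
    """Per-patient time-ordered state sequences from sample labels.

    Samples sort by (time_window, months_post_tx, sample_id); the
    sample_id tie-break is deterministic and warned about.  Patients
    with a single sample are retained (zero transitions).  When a
    ``graft_id`` clinical flag is present, each graft starts a fresh
    sequence (re-transplantation resets the chain).
    """
    by_id = {r.sample_id: r for r in info}
    missing = [s for s in labels.index if s not in by_id]
    if missing:
        raise ValidationError(f"labels for unknown samples: {missing[:3]}")
    groups: dict[tuple[str, str], list[tuple]] = {}
    for sid, state in labels.items():
        rec = by_id[sid]
        graft = rec.clinical_flags.get("graft_id", "1")
        key = (rec.patient_id, graft)
        groups.setdefault(key, []).append(
            (rec.time_window, rec.months_post_tx, str(sid), str(state))
        )
    seqs = []
    for (pid, graft), rows in sorted(groups.items()):
        rows.sort()
        keys = [(w, m) for w, m, _, _ in rows]
        if len(set(keys)) < len(keys):
            warnings.warn(
                f"patient {pid!r}: ties in (window, months) broken by sample_id",
                stacklevel=2,
            )
        seqs.append(
            StateSequence(
                patient_id=pid if graft == "1" else f"{pid}:{graft}",
                steps=[(int(w), s) for w, _, _, s in rows],
            )
        )
    return seqs


def _count_matrix(
    seqs: Sequence[StateSequence], states: list[str]
) -> np.ndarray:
    idx = {s: i for i, s in enumerate(states)}
    N = np.zeros((len(states), len(states)))
    for seq in seqs:
        for a, b in seq.transitions():
            N[idx[a], idx[b]] += 1
    return N


def _mle(N: np.ndarray) -> np.ndarray:
    totals = N.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals > 0, N / totals, np.nan)
    return P


def fit_markov(
    seqs: Sequence[StateSequence],
    bootstrap_reps: int = 100,
    level: float = 0.95,
    seed: int = 0,
    p0=None,
    states: list[str] | None = None,
    laplace: float = 0.0,
) -> MarkovModel:
    """MLE transition matrix with patient-bootstrap percentile CIs.

    ``laplace`` adds +alpha pseudocounts (off by default).  Rows with no
    outgoing transitions are reported as undefined and excluded from
    structural property claims.
    """
    if states is None:
        states = sorted({s for q in seqs for s in q.states()})
    if not states:
        raise ValidationError("no states observed")
    N = _count_matrix(seqs, states)
    if N.sum() < 1:
        raise ValidationError("no transitions observed")
    P = _mle(N + laplace if laplace > 0 else N)
    undefined = [states[i] for i in np.where(np.isnan(P).any(axis=1))[0]]
    flags = []
    if undefined:
        warnings.warn(
            f"states with no outgoing transitions: {undefined}", stacklevel=2
        )
        flags.append("undefined_rows")

    # patient bootstrap
    rng = np.random.default_rng(seed)
    per_patient = [
        _count_matrix([q], states) for q in seqs if len(q.steps) > 1
    ]
    if len(per_patient) < 2:
        flags.append("single-sequence bootstrap degenerate")
        warnings.warn(
            "bootstrap over a single sequence is degenerate; CIs unreliable",
            stacklevel=2,
        )
    reps = np.full((bootstrap_reps, len(states), len(states)), np.nan)
    if per_patient:
        stack = np.stack(per_patient)
        for b in range(bootstrap_reps):
            pick = rng.integers(0, len(stack), size=len(stack))
            reps[b] = _mle(stack[pick].sum(axis=0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan slices
        lo = np.nanpercentile(reps, (1 - level) / 2 * 100, axis=0)
        hi = np.nanpercentile(reps, (1 + level) / 2 * 100, axis=0)

    if p0 is None:
        p0 = np.full(len(states), 1.0 / len(states))
    model = MarkovModel(
        states=states,
        counts=N,
        P=P,
        undefined_rows=undefined,
        ci_lower=lo,
        ci_upper=hi,
        ci_level=level,
        bootstrap_reps=bootstrap_reps,
        p0=np.asarray(p0, dtype=float),
        flags=flags,
    )
    if not undefined:
        model.properties = chain_properties(P)
    return model


# ---------------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------------


def _class_period(nodes: list[int], edges: set[tuple[int, int]]) -> int | None:
    """Period of a communicating class: gcd of cycle lengths, via BFS levels."""
    inner = [(u, v) for (u, v) in edges if u in nodes and v in nodes]
    if not inner:
        return None
    adj: dict[int, list[int]] = {u: [] for u in nodes}
    for u, v in inner:
        adj[u].append(v)
    root = nodes[0]
    level = {root: 0}
    queue = [root]
    while queue:
        u = queue.pop(0)
        for v in adj[u]:
            if v not in level:
                level[v] = level[u] + 1
                queue.append(v)
    g = 0
    for u, v in inner:
        if u in level and v in level:
            g = gcd(g, level[u] + 1 - level[v])
    return abs(g) if g else None


def chain_properties(P) -> ChainProperties:
    """Communicating classes, periodicity, recurrence and stationarity of P.

    Classes are strongly connected components of the support digraph;
    recurrent classes are the closed ones; a state is absorbing iff its
    self-probability is 1.  The stationary distribution is obtained by
    power iteration (tolerance 1e-12) when the chain is irreducible and
    aperiodic.
    """
    P = np.asarray(P, dtype=float)
    if np.isnan(P).any():
        raise ValidationError(
            "P has undefined rows; see fit_markov flags before computing properties"
        )
    _check_stochastic(P)
    S = P.shape[0]
    support = P > 0
    G = nx.DiGraph()
    G.add_nodes_from(range(S))
    G.add_edges_from(zip(*np.nonzero(support)))
    sccs = [frozenset(c) for c in nx.strongly_connected_components(G)]
    # deterministic ordering by smallest member
    sccs.sort(key=min)
    edges = set(G.edges())
    periods = [_class_period(sorted(c), edges) for c in sccs]
    recurrent = [
        c
        for c in sccs
        if all(v in c for u in c for v in G.successors(u))
    ]
    irreducible = len(sccs) == 1
    aperiodic = all(p == 1 for p in periods if p is not None)
    absorbing = [i for i in range(S) if np.isclose(P[i, i], 1.0, atol=1e-12)]
    stationary = None
    if irreducible and aperiodic:
        pi = np.full(S, 1.0 / S)
        for _ in range(1_000_000):
            nxt = pi @ P
            if np.abs(nxt - pi).max() < 1e-12:
                pi = nxt
                break
            pi = nxt
        stationary = pi / pi.sum()
    return ChainProperties(
        classes=sccs,
        irreducible=irreducible,
        periods=periods,
        aperiodic=aperiodic,
        recurrent_classes=recurrent,
        absorbing_states=absorbing,
        stationary=stationary,
    )


# ---------------------------------------------------------------------------
# chi-square checks
# ---------------------------------------------------------------------------


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    note: str = ""


def memorylessness_test(seqs: Sequence[StateSequence]) -> ChiSquareResult:
    """First-order (memoryless) check from state triples.

    Within each stratum of the middle state, the (previous, next) table
    is tested for independence — under a first-order chain the next
    state is independent of the state two steps back.  Per-stratum
    Pearson chi-squares and dfs are summed; strata that cannot vary
    contribute nothing.  A warning is raised when any expected cell is
    below 5 (the asymptotic approximation degrades there).
    """
    triples: list[tuple[str, str, str]] = []
    for q in seqs:
        st = q.states()
        triples.extend(zip(st[:-2], st[1:-1], st[2:]))
    if not triples:
        raise ValidationError("no state triples available")
    frame = pd.DataFrame(triples, columns=["prev", "mid", "next"])
    if frame["next"].nunique() == 1 and frame["prev"].nunique() == 1:
        return ChiSquareResult(0.0, 0, 1.0, note="no variation in states")
    stat, df = 0.0, 0
    low_expected = False
    for _, sub in frame.groupby("mid"):
        tab = pd.crosstab(sub["prev"], sub["next"]).to_numpy(dtype=float)
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        if (expected < 5).any():
            low_expected = True
        stat += float(((tab - expected) ** 2 / expected).sum())
        df += (tab.shape[0] - 1) * (tab.shape[1] - 1)
    if df == 0:
        return ChiSquareResult(0.0, 0, 1.0, note="no variation in states")
    note = ""
    if low_expected:
        note = "expected cell counts < 5; chi-square approximation is rough"
        warnings.warn(note, stacklevel=2)
    return ChiSquareResult(stat, df, float(stats.chi2.sf(stat, df)), note)


def time_homogeneity_test(seqs: Sequence[StateSequence]) -> ChiSquareResult:
    """Pearson chi-square of the state x time-window sample contingency."""
    rows = [(w, s) for q in seqs for (w, s) in q.steps]
    frame = pd.DataFrame(rows, columns=["window", "state"])
    if frame["window"].nunique() < 2:
        raise ValidationError("need samples in at least two time windows")
    tab = pd.crosstab(frame["state"], frame["window"])
    stat, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def transition_edge_list(seqs: Sequence[StateSequence]) -> pd.DataFrame:
    """Sankey-ready edge list: (source state, target state, window, count)."""
    rows = []
    for q in seqs:
        for (w1, s1), (w2, s2) in zip(q.steps[:-1], q.steps[1:]):
            rows.append({"source": s1, "target": s2, "window": w1})
    if not rows:
        return pd.DataFrame(columns=["source", "target", "window", "count"])
    frame = pd.DataFrame(rows)
    return (
        frame.groupby(["source", "target", "window"])
        .size()
        .rename("count")
        .reset_index()
    )


__all__ = [
    "ChainProperties",
    "ChiSquareResult",
    "MarkovModel",
    "StateSequence",
    "build_sequences",
    "chain_properties",
    "fit_markov",
    "memorylessness_test",
    "simulate_chain",
    "time_homogeneity_test",
    "transition_edge_list",
]
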