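"""Alpha diversity (Hill numbers), beta diversity, and PERMANOVA.

Alpha diversity is reported as Hill numbers H_q, the effective species
counts of increasing order q: H_0 richness, H_1 = exp(Shannon),
H_2 = inverse Simpson, H_inf = 1/max p_i (inverse Berger-Parker).
They satisfy H_0 >= H_1 >= H_2 >= H_inf >= 1 for any non-empty sample.

Beta diversity offers Bray-Curtis, Sorensen (Bray-Curtis on
presence/absence) and Morisita-Horn (scale-invariant abundance overlap).
Group separation on a dissimilarity matrix is tested with one-factor
PERMANOVA (pseudo-F under label permutation), with pairwise contrasts
corrected by Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

METRICS = ("bray_curtis", "sorensen", "morisita_horn")


@dataclass
class AlphaDiversity:
    sample_id: str
    H0: float
    H1: float
    H2: float
    Hinf: float

    @property
    def dominance(self) -> float:
        return 1.0 / self.Hinf


def hill_numbers(p: np.ndarray, sample_id: str = "") -> AlphaDiversity:
    """Hill numbers of a relative-abundance vector.

    H_0 = #{p_i > 0};  H_1 = exp(-sum p_i ln p_i);  H_2 = 1 / sum p_i^2;
    H_inf = 1 / max p_i.  Inputs off the simplex by <= 1e-6 are
    renormalized with a warning.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValidationError("all-zero abundance vector")
    if abs(total - 1.0) > 1e-9:
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"vector sums to {total:.6g}, not a simplex")
        warnings.warn("renormalizing abundance vector", stacklevel=2)
    p = p / total
    pos = p[p > 0]
    return AlphaDiversity(
        sample_id=sample_id,
        H0=float(len(pos)),
        H1=float(np.exp(-(pos * np.log(pos)).sum())),
        H2=float(1.0 / (pos**2).sum()),
        Hinf=float(1.0 / pos.max()),
    )


def renyi_diversity(p: np.ndarray, q: float) -> float:
    """Hill number of arbitrary order q (generic; q in {0,1,2,inf} is the
    tested set)."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    pos = p[p > 0]
    if math.isinf(q):
        return float(1.0 / pos.max())
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-(pos * np.log(pos)).sum()))
    return float((pos**q).sum() ** (1.0 / (1.0 - q)))


def alpha_table(values: pd.DataFrame) -> pd.DataFrame:
    """Hill numbers per row of a samples x OTUs abundance frame."""
    rows = []
    for sid, row in values.iterrows():
        a = hill_numbers(row.to_numpy(), sample_id=str(sid))
        rows.append(
            {
                "sample_id": a.sample_id,
                "H0": a.H0,
                "H1": a.H1,
                "H2": a.H2,
                "Hinf": a.Hinf,
                "dominance": a.dominance,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    sample_ids: list[str]
    D: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity diagonal must be zero")
        if (D < -1e-12).any() or (D > 1 + 1e-9).any():
            raise ValidationError("dissimilarities must lie in [0, 1]")
        self.D = np.clip(D, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.sample_ids, columns=self.sample_ids)


def _bray_curtis(X: np.ndarray) -> np.ndarray:
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / den, 0.0)
    return D


def _morisita_horn(X: np.ndarray) -> np.ndarray:
    totals = X.sum(axis=1)
    d = (X**2).sum(axis=1) / totals**2  # Simpson index per sample
    cross = X @ X.T
    den = (d[:, None] + d[None, :]) * totals[:, None] * totals[None, :]
    D = 1.0 - 2.0 * cross / den
    np.fill_diagonal(D, 0.0)
    return D


def beta_matrix(values, metric: str = "bray_curtis") -> DissimilarityMatrix:
    """Pairwise dissimilarities between sample rows.

    bray_curtis(x, y) = sum|x-y| / sum(x+y);  sorensen applies the same
    to presence/absence indicators;  morisita_horn(x, y) =
    1 - 2 sum x_i y_i / ((d_x + d_y) X Y) with X = sum x, Y = sum y and
    d the per-sample Simpson concentration.
    """
    if hasattr(values, "counts"):
        frame = values.counts
    elif hasattr(values, "values") and isinstance(values.values, pd.DataFrame):
        frame = values.values
    else:
        frame = pd.DataFrame(values)
    if len(frame) < 2:
        raise ValidationError("need at least two samples")
    X = frame.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = frame.index[np.where(totals == 0)[0][0]]
        raise ValidationError(f"sample {bad!r} has zero total abundance")
    if metric == "bray_curtis":
        D = _bray_curtis(X)
    elif metric == "sorensen":
        D = _bray_curtis((X > 0).astype(float))
    elif metric == "morisita_horn":
        D = _morisita_horn(X)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix([str(s) for s in frame.index], D, metric)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int] = field(default_factory=dict)


def _ss_terms(D2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = len(codes)
    ss_total = D2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = np.where(codes == g)[0]
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_total, ss_within


def _pseudo_f_batch(D2: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """pseudo-F for each row of a (B, n) batch of label codes."""
    B, n = codes.shape
    ss_total = D2.sum() / (2.0 * n)
    ss_within = np.zeros(B)
    for g in range(k):
        M = (codes == g).astype(float)
        ng = M.sum(axis=1)
        ss_within += np.einsum("bi,ij,bj->b", M, D2, M) / (2.0 * ng)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dm: DissimilarityMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    pseudo-F = ((SS_total - SS_within)/(k-1)) / (SS_within/(n-k)) with
    SS built from squared dissimilarities.  The Monte-Carlo p-value uses
    the +1-corrected estimator p = (1 + #{F_perm >= F_obs}) / (n_perm + 1);
    ``exact=True`` instead enumerates every label permutation (feasible
    for small n) and reports the exact tail fraction.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != len(dm.sample_ids):
        raise ValidationError("group labels do not match sample count")
    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValidationError("need at least two groups")
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    if min(sizes.values()) < 2:
        small = min(sizes, key=sizes.get)
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    n = len(codes)
    D2 = dm.D**2
    ss_total, ss_within = _ss_terms(D2, codes, k)
    f_obs = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
    r2 = 1.0 - ss_within / ss_total

    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        f_perm = _pseudo_f_batch(D2, codes[perms], k)
        p = float((f_perm >= f_obs - 1e-12).mean())
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perm_codes = np.empty((n_perm, n), dtype=codes.dtype)
        for b in range(n_perm):
            perm_codes[b] = rng.permutation(codes)
        f_perm = _pseudo_f_batch(D2, perm_codes, k)
        p = (1.0 + float((f_perm >= f_obs - 1e-12).sum())) / (n_perm + 1.0)
        n_used = n_perm
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=float(p),
        n_permutations=n_used,
        group_sizes=sizes,
    )


def pairwise_permanova(
    dm: DissimilarityMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA for every unordered group pair with BH-adjusted p-values."""
    groups = np.asarray([str(g) for g in groups])
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least two groups")
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(labels, 2)):
        mask = (groups == a) | (groups == b)
        idx = np.where(mask)[0]
        sub = DissimilarityMatrix(
            [dm.sample_ids[j] for j in idx], dm.D[np.ix_(idx, idx)], dm.metric
        )
        res = permanova(sub, groups[idx], n_perm=n_perm, seed=seed + i)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": res.pseudo_F,
                "R2": res.R2,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


__all__ = [
    "METRICS",
    "AlphaDiversity",
    "DissimilarityMatrix",
    "PermanovaResult",
    "alpha_table",
    "beta_matrix",
    "hill_numbers",
    "pairwise_permanova",
    "permanova",
    "renyi_diversity",
]
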