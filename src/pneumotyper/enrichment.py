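"""Differential taxon incidence/abundance via aligned rank transform ANOVA.

Each community state is contrasted against the remaining states
combined in a two-factor layout (group = target vs rest, taxon = OTU
identity) on log10(absolute abundance + 1).  The aligned rank transform
(ART) makes factorial ANOVA applicable to such non-normal responses:
for every effect the responses are first *aligned* (all other estimated
effects subtracted), then ranked, then submitted to ordinary factorial
ANOVA, keeping only the F-test of the effect the data were aligned for.

Per-OTU post hoc contrasts are differences in mean ranks between the
target and rest groups within each taxon, with a normal approximation
and Benjamini-Hochberg correction across taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix
from .core_io import ValidationError

EFFECTS = ("A", "B", "A:B")


@dataclass
class ARTResult:
    effect: str
    aligned: np.ndarray
    ranks: np.ndarray
    F: float
    df: tuple[int, int]
    p: float


@dataclass
class EnrichmentRecord:
    otu_id: str
    state: str
    estimate: float  # difference of mean ranks, target - rest
    raw_p: float
    adj_p: float = np.nan
    direction: str = ""
    incidence_target_pct: float = np.nan
    incidence_rest_pct: float = np.nan


def _codes(x) -> tuple[np.ndarray, int]:
    _, codes = np.unique(np.asarray(x), return_inverse=True)
    return codes, codes.max() + 1


def _cell_stats(y, ai, bj, a, b):
    """Cell means and unweighted (means-of-cell-means) marginals."""
    sums = np.zeros((a, b))
    cnt = np.zeros((a, b))
    np.add.at(sums, (ai, bj), y)
    np.add.at(cnt, (ai, bj), 1.0)
    if (cnt == 0).any():
        i, j = np.argwhere(cnt == 0)[0]
        raise ValidationError(f"empty design cell (A level {i}, B level {j})")
    mu_ij = sums / cnt
    mu_i = mu_ij.mean(axis=1)
    mu_j = mu_ij.mean(axis=0)
    mu = mu_ij.mean()
    return mu_ij, mu_i, mu_j, mu


def art_transform(y, A, B) -> dict[str, np.ndarray]:
    """Aligned responses for each effect of a two-factor layout.

    With mu the grand mean, mu_i / mu_j unweighted marginal means and
    mu_ij cell means:
        Y'_A  = y - mu_ij + mu_i
        Y'_B  = y - mu_ij + mu_j
        Y'_AB = y - mu_i - mu_j + mu
    Marginal and grand means are means of cell means, so the alignment
    strips the other effects exactly in complete proportional layouts.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("response contains non-finite values")
    ai, a = _codes(A)
    bj, b = _codes(B)
    if len(y) != len(ai) or len(y) != len(bj):
        raise ValidationError("response/factor length mismatch")
    mu_ij, mu_i, mu_j, mu = _cell_stats(y, ai, bj, a, b)
    return {
        "A": y - mu_ij[ai, bj] + mu_i[ai],
        "B": y - mu_ij[ai, bj] + mu_j[bj],
        "A:B": y - mu_i[ai] - mu_j[bj] + mu,
    }


def _dummies(codes: np.ndarray, k: int) -> np.ndarray:
    """Drop-first treatment dummies."""
    out = np.zeros((len(codes), k - 1))
    for lev in range(1, k):
        out[codes == lev, lev - 1] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(((y - fitted) ** 2).sum())


def two_way_anova(y, A, B) -> dict[str, tuple[float, tuple[int, int], float]]:
    """Type-II factorial ANOVA: effect -> (F, (df1, df2), p).

    SS_A = RSS(B) - RSS(A+B), SS_B = RSS(A) - RSS(A+B),
    SS_AB = RSS(A+B) - RSS(full); the error term is the full-model
    residual mean square.
    """
    y = np.asarray(y, dtype=float)
    ai, a = _codes(A)
    bj, b = _codes(B)
    n = len(y)
    one = np.ones((n, 1))
    Xa = _dummies(ai, a)
    Xb = _dummies(bj, b)
    Xab = np.einsum("ni,nj->nij", Xa, Xb).reshape(n, -1)
    rss_a = _rss(np.hstack([one, Xa]), y)
    rss_b = _rss(np.hstack([one, Xb]), y)
    rss_ab_main = _rss(np.hstack([one, Xa, Xb]), y)
    rss_full = _rss(np.hstack([one, Xa, Xb, Xab]), y)
    df_err = n - a * b
    if df_err <= 0:
        raise ValidationError("no residual degrees of freedom (one obs per cell)")
    mse = rss_full / df_err
    # numerical floor relative to the total variation
    tol = 1e-10 * max(1.0, float(((y - y.mean()) ** 2).sum()))
    out = {}
    for effect, ss, df1 in (
        ("A", rss_b - rss_ab_main, a - 1),
        ("B", rss_a - rss_ab_main, b - 1),
        ("A:B", rss_ab_main - rss_full, (a - 1) * (b - 1)),
    ):
        ss = 0.0 if ss <= tol else ss
        if mse <= tol:
            f = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = (ss / df1) / mse
            p = float(stats.f.sf(f, df1, df_err))
        out[effect] = (float(f), (df1, df_err), p)
    return out


def art_anova(y, A, B) -> list[ARTResult]:
    """Full ART procedure: align per effect, rank, factorial F-test."""
    aligned = art_transform(y, A, B)
    results = []
    for effect in EFFECTS:
        vals = aligned[effect]
        # collapse float dust so exactly-aligned responses tie cleanly
        scale = max(float(np.abs(vals).max()), 1.0)
        ranks = stats.rankdata(np.round(vals / scale, 10), method="average")
        f, df, p = two_way_anova(ranks, A, B)[effect]
        results.append(
            ARTResult(effect=effect, aligned=aligned[effect], ranks=ranks,
                      F=f, df=df, p=p)
        )
    return results


def rank_contrasts(y, A, B, target) -> pd.DataFrame:
    """Per-B-level rank contrast of target group vs rest.

    Responses are ranked globally (average ties); within each taxon
    stratum the difference in mean rank between target and rest is
    compared to its permutation variance under within-stratum
    exchangeability, using a normal approximation.
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray([str(x) for x in A])
    B = np.asarray([str(x) for x in B])
    ranks = stats.rankdata(y, method="average")
    rows = []
    for lev in pd.unique(B):
        m = B == lev
        in_t = m & (A == str(target))
        in_r = m & (A != str(target))
        n1, n2 = int(in_t.sum()), int(in_r.sum())
        if n1 < 2 or n2 < 2:
            raise ValidationError(f"taxon {lev!r} lacks samples in a group")
        est = ranks[in_t].mean() - ranks[in_r].mean()
        s2 = ranks[m].var(ddof=1)
        var = s2 * (1.0 / n1 + 1.0 / n2)
        if var == 0:
            z, p = 0.0, 1.0
        else:
            z = est / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"otu_id": lev, "estimate": est, "z": z, "raw_p": p})
    return pd.DataFrame(rows)


def pneumotype_enrichment(
    absolute: AbundanceMatrix,
    labels: pd.Series,
    target,
    n_top: int = 30,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Enrichment of the dominant taxa in one state vs the rest combined.

    Restricted to the ``n_top`` taxa with the largest summed absolute
    abundance; the response is log10(absolute abundance + 1) — the
    rank-based inference is invariant to this monotone choice.
    """
    if absolute.mode != "absolute":
        raise ValidationError("enrichment expects absolute abundances")
    labels = labels.reindex(absolute.sample_ids)
    if labels.isna().any():
        raise ValidationError("labels missing for some samples")
    target = str(target)
    lab = labels.astype(str)
    if target not in set(lab):
        raise ValidationError(f"state {target!r} absent from labels")
    totals = absolute.values.sum(axis=0).sort_values(ascending=False)
    top = list(totals.index[:n_top])
    sub = absolute.values[top]
    y = np.log10(sub.to_numpy(dtype=float) + 1.0).ravel()
    A = np.repeat(np.where(lab.to_numpy() == target, "target", "rest"), len(top))
    B = np.tile(np.asarray(top, dtype=object), len(sub))
    contrasts = rank_contrasts(y, A, B, "target")
    contrasts["adj_p"] = multipletests(contrasts["raw_p"], method="fdr_bh")[1]

    present = sub.to_numpy() > 0
    is_t = (lab.to_numpy() == target)
    inc_t = present[is_t].mean(axis=0) * 100.0
    inc_r = present[~is_t].mean(axis=0) * 100.0
    inc = dict(zip(top, zip(inc_t, inc_r)))

    records = []
    for _, row in contrasts.iterrows():
        it, ir = inc[row["otu_id"]]
        records.append(
            EnrichmentRecord(
                otu_id=str(row["otu_id"]),
                state=target,
                estimate=float(row["estimate"]),
                raw_p=float(row["raw_p"]),
                adj_p=float(row["adj_p"]),
                direction="enriched" if row["estimate"] > 0 else "depleted",
                incidence_target_pct=float(it),
                incidence_rest_pct=float(ir),
            )
        )
    records.sort(key=lambda r: (r.adj_p, -abs(r.estimate), r.otu_id))
    return records


def enrichment_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": [r.otu_id for r in records],
            "state": [r.state for r in records],
            "estimate": [r.estimate for r in records],
            "raw_p": [r.raw_p for r in records],
            "adj_p": [r.adj_p for r in records],
            "direction": [r.direction for r in records],
            "incidence_target_pct": [r.incidence_target_pct for r in records],
            "incidence_rest_pct": [r.incidence_rest_pct for r in records],
        }
    )


__all__ = [
    "ARTResult",
    "EnrichmentRecord",
    "art_anova",
    "art_transform",
    "enrichment_frame",
    "pneumotype_enrichment",
    "rank_contrasts",
    "two_way_anova",
]
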