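"""The statistical layer of the integration analysis.

Covers: hypergeometric over-enrichment of gene-set overlaps, Mann-Whitney
U rank tests (exact by enumeration at small n, normal approximation with
tie and continuity corrections otherwise), the one-degree Pearson
chi-square for up/down asymmetry among deregulated genes, Bonferroni
correction with a caller-fixed family size, two-factor additive ANCOVA
with estimated marginal means on the fpkm scale, DE-table threshold
filtering, and responsiveness-by-category summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import UsageError

__all__ = [
    "OverlapEnrichment",
    "EMMResult",
    "hypergeometric_enrichment",
    "mann_whitney",
    "chisq_updown",
    "bonferroni",
    "ancova_emm",
    "de_filter",
    "responsiveness_by_category",
]


@dataclass(frozen=True)
class OverlapEnrichment:
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    expected: float
    fold: float
    p_value: float


@dataclass(frozen=True)
class EMMResult:
    factor: str  # {h2aub, k27}
    level: str  # {absent, present}
    emm: float
    se: float


def hypergeometric_enrichment(
    set_a: set, set_b: set, universe: set
) -> OverlapEnrichment:
    """Fold enrichment and upper-tail hypergeometric p of a set overlap.

    Expected overlap under chance = |A|·|B|/N; fold = observed/expected;
    p = P[X >= observed] for X ~ Hypergeom(N, |A|, |B|).
    """
    if not universe:
        raise UsageError("empty universe")
    if not set_a or not set_b:
        raise UsageError("fold enrichment undefined for an empty gene set")
    if not (set_a <= universe and set_b <= universe):
        raise UsageError("sets must be subsets of the universe")
    N, na, nb = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    expected = na * nb / N
    p = float(sps.hypergeom.sf(k - 1, N, na, nb))
    return OverlapEnrichment(N, na, nb, k, expected, k / expected, p)


def _mw_exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled
    sample to the two groups (tie-free inputs)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    total = math.comb(len(pooled), n1)
    le = ge = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided).

    U is computed with midrank tie handling and reported for ``x``.
    The p-value is exact (full labeling enumeration) when the pooled
    sample has <= 12 observations and no ties; otherwise the normal
    approximation with continuity and tie corrections is used.
    """
    if alternative != "two-sided":
        raise UsageError("only the two-sided alternative is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise UsageError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n2 = len(x), len(y)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    tie_free = len(np.unique(pooled)) == len(pooled)
    if n1 + n2 <= 12 and tie_free:
        return u, _mw_exact_p(x, y, u)
    if np.ptp(pooled) == 0:
        return u, 1.0
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def chisq_updown(n_up: int, n_down: int) -> tuple[float, float]:
    """Pearson chi-square (1 df) of an up/down split against equality."""
    total = n_up + n_down
    if total <= 0:
        raise UsageError("need at least one deregulated gene")
    e = total / 2
    chi2 = (n_up - e) ** 2 / e + (n_down - e) ** 2 / e
    return float(chi2), float(sps.chi2.sf(chi2, 1))


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment with a fixed family size m: min(1, p·m)."""
    if m < 1:
        raise UsageError("family size m must be >= 1")
    return [min(1.0, float(p) * m) for p in p_values]


_CELLS = ((0, 0), (1, 0), (0, 1), (1, 1))


def ancova_emm(
    expression: Mapping[str, float],
    h2aub: Mapping[str, bool],
    k27: Mapping[str, bool],
    bonferroni_m: int = 6,
) -> tuple[list[EMMResult], pd.DataFrame]:
    """Additive two-factor model of expression with estimated marginal means.

    Fits ``expression ~ h2aub + k27`` (no interaction) by OLS on the
    fpkm scale. The EMM of a factor level is the model prediction
    averaged with equal weight over both levels of the other factor.
    Post-hoc pairwise contrasts between the four cells are t-tests on
    the model coefficients, Bonferroni-corrected with family size
    ``bonferroni_m``.
    """
    genes = sorted(expression)
    df = pd.DataFrame(
        {
            "expr": [expression[g] for g in genes],
            "h2aub": [int(h2aub[g]) for g in genes],
            "k27": [int(k27[g]) for g in genes],
        }
    )
    counts = df.groupby(["h2aub", "k27"]).size()
    if len(counts) < 4:
        warnings.warn(
            "empty design cell(s): EMMs computed from the available cells"
        )
    X = sm.add_constant(df[["h2aub", "k27"]].to_numpy(dtype=float), has_constant="add")
    model = sm.OLS(df["expr"].to_numpy(), X).fit()

    def cell_vec(h, k):
        return np.array([1.0, h, k])

    emms = []
    for factor, col in (("h2aub", 1), ("k27", 2)):
        for level_val, level in ((0, "absent"), (1, "present")):
            vecs = []
            for other in (0, 1):
                v = [1.0, 0.0, 0.0]
                v[col] = level_val
                v[2 if col == 1 else 1] = other
                vecs.append(v)
            L = np.mean(vecs, axis=0)
            emm = float(L @ model.params)
            se = float(np.sqrt(L @ model.cov_params() @ L))
            emms.append(EMMResult(factor, level, emm, se))

    rows = []
    raw_ps = []
    for (h1, k1), (h2, k2) in combinations(_CELLS, 2):
        L = cell_vec(h1, k1) - cell_vec(h2, k2)
        tt = model.t_test(L)
        raw_ps.append(float(tt.pvalue))
        rows.append(
            {
                "cell_1": f"h2aub={h1},k27={k1}",
                "cell_2": f"h2aub={h2},k27={k2}",
                "estimate": float(tt.effect[0]),
                "p_raw": float(tt.pvalue),
            }
        )
    contrasts = pd.DataFrame(rows)
    contrasts["p_adj"] = bonferroni(raw_ps, bonferroni_m)
    return emms, contrasts


def de_filter(
    records: pd.DataFrame,
    lfc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Significantly up/down gene sets from a DE table.

    Expects columns ``gene_id``, ``log2FC``, ``p_adj`` and optionally
    ``cpm_pass`` (rows failing the expression filter are excluded).
    """
    if lfc_cutoff <= 0:
        raise UsageError("lfc_cutoff must be > 0")
    df = records
    if "cpm_pass" in df.columns:
        df = df[df["cpm_pass"].astype(bool)]
    sig = df[df["p_adj"] < p_cutoff]
    up = set(sig.loc[sig["log2FC"] >= lfc_cutoff, "gene_id"])
    down = set(sig.loc[sig["log2FC"] <= -lfc_cutoff, "gene_id"])
    return up, down


def responsiveness_by_category(
    scores: Mapping[str, float],
    table: pd.DataFrame,
    bonferroni_m: int = 6,
) -> dict:
    """Responsiveness medians per mark category, with pairwise tests.

    Genes without a score are excluded; categories with < 2 scored genes
    are skipped with a warning. Also reports the H2Aub1 and H3K27me3
    presence/absence splits with their Mann-Whitney p-values
    (Bonferroni-adjusted with family size ``bonferroni_m``).
    """
    common = [g for g in table.index if g in scores]
    sub = table.loc[common].copy()
    sub["score"] = [scores[g] for g in common]

    medians = {}
    groups = {}
    for cat, grp in sub.groupby("category"):
        if len(grp) < 2:
            warnings.warn(f"category {cat!r} has < 2 scored genes; excluded")
            continue
        groups[cat] = grp["score"].to_numpy()
        medians[cat] = float(grp["score"].median())

    pairs = []
    raw_ps = []
    for a, b in combinations(sorted(groups), 2):
        _, p = mann_whitney(groups[a], groups[b])
        pairs.append({"cat_1": a, "cat_2": b, "p_raw": p})
        raw_ps.append(p)
    adj = bonferroni(raw_ps, bonferroni_m) if raw_ps else []
    for row, p in zip(pairs, adj):
        row["p_adj"] = p

    mark_split = {}
    for mark in ("h2aub", "k27"):
        pres = sub.loc[sub[mark].astype(bool), "score"].to_numpy()
        absent = sub.loc[~sub[mark].astype(bool), "score"].to_numpy()
        if len(pres) and len(absent):
            _, p = mann_whitney(pres, absent)
            mark_split[mark] = {
                "median_present": float(np.median(pres)),
                "median_absent": float(np.median(absent)),
                "p": p,
            }
    return {"medians": medians, "pairwise": pairs, "mark_split": mark_split}
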