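"""CRISPR screen count normalization and rank-based gene scoring.

Guide counts are depth-normalized (counts + 1 → counts per million),
converted to per-guide log2 fold changes against the control sample, and
genes are scored with a binomial rank-walk statistic: walking a gene's
guides down the ranked guide list, the j-th gene guide found at overall
rank r contributes the binomial tail P(X ≥ j), X ~ Binomial(m, r/N); the
gene score is −log10 of the best (smallest) such tail among guides inside
a top-percentile window. A false-discovery rate comes from permuting the
guide→gene assignment.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_cpm",
    "guide_lfc",
    "stars_score",
    "stars_fdr",
]


def normalize_cpm(counts: pd.DataFrame, sample_cols: Sequence[str] | None = None) -> pd.DataFrame:
    """Counts-per-million after a +1 pseudocount.

    cpm[g, s] = 1e6 · (counts[g, s] + 1) / Σ_g (counts[g, s] + 1); every
    sample column sums to exactly 1e6.
    """
    out = counts.copy()
    if sample_cols is None:
        sample_cols = [
            c for c in counts.columns
            if c not in ("sgRNA", "gene") and np.issubdtype(counts[c].dtype, np.number)
        ]
    for col in sample_cols:
        plus = counts[col].to_numpy(dtype=float) + 1.0
        total = plus.sum()
        if total <= 0:
            raise ValueError(f"sample {col!r} has non-positive total")
        out[col] = 1e6 * plus / total
    return out


def guide_lfc(
    cpm_treatment: pd.Series | Mapping[str, float],
    cpm_control: pd.Series | Mapping[str, float],
) -> pd.Series:
    """Per-guide log2 fold change of treatment CPM over control CPM."""
    trt = pd.Series(cpm_treatment, dtype=float)
    ctl = pd.Series(cpm_control, dtype=float)
    only = trt.index.symmetric_difference(ctl.index)
    if len(only):
        raise ValueError(f"guides present in only one table: {list(only[:5])}")
    return np.log2(trt) - np.log2(ctl.reindex(trt.index))


def _rank_guides(lfc: pd.Series, direction: str) -> pd.Series:
    """Deterministic 1-based ranks, best first; tied fold changes share
    their midrank so exchangeable inputs cannot separate genes, and the
    walk order among ties is fixed by guide label."""
    sign = -1.0 if direction == "positive" else 1.0
    order = sorted(lfc.index, key=lambda g: (sign * lfc[g], str(g)))
    mid = stats.rankdata(sign * lfc.loc[order].to_numpy(), method="average")
    return pd.Series(mid, index=order)


def _score_genes(
    ranks: pd.Series,
    gene_of: pd.Series,
    thr_percent: float,
) -> pd.Series:
    n = len(ranks)
    window = thr_percent * n / 100.0
    guides_by_gene: dict[str, list[float]] = {}
    for guide, r in ranks.items():
        guides_by_gene.setdefault(gene_of[guide], []).append(float(r))
    scores = {}
    for gene, rs in guides_by_gene.items():
        m = len(rs)
        if m < 2:
            continue
        rs = sorted(rs)
        best = None
        for j, r in enumerate(rs, start=1):
            if r > window:
                break
            p = stats.binom.sf(j - 1, m, r / n)
            if best is None or p < best:
                best = p
        if best is not None:
            scores[gene] = -np.log10(max(best, 1e-300))
    return pd.Series(scores, dtype=float)


def stars_score(
    lfc: pd.Series,
    gene_map: Mapping[str, str] | pd.Series,
    thr_percent: float = 10.0,
    direction: str = "positive",
) -> pd.DataFrame:
    """Binomial rank-walk gene scores from per-guide log2 fold changes.

    Only guides ranked within the top ``thr_percent`` of the list
    contribute; genes with no guide in the window (or fewer than two guides
    overall) are unscored. ``direction='positive'`` ranks enrichment
    (largest lfc first); depletion is scored by negating lfc.
    """
    if len(lfc) == 0:
        raise ValueError("empty lfc input")
    gene_of = pd.Series(gene_map)
    ranks = _rank_guides(lfc, direction)
    scores = _score_genes(ranks, gene_of, thr_percent)
    n_guides = gene_of.groupby(gene_of).size()
    out = pd.DataFrame({"gene": scores.index, "score": scores.to_numpy()})
    out["n_guides_used"] = out["gene"].map(n_guides).astype(int)
    return out.sort_values(["score", "gene"], ascending=[False, True]).reset_index(drop=True)


def stars_fdr(
    lfc: pd.Series,
    gene_map: Mapping[str, str] | pd.Series,
    thr_percent: float = 10.0,
    direction: str = "positive",
    b: int = 1000,
    seed: int = 0,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Gene scores with a permutation false-discovery rate.

    The guide→gene assignment is permuted ``b`` times and genes rescored;
    FDR(s) = (average number of null genes scoring ≥ s) / (number of
    observed genes scoring ≥ s), clipped to [0, 1] and monotonized by a
    running minimum from the top score downward. Hits are fdr < 0.05.
    """
    if b < 100:
        warnings.warn("b < 100 permutations gives an unstable FDR estimate")
    gene_of = pd.Series(gene_map)
    observed = stars_score(lfc, gene_of, thr_percent, direction)
    obs_scores = observed["score"].to_numpy()  # descending

    rng = np.random.default_rng(seed)
    ranks = _rank_guides(lfc, direction)
    guides = gene_of.index.to_numpy()
    agg = np.mean if aggregate == "mean" else np.median
    null_ge: list[np.ndarray] = []
    for _ in range(b):
        perm = pd.Series(gene_of.to_numpy()[rng.permutation(len(guides))], index=guides)
        null_scores = _score_genes(ranks, perm, thr_percent).to_numpy()
        # for each observed score, count null genes scoring >= it
        if len(null_scores):
            ns = np.sort(null_scores)
            cnt = len(ns) - np.searchsorted(ns, obs_scores, side="left")
        else:
            cnt = np.zeros(len(obs_scores))
        null_ge.append(np.asarray(cnt, dtype=float))
    null_mat = np.vstack(null_ge) if null_ge else np.zeros((1, len(obs_scores)))
    mean_null = agg(null_mat, axis=0)
    n_obs_ge = np.arange(1, len(obs_scores) + 1, dtype=float)
    # ties: all genes at the same score share the same numerator/denominator
    for i in range(len(obs_scores) - 2, -1, -1):
        if obs_scores[i] == obs_scores[i + 1]:
            n_obs_ge[i] = n_obs_ge[i + 1]
    fdr = np.clip(mean_null / n_obs_ge, 0.0, 1.0)
    # step-up coherence: each gene gets the best rate achievable at or below
    # its score, making fdr non-decreasing down the ranking
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    out = observed.copy()
    out["fdr"] = fdr
    out["hit"] = out["fdr"] < 0.05
    out["rank"] = np.arange(1, len(out) + 1)
    return out
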