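"""Metascore gene ranking and weighted preranked gene-set enrichment.

The metascore is a conservative evidence combination for differential
expression: per gene, three percentile scores (|log2FC|, baseMean and
1 − p, each oriented so larger = stronger) are computed across the table
and the gene's score magnitude is the *worst* (minimum) of the three,
signed by the direction of its fold change. Preranked GSEA then runs the
classical weighted Kolmogorov–Smirnov-like running sum over the ranked
list, with a gene-set-sampling null, mean-division NES normalization and
leading-edge extraction.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedGeneList",
    "GseaResult",
    "metascore_rank",
    "read_gmt",
    "enrichment_score",
    "gsea_preranked",
]


@dataclasses.dataclass
class RankedGeneList:
    """Genes ordered best-to-worst with non-increasing signed scores."""

    genes: list[str]
    scores: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")


@dataclasses.dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    n_matched: int
    leading_edge: list[str]


def metascore_rank(diff_table: pd.DataFrame) -> RankedGeneList:
    """Rank genes by the worst of three oriented evidence percentiles.

    Expects columns (gene|entity, log2fc, baseMean, pvalue). Each evidence
    axis is converted to a percentile in (0, 1] (larger = stronger:
    |log2FC|, baseMean, 1 − p); the metascore magnitude is the minimum of
    the three and its sign is the sign of log2FC, yielding a signed total
    order from strongest up- to strongest downregulation.
    """
    id_col = next(
        (c for c in ("gene", "entity", "protein") if c in diff_table.columns),
        diff_table.columns[0],
    )
    genes = diff_table[id_col].astype(str)
    if genes.duplicated().any():
        raise ValueError("duplicate gene labels in differential table")
    p_col = "pvalue" if "pvalue" in diff_table.columns else "p"
    n = len(diff_table)

    def pctl(values: np.ndarray) -> np.ndarray:
        return stats.rankdata(values, method="average") / n

    s_lfc = pctl(diff_table["log2fc"].abs().to_numpy())
    s_base = pctl(diff_table["baseMean"].to_numpy())
    s_p = pctl(1.0 - diff_table[p_col].to_numpy())
    magnitude = np.minimum(np.minimum(s_lfc, s_base), s_p)
    signed = magnitude * np.sign(diff_table["log2fc"].to_numpy())

    order = np.lexsort((genes.to_numpy(), -signed))
    return RankedGeneList(
        genes=[genes.iloc[i] for i in order],
        scores=signed[order],
        provenance="metascore: min of oriented percentiles of |log2fc|, baseMean, 1-p; "
        "sign from log2fc",
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members…)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def enrichment_score(
    scores: np.ndarray,
    hit_mask: np.ndarray,
    weight: float = 1.0,
) -> tuple[float, int]:
    """Weighted running-sum enrichment score and the extremum position.

    Hits increment by |score|^weight normalized to the set total; misses
    decrement by 1/(N − set size). ES is the running-sum value of largest
    magnitude (positive extremum if it dominates, else negative).
    """
    n = len(scores)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set matches none or all of the ranked list")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all matched scores are zero: fall back to unweighted increments
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask) / (n - n_hit)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def _match_mask(genes: Sequence[str], members: Sequence[str]) -> np.ndarray:
    member_set = set(members)
    return np.fromiter((g in member_set for g in genes), dtype=bool, count=len(genes))


def gsea_preranked(
    ranked: RankedGeneList,
    gene_sets: Mapping[str, Sequence[str]],
    nperm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> list[GseaResult]:
    """Preranked GSEA with a gene-set-sampling null and meandiv NES.

    For each set, ``nperm`` random same-size gene sets are drawn from the
    ranked list; NES = ES / mean(same-sign null ES magnitudes); the nominal
    p compares ES against the same-sign null pool and the FDR compares NES
    against the pooled null NES across all sets (same-sign proportions).
    Leading edge: members at/before the positive extremum or at/after the
    negative one.
    """
    if len(ranked.genes) == 0:
        raise ValueError("empty ranked list")
    genes = ranked.genes
    scores = ranked.scores
    n = len(genes)
    rng = np.random.default_rng(seed)

    prepared = []
    for name, members in gene_sets.items():
        mask = _match_mask(genes, members)
        size = int(mask.sum())
        if size < min_size or size > max_size or size == n:
            continue
        prepared.append((name, mask, size))

    results = []
    null_nes_pool: list[np.ndarray] = []
    for name, mask, size in prepared:
        es, pos = enrichment_score(scores, mask, weight)
        null_es = np.empty(nperm)
        for i in range(nperm):
            idx = rng.choice(n, size=size, replace=False)
            m = np.zeros(n, dtype=bool)
            m[idx] = True
            null_es[i], _ = enrichment_score(scores, m, weight)
        pos_null = null_es[null_es > 0]
        neg_null = null_es[null_es < 0]
        if es >= 0:
            denom = pos_null.mean() if pos_null.size else np.nan
            same = pos_null
            p = float((same >= es).sum() / same.size) if same.size else 1.0
        else:
            denom = -neg_null.mean() if neg_null.size else np.nan
            same = neg_null
            p = float((same <= es).sum() / same.size) if same.size else 1.0
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        pos_mean = pos_null.mean() if pos_null.size else np.nan
        neg_mean_abs = -neg_null.mean() if neg_null.size else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(null_es >= 0, null_es / pos_mean, null_es / neg_mean_abs)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])

        if es >= 0:
            hit_idx = np.nonzero(mask)[0]
            lead = [genes[i] for i in hit_idx if i <= pos]
        else:
            hit_idx = np.nonzero(mask)[0]
            lead = [genes[i] for i in hit_idx if i >= pos]
        results.append(
            GseaResult(
                set_name=name, es=es, nes=float(nes) if np.isfinite(nes) else np.nan,
                p=p, fdr=np.nan, n_matched=size, leading_edge=lead,
            )
        )

    if results:
        pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
        obs_nes = np.array([r.nes for r in results])
        for r in results:
            if not np.isfinite(r.nes):
                r.fdr = 1.0
                continue
            if r.nes >= 0:
                num_pool = pool[pool >= 0]
                num = (num_pool >= r.nes).mean() if num_pool.size else 1.0
                obs_pos = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
                den = (obs_pos >= r.nes).mean() if obs_pos.size else 1.0
            else:
                num_pool = pool[pool < 0]
                num = (num_pool <= r.nes).mean() if num_pool.size else 1.0
                obs_neg = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
                den = (obs_neg <= r.nes).mean() if obs_neg.size else 1.0
            r.fdr = float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0))
    return results
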