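"""Synthetic benchmark generators with recorded ground truth.

Every pipeline input — TMT melting-curve tensors, cell-painting feature
tables, interaction edge lists, sgRNA count matrices, viability plates and
differential tables — can be generated here with known truth, so each
downstream stage is testable without external downloads. All generators are
deterministic under a fixed seed and emit tidy tables plus a
:class:`SimTruth` sidecar describing which entities were perturbed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .meltcurve import TppDataset, melt_curve

__all__ = [
    "SimTruth",
    "DEFAULT_TEMPS",
    "DEFAULT_DOSE_CONCS",
    "gen_tpp",
    "gen_ppi",
    "gen_featuretable",
    "gen_crispr",
    "gen_doseresp",
    "gen_expression",
]

#: Eight-point thermal gradient (°C) used by default for melting simulations.
DEFAULT_TEMPS = (37.3, 42.7, 46.2, 49.4, 52.7, 55.9, 59.4, 62.3)

#: Eight-point half-log dilution series (μM) used by default for dose-response.
DEFAULT_DOSE_CONCS = (10.0, 3.0, 1.0, 0.3, 0.1, 0.03, 0.01, 0.003)


@dataclasses.dataclass
class SimTruth:
    """Ground-truth record emitted alongside every simulated dataset.

    ``truth`` lists every perturbed entity; entities absent from it are
    null entities by construction.
    """

    kind: str
    seed: int
    params: dict[str, Any]
    truth: dict[str, Any]

    def to_json(self, path=None, **kwargs) -> str | None:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, default=_jsonify, **kwargs)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Thermal proteome profiling
# ---------------------------------------------------------------------------

def _min_slope(tm: float, plateau: float, t_low: float, t_high: float) -> float:
    """Smallest slope parameter b such that the melting curve is ≥0.95 at
    ``t_low`` and ≤ plateau+0.05 at ``t_high`` for a protein with midpoint
    ``tm``.  Steeper (larger b) always satisfies both constraints."""
    ell = np.log(0.5 / (0.5 - plateau))
    # f(t_low) >= 0.95  <=>  b(1 - tm/t_low) + ell*tm/t_low <= log(0.05/(0.95-p))
    rhs_low = np.log(0.05 / (0.95 - plateau))
    b_low = (rhs_low - ell * tm / t_low) / (1.0 - tm / t_low)
    # f(t_high) <= p+0.05  <=>  b(1 - tm/t_high) + ell*tm/t_high >= log((0.95-p)/0.05)
    rhs_high = np.log((0.95 - plateau) / 0.05)
    b_high = (rhs_high - ell * tm / t_high) / (1.0 - tm / t_high)
    return float(max(b_low, b_high))


def gen_tpp(
    n_proteins: int = 100,
    n_shifted: int = 5,
    delta_tm: float = 3.0,
    noise_cv: float = 0.05,
    temps: Sequence[float] = DEFAULT_TEMPS,
    n_replicates: int = 2,
    psm_range: tuple[int, int] = (2, 30),
    seed: int = 0,
) -> tuple[TppDataset, SimTruth]:
    """Simulate a TMT thermal-profiling experiment.

    Vehicle curves follow a sigmoid melting model with per-protein midpoint
    Tm ~ U(45, 55) °C, plateau ~ U(0, 0.2) and a slope steep enough that the
    curve falls from ≥0.95 to ≤ plateau+0.05 across the gradient. The first
    ``n_shifted`` proteins are thermally stabilized in the treatment
    condition by ``delta_tm`` °C; all other proteins share vehicle
    parameters. Abundances carry multiplicative log-normal noise with
    coefficient of variation ``noise_cv`` at every non-reference
    temperature; the lowest-temperature (reference) measurement is
    generated exactly, so after scaling the fold-change observations carry
    independent noise of the stated CV rather than a shared reference
    error.
    """
    temps = np.asarray(temps, dtype=float)
    if not np.all(np.diff(temps) > 0):
        raise ValueError("temps must be strictly increasing")
    if n_shifted > n_proteins:
        raise ValueError("n_shifted must not exceed n_proteins")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")

    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    shifted = proteins[:n_shifted]

    tm_v = rng.uniform(45.0, 55.0, n_proteins)
    plateau = rng.uniform(0.0, 0.2, n_proteins)
    t_low, t_high = float(temps[0]), float(temps[-1])
    b = np.array(
        [
            rng.uniform(1.0, 1.3) * _min_slope(tm_v[i], plateau[i], t_low, t_high)
            for i in range(n_proteins)
        ]
    )
    ell = np.log(0.5 / (0.5 - plateau))
    a_v = tm_v * (b - ell)

    tm_t = tm_v.copy()
    tm_t[:n_shifted] += delta_tm
    if n_shifted and (tm_t[:n_shifted].max() > t_high or tm_t[:n_shifted].min() < t_low):
        warnings.warn(
            "delta_tm pushes a treated Tm outside the simulated gradient; "
            "generating anyway",
            stacklevel=2,
        )
    a_t = tm_t * (b - ell)

    base = 10.0 ** rng.uniform(4.0, 6.0, n_proteins)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    rows = []
    for cond, a_par in (("vehicle", a_v), ("treatment", a_t)):
        for rep in range(1, n_replicates + 1):
            frac = melt_curve(temps[None, :], a_par[:, None], b[:, None], plateau[:, None])
            mean = base[:, None] * frac
            if sigma > 0:
                noise = rng.lognormal(-0.5 * sigma**2, sigma, mean.shape)
                noise[:, 0] = 1.0  # reference point measured exactly
            else:
                noise = 1.0
            abund = mean * noise
            for i, prot in enumerate(proteins):
                for j, t in enumerate(temps):
                    rows.append((prot, cond, rep, t, abund[i, j]))
    data = pd.DataFrame(
        rows, columns=["protein", "condition", "replicate", "temperature", "abundance"]
    )

    psm_rows = []
    for prot in proteins:
        for cond in ("vehicle", "treatment"):
            psm_rows.append((prot, cond, int(rng.integers(psm_range[0], psm_range[1] + 1))))
    psm = pd.DataFrame(psm_rows, columns=["protein", "condition", "psm"])

    truth = {
        prot: {
            "a_vehicle": a_v[i],
            "a_treatment": a_t[i],
            "b": b[i],
            "plateau": plateau[i],
            "tm_vehicle": tm_v[i],
            "tm_treatment": tm_t[i],
            "delta_tm": tm_t[i] - tm_v[i],
        }
        for i, prot in enumerate(shifted)
    }
    sim = SimTruth(
        kind="tpp",
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "n_shifted": n_shifted,
            "delta_tm": delta_tm,
            "noise_cv": noise_cv,
            "temps": list(map(float, temps)),
            "n_replicates": n_replicates,
            "psm_range": list(psm_range),
        },
        truth=truth,
    )
    return TppDataset(data=data, psm=psm), sim


# ---------------------------------------------------------------------------
# Protein-protein interaction graphs
# ---------------------------------------------------------------------------

def gen_ppi(
    n_nodes: int = 500,
    mean_degree: float = 4.0,
    model: str = "uniform-random",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an annotated physical-interaction edge list.

    ``model`` selects uniform-random (Erdős–Rényi) or degree-heterogeneous
    (Chung–Lu with a power-law expected-degree sequence) wiring; ``complete``
    yields all pairs. Records mimic a TAB3-style table with organism 9606
    and an accepted affinity-capture evidence code so they pass the default
    interaction filter unchanged.
    """
    if mean_degree >= n_nodes:
        raise ValueError("mean_degree must be < n_nodes - 1")
    rng = np.random.default_rng(seed)
    nodes = [f"G{i:04d}" for i in range(n_nodes)]
    edges: list[tuple[str, str]] = []
    if model == "complete":
        edges = [(nodes[i], nodes[j]) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    elif model == "uniform-random":
        p = mean_degree / max(n_nodes - 1, 1)
        iu, ju = np.triu_indices(n_nodes, k=1)
        keep = rng.random(iu.size) < p
        edges = [(nodes[i], nodes[j]) for i, j in zip(iu[keep], ju[keep])]
    elif model == "degree-heterogeneous":
        w = rng.pareto(2.5, n_nodes) + 1.0
        w *= mean_degree * n_nodes / w.sum()
        s = w.sum()
        iu, ju = np.triu_indices(n_nodes, k=1)
        pij = np.minimum(w[iu] * w[ju] / s, 1.0)
        keep = rng.random(iu.size) < pij
        edges = [(nodes[i], nodes[j]) for i, j in zip(iu[keep], ju[keep])]
    else:
        raise ValueError(f"unknown model: {model!r}")

    systems = ("Affinity Capture-Western", "Co-purification", "Affinity Capture-MS")
    records = pd.DataFrame(
        {
            "Official Symbol Interactor A": [a for a, _ in edges],
            "Official Symbol Interactor B": [b for _, b in edges],
            "Organism ID Interactor A": 9606,
            "Organism ID Interactor B": 9606,
            "Experimental System": [systems[k] for k in rng.integers(0, 3, len(edges))],
            "Experimental System Type": "physical",
        }
    )
    return records


# ---------------------------------------------------------------------------
# Cell painting feature tables
# ---------------------------------------------------------------------------

def gen_featuretable(
    n_compound_wells: int = 24,
    n_dmso_wells: int = 16,
    n_features: int = 579,
    phenotype_axes: int = 3,
    effect_size: float = 8.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a wells × features morphological-profiling table.

    DMSO wells are drawn from a common per-feature Gaussian; each compound
    well is displaced along one of ``phenotype_axes`` latent unit directions
    scaled by ``effect_size`` median-absolute-deviations, so wells sharing an
    axis are mutually biosimilar by construction. The default feature count
    matches a standard image-based profiling panel (579 features).
    """
    if n_dmso_wells < 4:
        raise ValueError("need at least 4 DMSO wells")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(0.0, 3.0, n_features)
    axes = rng.normal(0.0, 1.0, (max(phenotype_axes, 1), n_features))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    well_ids, roles, classes, rows = [], [], [], []
    for w in range(n_dmso_wells):
        well_ids.append(f"DMSO_{w:03d}")
        roles.append("DMSO")
        classes.append(None)
        rows.append(baseline + rng.normal(0.0, noise_sd, n_features))
    assign = rng.integers(0, max(phenotype_axes, 1), n_compound_wells)
    for w in range(n_compound_wells):
        well_ids.append(f"CPD_{w:03d}")
        roles.append("compound")
        classes.append(int(assign[w]))
        disp = effect_size * axes[assign[w]] * np.sqrt(n_features) if effect_size else 0.0
        rows.append(baseline + disp + rng.normal(0.0, noise_sd, n_features))

    table = pd.DataFrame(
        rows, index=pd.Index(well_ids, name="well"),
        columns=[f"feat_{k:04d}" for k in range(n_features)],
    )
    table.insert(0, "role", roles)
    truth = {
        wid: {"axis": cls}
        for wid, role, cls in zip(well_ids, roles, classes)
        if role == "compound" and effect_size != 0
    }
    sim = SimTruth(
        kind="features",
        seed=seed,
        params={
            "n_compound_wells": n_compound_wells,
            "n_dmso_wells": n_dmso_wells,
            "n_features": n_features,
            "phenotype_axes": phenotype_axes,
            "effect_size": effect_size,
            "noise_sd": noise_sd,
        },
        truth=truth,
    )
    return table, sim


# ---------------------------------------------------------------------------
# CRISPR resistance screens
# ---------------------------------------------------------------------------

def _nb_sample(rng, mean, dispersion):
    """Gamma-Poisson draw with Var = m + dispersion * m^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def gen_crispr(
    n_genes: int = 1000,
    guides_per_gene: int = 4,
    n_resistance: int = 10,
    effect_lfc: float = 2.0,
    frac_active_guides: float = 0.75,
    depth: int = 500,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a genome-scale positive-selection screen count table.

    Control counts are negative-binomial around library proportions at mean
    coverage ``depth`` reads per guide; in the treated sample the active
    guides (a ``frac_active_guides`` fraction, at least one) of the first
    ``n_resistance`` genes have their expected counts multiplied by
    ``2**effect_lfc`` before resampling — an enrichment (resistance) screen.
    """
    if n_resistance > n_genes:
        raise ValueError("n_resistance must not exceed n_genes")
    rng = np.random.default_rng(seed)
    n_guides = n_genes * guides_per_gene
    guides = [f"sg_{g:05d}_{k}" for g in range(n_genes) for k in range(guides_per_gene)]
    genes = [f"GENE{g:05d}" for g in range(n_genes) for _ in range(guides_per_gene)]

    # library skew: log-normal guide representation
    prop = rng.lognormal(0.0, 0.4, n_guides)
    prop /= prop.sum()
    mean_ctl = prop * depth * n_guides

    n_active = max(1, int(round(frac_active_guides * guides_per_gene)))
    active = np.zeros(n_guides, dtype=bool)
    for g in range(n_resistance):
        idx = np.arange(g * guides_per_gene, g * guides_per_gene + n_active)
        active[idx] = True
    mean_trt = np.where(active, mean_ctl * 2.0**effect_lfc, mean_ctl)

    counts = pd.DataFrame(
        {
            "sgRNA": guides,
            "gene": genes,
            "control": _nb_sample(rng, mean_ctl, dispersion),
            "treatment": _nb_sample(rng, mean_trt, dispersion),
        }
    )
    truth = {
        f"GENE{g:05d}": {
            "resistance": True,
            "effect_lfc": effect_lfc,
            "active_guides": [f"sg_{g:05d}_{k}" for k in range(n_active)],
        }
        for g in range(n_resistance)
        if effect_lfc != 0
    }
    sim = SimTruth(
        kind="crispr",
        seed=seed,
        params={
            "n_genes": n_genes,
            "guides_per_gene": guides_per_gene,
            "n_resistance": n_resistance,
            "effect_lfc": effect_lfc,
            "frac_active_guides": frac_active_guides,
            "depth": depth,
            "dispersion": dispersion,
        },
        truth=truth,
    )
    return counts, sim


# ---------------------------------------------------------------------------
# Dose-response plates
# ---------------------------------------------------------------------------

def gen_doseresp(
    ec50: float = 0.1,
    hill: float = 1.5,
    top: float = 1.0,
    bottom: float = 0.05,
    concs: Sequence[float] = DEFAULT_DOSE_CONCS,
    noise_cv: float = 0.0,
    n_dmso: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a luminescence viability plate on a 4PL dose-response.

    Signal = 4PL(conc) × (1 + multiplicative log-normal noise); DMSO control
    wells sit at viability ``top``. Default concentrations are the
    eight-point half-log screening dilution (10 → 0.003 μM).
    """
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive")
    if hill == 0:
        raise ValueError("hill must be nonzero")
    rng = np.random.default_rng(seed)
    resp = bottom + (top - bottom) / (1.0 + (concs / ec50) ** hill)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(vals):
        vals = np.asarray(vals, dtype=float)
        if sigma == 0:
            return vals
        return vals * rng.lognormal(-0.5 * sigma**2, sigma, vals.shape)

    gain = 1e5  # arbitrary luminescence gain
    rows = [
        {"well": f"S{k:02d}", "role": "sample", "concentration": c, "signal": gain * v}
        for k, (c, v) in enumerate(zip(concs, noisy(resp)))
    ]
    for k, v in enumerate(noisy(np.full(n_dmso, top))):
        rows.append({"well": f"D{k:02d}", "role": "dmso", "concentration": np.nan, "signal": gain * v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential expression / proteomics tables
# ---------------------------------------------------------------------------

def gen_expression(
    n_entities: int = 1000,
    n_regulated: int = 50,
    lfc_scale: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a differential table (entity, log2FC, baseMean, pvalue, padj).

    The first ``n_regulated`` entities are regulated by construction:
    |log2FC| > 0.25 and adjusted p < 0.05. Null entities receive small fold
    changes and uniform p values. baseMean is log-normal, loosely coupled to
    effect strength so evidence axes are not independent.
    """
    if n_regulated > n_entities:
        raise ValueError("n_regulated must not exceed n_entities")
    rng = np.random.default_rng(seed)
    names = [f"E{i:05d}" for i in range(n_entities)]
    lfc = rng.normal(0.0, 0.1, n_entities)
    padj = rng.uniform(0.05, 1.0, n_entities)
    if n_regulated:
        sign = rng.choice([-1.0, 1.0], n_regulated)
        mag = 0.3 + np.abs(rng.normal(0.0, lfc_scale, n_regulated))
        lfc[:n_regulated] = sign * mag
        padj[:n_regulated] = 10.0 ** rng.uniform(-8, np.log10(0.049), n_regulated)
    base_mean = np.exp(rng.normal(5.0, 1.5, n_entities) + 0.3 * np.abs(lfc))
    pval = np.clip(padj * rng.uniform(0.3, 1.0, n_entities), 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "entity": names,
            "log2fc": lfc,
            "baseMean": base_mean,
            "pvalue": pval,
            "padj": padj,
        }
    )
    truth = {
        names[i]: {"log2fc": lfc[i], "padj": padj[i]} for i in range(n_regulated)
    }
    sim = SimTruth(
        kind="expression",
        seed=seed,
        params={
            "n_entities": n_entities,
            "n_regulated": n_regulated,
            "lfc_scale": lfc_scale,
        },
        truth=truth,
    )
    return table, sim
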