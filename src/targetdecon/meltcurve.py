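"""Thermal proteome profiling and CETSA melting-curve analysis.

Implements the standard intact-cell thermal-shift workflow: per-temperature
sum-total normalization, a PSM quantification filter, scaling to the lowest
(reference) temperature, sigmoid melting-curve fits, a nested-model F test
comparing a shared curve against per-condition curves (the NPARC approach),
and Tm/ΔTm hit calling with Benjamini–Hochberg control.

The melting model is the three-parameter sigmoid

    f(T) = (1 - plateau) / (1 + exp(b - a/T)) + plateau

whose half-denaturation point (Tm) has the closed form
``a / (b - ln(0.5 / (0.5 - plateau)))`` when plateau < 0.5.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TppDataset",
    "MeltFitResult",
    "NparcResult",
    "melt_curve",
    "melt_tm",
    "sum_total_normalize",
    "psm_filter",
    "scale_to_reference",
    "fit_melt_curve",
    "nparc_test",
    "run_nparc",
    "call_hits",
    "cetsa_melt",
]

# Tm is only reported within this margin (°C) beyond the measured gradient;
# further extrapolation is numerically meaningless.
TM_EXTRAPOLATION_MARGIN = 10.0

_BOUNDS = ([1e-3, 1e-3, 0.0], [1e5, 500.0, 1.0 - 1e-9])


@dataclasses.dataclass
class TppDataset:
    """Long-format thermal-profiling dataset.

    ``data`` columns: protein, condition ∈ {vehicle, treatment}, replicate,
    temperature (°C), abundance (≥ 0; NaN marks missing). ``psm`` columns:
    protein, condition, psm (minimum PSM evidence per condition). The lowest
    temperature is the reference point.
    """

    data: pd.DataFrame
    psm: pd.DataFrame | None = None

    def __post_init__(self):
        required = {"protein", "condition", "replicate", "temperature", "abundance"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.data["temperature"].unique())

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein"].unique())

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TppDataset":
        df = pd.read_csv(path, sep="\t")
        psm = None
        if "psm" in df.columns:
            psm = (
                df.groupby(["protein", "condition"], as_index=False)["psm"].min()
            )
            df = df.drop(columns=["psm"])
        return cls(data=df, psm=psm)


@dataclasses.dataclass
class MeltFitResult:
    """Fitted sigmoid melting curve for one protein/condition."""

    a: float
    b: float
    plateau: float
    rss: float
    tm: float | None
    n_points: int
    converged: bool = True


@dataclasses.dataclass
class NparcResult:
    """Per-protein nested-model comparison of melting behavior."""

    protein: str
    f_stat: float
    p: float
    delta_tm: float | None
    tm_vehicle: float | None
    tm_treatment: float | None
    rss_null: float
    rss_alt: float
    d1: int
    d2: int
    p_adj: float | None = None
    direction: str = "none"


def melt_curve(temps, a, b, plateau):
    """Sigmoid melting model f(T) = (1-plateau)/(1+exp(b - a/T)) + plateau."""
    temps = np.asarray(temps, dtype=float)
    return (1.0 - plateau) / (1.0 + np.exp(b - a / temps)) + plateau


def melt_tm(a: float, b: float, plateau: float) -> float | None:
    """Closed-form half-denaturation temperature; None if plateau ≥ 0.5."""
    if plateau >= 0.5:
        return None
    denom = b - math.log(0.5 / (0.5 - plateau))
    if denom <= 0:
        return None
    return a / denom


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def sum_total_normalize(ds: TppDataset) -> TppDataset:
    """Equalize per-sample abundance totals at each temperature point.

    For every temperature, per-sample totals are computed over the proteins
    quantified in *all* samples at that temperature (so missingness cannot
    bias the totals), and each sample column is rescaled so its total equals
    the across-sample mean of totals.
    """
    df = ds.data.copy()
    df["_sample"] = df["condition"].astype(str) + "/" + df["replicate"].astype(str)
    out = []
    for temp, sub in df.groupby("temperature", sort=False):
        wide = sub.pivot_table(
            index="protein", columns="_sample", values="abundance", aggfunc="first"
        )
        complete = wide.dropna()
        if complete.empty:
            raise ValueError(f"no protein quantified in all samples at T={temp}")
        totals = complete.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError(f"sample with zero total at T={temp}")
        factors = totals.mean() / totals
        sub = sub.copy()
        sub["abundance"] = sub["abundance"] * sub["_sample"].map(factors)
        out.append(sub)
    norm = pd.concat(out, ignore_index=True).drop(columns="_sample")
    return TppDataset(data=norm, psm=ds.psm)


def psm_filter(ds: TppDataset, min_psm: int = 2) -> TppDataset:
    """Keep proteins with PSM evidence ≥ ``min_psm`` in both conditions."""
    if ds.psm is None:
        raise ValueError("dataset has no PSM table")
    per_cond = ds.psm.pivot_table(index="protein", columns="condition", values="psm")
    keep = per_cond.index[(per_cond >= min_psm).all(axis=1) & per_cond.notna().all(axis=1)]
    data = ds.data[ds.data["protein"].isin(keep)].reset_index(drop=True)
    psm = ds.psm[ds.psm["protein"].isin(keep)].reset_index(drop=True)
    return TppDataset(data=data, psm=psm)


def scale_to_reference(ds: TppDataset) -> TppDataset:
    """Express abundances as fold changes relative to the lowest temperature.

    Each (protein, condition, replicate) series is divided by its abundance
    at the reference (lowest) temperature; series with a missing or
    non-positive reference value are excluded with a log record.
    """
    df = ds.data
    t_ref = df["temperature"].min()
    ref = (
        df[df["temperature"] == t_ref]
        .set_index(["protein", "condition", "replicate"])["abundance"]
    )
    keys = pd.MultiIndex.from_frame(df[["protein", "condition", "replicate"]])
    ref_vals = ref.reindex(keys).to_numpy()
    bad = ~(ref_vals > 0)
    if bad.any():
        dropped_series = sorted(set(keys[bad]))
        dropped = sorted({k[0] for k in dropped_series})
        logger.info(
            "scale_to_reference: excluding %d series with missing/zero reference "
            "(proteins: %s%s)",
            len(dropped_series),
            ", ".join(dropped[:5]),
            "…" if len(dropped) > 5 else "",
        )
    out = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["abundance"] = df["abundance"].to_numpy() / ref_vals
    out = out[~bad].reset_index(drop=True)
    return TppDataset(data=out, psm=ds.psm)


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

def _residuals(theta, temps, fc):
    a, b, plateau = theta
    return melt_curve(temps, a, b, plateau) - fc


def _heuristic_start(temps, fc):
    """Data-driven initial guess: plateau from the tail, Tm near the 0.5
    crossing, slope from a representative steepness."""
    plateau = float(np.clip(np.min(fc), 0.0, 0.49))
    half = 0.5 * (1 + plateau)
    below = np.nonzero(fc < half)[0]
    tm0 = float(temps[below[0]]) if below.size else float(np.median(temps))
    b0 = 15.0
    ell = math.log(0.5 / (0.5 - plateau)) if plateau < 0.5 else 0.0
    a0 = max(tm0 * (b0 - ell), 1.0)
    return (a0, b0, plateau)


_GRID_STARTS = [
    (400.0, 8.0, 0.0),
    (700.0, 14.0, 0.05),
    (1100.0, 22.0, 0.1),
    (550.0, 11.0, 0.3),
]


def fit_melt_curve(
    temps: Sequence[float],
    fc: Sequence[float],
    starts: Iterable[tuple[float, float, float]] | None = None,
) -> MeltFitResult:
    """Least-squares sigmoid fit with multi-start initialization.

    Starts comprise a data-driven guess plus a fixed parameter grid (and any
    caller-supplied extras); the solution with the lowest residual sum of
    squares is kept. Tm is reported only inside the extrapolation window
    [min(T) − 10, max(T) + 10] °C.
    """
    temps = np.asarray(temps, dtype=float)
    fc = np.asarray(fc, dtype=float)
    ok = np.isfinite(fc) & np.isfinite(temps)
    temps, fc = temps[ok], fc[ok]
    if temps.size < 5:
        raise ValueError("need at least 5 points to fit a melting curve")

    all_starts = [_heuristic_start(temps, fc)] + list(_GRID_STARTS)
    if starts is not None:
        all_starts += list(starts)

    best = None
    for x0 in all_starts:
        x0 = np.clip(x0, _BOUNDS[0], _BOUNDS[1])
        try:
            sol = optimize.least_squares(
                _residuals, x0, args=(temps, fc), bounds=_BOUNDS,
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - solver pathologies
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return MeltFitResult(
            a=np.nan, b=np.nan, plateau=np.nan, rss=np.inf,
            tm=None, n_points=int(temps.size), converged=False,
        )
    rss, (a, b, plateau) = best
    tm = melt_tm(a, b, plateau)
    if tm is not None and not (
        temps.min() - TM_EXTRAPOLATION_MARGIN <= tm <= temps.max() + TM_EXTRAPOLATION_MARGIN
    ):
        tm = None
    return MeltFitResult(
        a=float(a), b=float(b), plateau=float(plateau),
        rss=rss, tm=tm, n_points=int(temps.size),
    )


# ---------------------------------------------------------------------------
# Nested-model testing
# ---------------------------------------------------------------------------

def nparc_test(
    vehicle: tuple[Sequence[float], Sequence[float]],
    treatment: tuple[Sequence[float], Sequence[float]],
    protein: str = "",
    d1: int | None = None,
    d2: int | None = None,
) -> NparcResult:
    """Nested-model F test of condition-dependent melting.

    The null model fits one sigmoid to all points pooled (3 parameters); the
    alternative fits one per condition (6 parameters), each seeded with the
    null solution so rss_alt ≤ rss_null holds by construction.
    F = ((rss_null − rss_alt)/d1) / (rss_alt/d2) with theoretical degrees of
    freedom d1 = 3 and d2 = n − 6 unless overridden.
    """
    t_v, y_v = (np.asarray(x, dtype=float) for x in vehicle)
    t_t, y_t = (np.asarray(x, dtype=float) for x in treatment)
    t_all = np.concatenate([t_v, t_t])
    y_all = np.concatenate([y_v, y_t])
    n = int(np.isfinite(y_all).sum())

    fit_null = fit_melt_curve(t_all, y_all)
    null_seed = [(fit_null.a, fit_null.b, fit_null.plateau)] if fit_null.converged else None
    fit_v = fit_melt_curve(t_v, y_v, starts=null_seed)
    fit_t = fit_melt_curve(t_t, y_t, starts=null_seed)
    rss_null = fit_null.rss
    rss_alt = fit_v.rss + fit_t.rss
    # guard against numerically negative improvements
    rss_alt = min(rss_alt, rss_null)

    d1 = 3 if d1 is None else d1
    d2 = (n - 6) if d2 is None else d2
    if d2 <= 0:
        raise ValueError("too few points for the nested F test (n - 6 <= 0)")
    # Degenerate cases: an essentially perfect shared fit, or an RSS
    # improvement within optimizer noise, carries no evidence of a shift.
    rel_impr = (rss_null - rss_alt) / rss_null if rss_null > 0 else 0.0
    if rss_null <= 1e-12 * n or rel_impr <= 1e-6:
        f_stat = 0.0
    else:
        f_stat = ((rss_null - rss_alt) / d1) / (rss_alt / d2)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, d1, d2))

    delta = None
    if fit_v.tm is not None and fit_t.tm is not None:
        delta = fit_t.tm - fit_v.tm
    return NparcResult(
        protein=protein, f_stat=float(f_stat), p=p, delta_tm=delta,
        tm_vehicle=fit_v.tm, tm_treatment=fit_t.tm,
        rss_null=rss_null, rss_alt=rss_alt, d1=d1, d2=d2,
    )


def empirical_df(results: pd.DataFrame, trim: float = 0.1) -> tuple[float, float]:
    """Empirically fitted effective degrees of freedom for the nested F test.

    Residuals left after reference scaling are not independent (all points
    of a sample share the reference measurement's noise), which makes the
    theoretical (d1 = 3, d2 = n − 6) F distribution anticonservative.
    Following the empirical-null idea behind the NPARC method, effective
    degrees of freedom (d1', d2') are fitted by maximum likelihood so that
    the scale-free statistics r = (rss_null − rss_alt)/rss_alt follow
    (d1'/d2')·F(d1', d2') across proteins. The top ``trim`` fraction of r
    is excluded and the likelihood truncated accordingly, so a minority of
    genuine shifts does not distort the null fit.
    """
    ok = results["tested"].fillna(False).astype(bool)
    diff = (results.loc[ok, "rss_null"] - results.loc[ok, "rss_alt"]).to_numpy()
    rss = results.loc[ok, "rss_alt"].to_numpy()
    good = (rss > 0) & np.isfinite(diff)
    ratio = np.maximum(diff[good] / rss[good], 0.0)
    if ratio.size < 50:
        raise ValueError("too few tested proteins to estimate empirical df")
    cutoff = np.quantile(ratio, 1.0 - trim)
    bulk = ratio[ratio <= cutoff]

    def negll(log_theta):
        d1, d2 = np.exp(log_theta)
        f = np.maximum(bulk * d2 / d1, 1e-12)
        ll = stats.f.logpdf(f, d1, d2) + np.log(d2 / d1)
        trunc = stats.f.logcdf(cutoff * d2 / d1, d1, d2)
        return -(ll.sum() - bulk.size * trunc)

    sol = optimize.minimize(negll, np.log([2.0, 10.0]), method="Nelder-Mead")
    d1_eff, d2_eff = np.exp(sol.x)
    return float(max(d1_eff, 0.5)), float(max(d2_eff, 1.0))


def rescore_empirical(results: pd.DataFrame) -> pd.DataFrame:
    """Recompute F statistics and p values under empirical degrees of freedom."""
    d1_eff, d2_eff = empirical_df(results)
    out = results.copy()
    ok = out["tested"].fillna(False).astype(bool)
    diff = out.loc[ok, "rss_null"] - out.loc[ok, "rss_alt"]
    rss = out.loc[ok, "rss_alt"]
    f_emp = (diff / d1_eff) / (rss / d2_eff)
    f_emp = f_emp.clip(lower=0.0).where(out.loc[ok, "f_stat"] > 0, 0.0)
    out.loc[ok, "f_stat"] = f_emp
    out.loc[ok, "p"] = stats.f.sf(f_emp, d1_eff, d2_eff)
    out.attrs["df_mode"] = "empirical"
    out.attrs["d1_eff"] = d1_eff
    out.attrs["d2_eff"] = d2_eff
    return out


def run_nparc(ds: TppDataset, df_mode: str = "theoretical") -> pd.DataFrame:
    """Fit and test every protein of a reference-scaled dataset.

    Returns one row per protein with the F statistic, p value and ΔTm;
    proteins whose fits fail or that lack enough points are recorded with
    ``tested = False``. ``df_mode='empirical'`` replaces the theoretical
    F degrees of freedom with moment-matched effective ones (see
    :func:`empirical_df`), which restores calibration when residuals are
    correlated by the reference scaling.
    """
    rows = []
    for protein, sub in ds.data.groupby("protein", sort=True):
        veh = sub[sub["condition"] == "vehicle"]
        trt = sub[sub["condition"] == "treatment"]
        try:
            res = nparc_test(
                (veh["temperature"].to_numpy(), veh["abundance"].to_numpy()),
                (trt["temperature"].to_numpy(), trt["abundance"].to_numpy()),
                protein=protein,
            )
        except ValueError:
            rows.append({"protein": protein, "tested": False})
            continue
        rows.append(
            {
                "protein": protein,
                "tested": True,
                "f_stat": res.f_stat,
                "p": res.p,
                "delta_tm": res.delta_tm,
                "tm_vehicle": res.tm_vehicle,
                "tm_treatment": res.tm_treatment,
                "rss_null": res.rss_null,
                "rss_alt": res.rss_alt,
            }
        )
    out = pd.DataFrame(rows)
    if df_mode == "empirical":
        out = rescore_empirical(out)
    elif df_mode != "theoretical":
        raise ValueError("df_mode must be 'theoretical' or 'empirical'")
    return out


def call_hits(
    results: pd.DataFrame,
    alpha: float = 0.01,
    min_abs_dtm: float = 1.0,
) -> pd.DataFrame:
    """BH-adjust NPARC p values and call thermal-shift hits.

    Hits require adjusted p < ``alpha`` AND |ΔTm| strictly greater than
    ``min_abs_dtm`` °C; proteins with undefined ΔTm cannot be hits.
    Direction is 'stabilized' for positive ΔTm, 'destabilized' for negative.
    """
    if results.empty:
        raise ValueError("empty result table")
    out = results.copy()
    tested = out.get("tested", pd.Series(True, index=out.index)).fillna(False).astype(bool)
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    dtm = out.get("delta_tm")
    has_dtm = dtm.notna() if dtm is not None else pd.Series(False, index=out.index)
    out["hit"] = (
        tested
        & (out["p_adj"] < alpha)
        & has_dtm
        & (out["delta_tm"].abs() > min_abs_dtm)
    )
    out["direction"] = "none"
    out.loc[out["hit"] & (out["delta_tm"] > 0), "direction"] = "stabilized"
    out.loc[out["hit"] & (out["delta_tm"] < 0), "direction"] = "destabilized"
    return out


# ---------------------------------------------------------------------------
# Targeted thermal shift (CETSA)
# ---------------------------------------------------------------------------

def cetsa_melt(temps: Sequence[float], luminescence: Sequence[float]) -> MeltFitResult:
    """Tm from a targeted (e.g. split-luciferase-tagged) melt curve.

    Signals are normalized to the mean at the lowest temperature, then
    fitted with the shared sigmoid model. Replicate measurements at the same
    temperature are averaged before normalization.
    """
    temps = np.asarray(temps, dtype=float)
    lum = np.asarray(luminescence, dtype=float)
    df = pd.DataFrame({"t": temps, "y": lum}).groupby("t", as_index=False)["y"].mean()
    t, y = df["t"].to_numpy(), df["y"].to_numpy()
    ref = y[np.argmin(t)]
    if not ref > 0:
        raise ValueError("non-positive signal at the reference temperature")
    return fit_melt_curve(t, y / ref)
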