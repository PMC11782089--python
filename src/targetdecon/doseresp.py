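"""Viability and binding-assay dose-response reduction.

Luminescence signals are normalized to a control anchor (DMSO mean or the
lowest drug concentration), fitted with the four-parameter logistic model

    f(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill)

and summarized as EC50 and a relative area under the curve (trapezoidal
area of viability over log10 concentration, relative to constant full
viability on the same grid). A two-point normalization converts
fluorescence-polarization signals to percent inhibition between two
control anchors.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DoseResponse",
    "FourPlFit",
    "four_pl",
    "normalize_to_control",
    "fit_4pl",
    "relative_auc",
    "normalize_fp",
]


@dataclasses.dataclass
class DoseResponse:
    """Control-normalized viability measured at positive concentrations."""

    concentrations: np.ndarray
    viability: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability must be finite")
        if len(self.concentrations) != len(self.viability):
            raise ValueError("concentration and viability lengths differ")


@dataclasses.dataclass
class FourPlFit:
    ec50: float | None
    hill: float
    top: float
    bottom: float
    rss: float
    rel_auc: float


def four_pl(conc, ec50, hill, top, bottom):
    """Four-parameter logistic response."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ec50) ** hill)


def normalize_to_control(lum: Sequence[float], control_lum: Sequence[float]) -> np.ndarray:
    """Viability fractions: signal divided by the mean control signal."""
    control = np.asarray(control_lum, dtype=float)
    if control.size == 0:
        raise ValueError("need at least one control well")
    mean_ctl = control.mean()
    if mean_ctl <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(lum, dtype=float) / mean_ctl


def relative_auc(dr: DoseResponse) -> float:
    """Relative AUC: trapezoidal viability area over log10(concentration),
    normalized by the constant-1 reference on the same grid. Viability is
    clipped at 0 from below; 1.0 means no effect, 0.0 complete killing."""
    if len(dr.concentrations) < 2:
        raise ValueError("need at least 2 concentrations")
    order = np.argsort(dr.concentrations)
    x = np.log10(dr.concentrations[order])
    y = np.clip(dr.viability[order], 0.0, None)
    area = np.trapezoid(y, x)
    ref = x[-1] - x[0]
    return float(area / ref)


def fit_4pl(dr: DoseResponse) -> FourPlFit:
    """Least-squares 4PL fit with multi-start over the Hill-slope sign.

    EC50 is flagged undefined (None) when the data carry no dose trend
    (fitted |top − bottom| below 1% of the response scale) or when no start
    converges.
    """
    conc = dr.concentrations
    y = dr.viability
    uniq = np.unique(conc)
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    span = max(np.ptp(y), 1e-12)
    geo_mid = float(np.exp(np.mean(np.log(conc))))
    starts = []
    for hill0 in (1.0, -1.0, 2.0, -2.0):
        starts.append((geo_mid, hill0, float(y.max()), float(y.min())))
    lo = [conc.min() / 1e3, -20.0, -np.inf, -np.inf]
    hi = [conc.max() * 1e3, 20.0, np.inf, np.inf]

    def resid(theta):
        return four_pl(conc, *theta) - y

    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return FourPlFit(
            ec50=None, hill=np.nan, top=np.nan, bottom=np.nan,
            rss=np.inf, rel_auc=relative_auc(dr),
        )
    rss, (ec50, hill, top, bottom) = best
    # canonical orientation: the model is invariant under
    # (hill, top, bottom) -> (-hill, bottom, top); report top >= bottom
    if top < bottom:
        top, bottom, hill = bottom, top, -hill
    defined = abs(top - bottom) > 0.01 * max(abs(top), abs(bottom), span, 1e-12)
    return FourPlFit(
        ec50=float(ec50) if defined else None,
        hill=float(hill), top=float(top), bottom=float(bottom),
        rss=rss, rel_auc=relative_auc(dr),
    )


def normalize_fp(
    fp_sample,
    fp_protein_probe_ctrl: float,
    fp_probe_ctrl: float,
    anchor_100: str = "protein_probe",
) -> np.ndarray | float:
    """Two-point percent-inhibition normalization of polarization signals.

    The default maps the protein + fluorophore control to 100% inhibition
    and the fluorophore-only control to 0%; ``anchor_100='probe'`` swaps
    the anchors for the conventional assignment.
    """
    if fp_protein_probe_ctrl == fp_probe_ctrl:
        raise ValueError("control anchors must differ")
    if anchor_100 == "protein_probe":
        hi, lo = fp_protein_probe_ctrl, fp_probe_ctrl
    elif anchor_100 == "probe":
        hi, lo = fp_probe_ctrl, fp_protein_probe_ctrl
    else:
        raise ValueError("anchor_100 must be 'protein_probe' or 'probe'")
    sample = np.asarray(fp_sample, dtype=float)
    out = 100.0 * (sample - lo) / (hi - lo)
    return float(out) if out.ndim == 0 else out
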