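"""Cell-painting phenotypic profiles, induction and biosimilarity.

A well's phenotypic profile is the vector of robust z scores of its image
features relative to the DMSO control wells on the plate: each feature's
value is expressed as the number of raw median absolute deviations it lies
from the control median. From a profile two summary statistics follow:

* induction — the percentage of features with |z| strictly above 3, a
  measure of how much morphology a compound induces;
* biosimilarity — 1 minus the correlation distance between two profiles,
  i.e. the Pearson correlation of the mean-centered z vectors, used to match
  a query compound against annotated reference profiles.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import correlation as _correlation_distance

__all__ = [
    "PhenotypicProfile",
    "ConstantProfileError",
    "robust_z",
    "induction",
    "biosimilarity",
    "biosimilarity_matrix",
    "reference_match",
    "aggregate_replicates",
]


class ConstantProfileError(ValueError):
    """Raised when biosimilarity is requested for a constant profile
    (correlation distance is undefined)."""


@dataclasses.dataclass
class PhenotypicProfile:
    """One compound/concentration's feature z-score vector."""

    compound_id: str
    z: np.ndarray
    feature_index: pd.Index
    concentration: float | None = None
    mad_zero_features: tuple[str, ...] = ()

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if len(self.z) != len(self.feature_index):
            raise ValueError("z length must equal the feature index length")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("profile contains non-finite z scores")

    @property
    def n_features(self) -> int:
        return len(self.z)


def _check_shared_index(a: PhenotypicProfile, b: PhenotypicProfile) -> None:
    if not a.feature_index.equals(b.feature_index):
        raise ValueError("profiles do not share a feature index")


def robust_z(
    feature_table: pd.DataFrame,
    dmso_well_ids: Sequence[str],
    concentration: float | None = None,
) -> dict[str, PhenotypicProfile]:
    """Robust z profiles for every well of a wells × features table.

    z[f] = (x[f] − median_DMSO[f]) / MAD_DMSO[f] with the raw median
    absolute deviation (no consistency factor). Features whose control MAD
    is zero get z = 0 and are flagged on the profile.
    """
    dmso_well_ids = list(dmso_well_ids)
    if len(dmso_well_ids) < 4:
        raise ValueError("need at least 4 DMSO wells")
    missing = set(dmso_well_ids) - set(feature_table.index)
    if missing:
        raise ValueError(f"DMSO wells not in table: {sorted(missing)}")
    if not all(np.issubdtype(dt, np.number) for dt in feature_table.dtypes):
        raise ValueError("all features must be numeric")

    ctrl = feature_table.loc[dmso_well_ids]
    med = ctrl.median(axis=0)
    mad = (ctrl - med).abs().median(axis=0)
    zero_mad = mad.index[mad == 0]
    safe_mad = mad.replace(0, np.nan)

    z_all = (feature_table - med) / safe_mad
    z_all[zero_mad] = 0.0
    return {
        well: PhenotypicProfile(
            compound_id=str(well),
            z=z_all.loc[well].to_numpy(),
            feature_index=feature_table.columns,
            concentration=concentration,
            mad_zero_features=tuple(zero_mad),
        )
        for well in feature_table.index
    }


def induction(profile: PhenotypicProfile, threshold: float = 3.0) -> float:
    """Induction (%): share of features with |z| strictly above ``threshold``."""
    if profile.n_features == 0:
        raise ValueError("profile has no features")
    return 100.0 * float(np.count_nonzero(np.abs(profile.z) > threshold)) / profile.n_features


def biosimilarity(a: PhenotypicProfile, b: PhenotypicProfile) -> float:
    """Biosimilarity = 1 − correlation distance between two profiles.

    Equals the Pearson correlation of the two z vectors; symmetric and in
    [−1, 1]. Raises :class:`ConstantProfileError` for constant profiles.
    """
    _check_shared_index(a, b)
    if np.ptp(a.z) == 0 or np.ptp(b.z) == 0:
        raise ConstantProfileError("biosimilarity undefined for a constant profile")
    return float(1.0 - _correlation_distance(a.z, b.z))


def biosimilarity_matrix(profiles: Sequence[PhenotypicProfile]) -> pd.DataFrame:
    """Symmetric pairwise biosimilarity matrix (NaN where undefined)."""
    n = len(profiles)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            try:
                v = biosimilarity(profiles[i], profiles[j])
            except ConstantProfileError:
                v = np.nan
            out[i, j] = out[j, i] = v
    labels = [p.compound_id for p in profiles]
    return pd.DataFrame(out, index=labels, columns=labels)


def reference_match(
    query: PhenotypicProfile,
    references: Sequence[PhenotypicProfile],
    min_induction: float = 5.0,
) -> pd.DataFrame:
    """Rank reference profiles by biosimilarity to a query.

    Returns a table sorted by descending biosimilarity with a
    ``low_activity`` flag for references (or the query) whose induction is
    below ``min_induction`` percent — similarity to an inactive profile is
    not biologically interpretable.
    """
    if not references:
        raise ValueError("empty reference list")
    query_low = induction(query) < min_induction
    rows = []
    for ref in references:
        try:
            sim = biosimilarity(query, ref)
        except ConstantProfileError:
            sim = np.nan
        rows.append(
            {
                "reference": ref.compound_id,
                "biosimilarity": sim,
                "induction": induction(ref),
                "low_activity": query_low or induction(ref) < min_induction,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["biosimilarity", "reference"], ascending=[False, True], na_position="last"
    )
    return out.reset_index(drop=True)


def aggregate_replicates(profiles: Sequence[PhenotypicProfile]) -> PhenotypicProfile:
    """Feature-wise median profile across replicate wells of one compound."""
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    ids = {p.compound_id for p in profiles}
    if len(ids) > 1:
        raise ValueError(f"mixed compound ids: {sorted(ids)}")
    for p in profiles[1:]:
        _check_shared_index(first, p)
    z = np.median(np.vstack([p.z for p in profiles]), axis=0)
    return PhenotypicProfile(
        compound_id=first.compound_id,
        z=z,
        feature_index=first.feature_index,
        concentration=first.concentration,
    )
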