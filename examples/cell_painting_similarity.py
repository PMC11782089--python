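"""Morphological profiling: induction and biosimilarity of compound wells.

Simulates a cell-painting plate (579 features) where compound wells are
displaced along one of three latent phenotype axes, computes robust z
profiles against the DMSO wells, and reports per-well induction plus the
best phenotype match for one query well.
"""

from targetdecon import morphoprofile as mp
from targetdecon import synthetic as syn

table, truth = syn.gen_featuretable(
    n_compound_wells=9, n_dmso_wells=8, n_features=579,
    phenotype_axes=3, effect_size=8.0, seed=2,
)
feats = table.drop(columns="role")
dmso_wells = table.index[table.role == "DMSO"].tolist()
profiles = mp.robust_z(feats, dmso_wells)

compound_wells = [w for w in table.index if w.startswith("CPD")]
query = profiles[compound_wells[0]]
references = [profiles[w] for w in compound_wells[1:]]

print(f"query {query.compound_id} (axis {truth.truth[query.compound_id]['axis']}), "
      f"induction = {mp.induction(query):.1f}%")
ranked = mp.reference_match(query, references, min_induction=5.0)
for _, row in ranked.head(4).iterrows():
    axis = truth.truth[row.reference]["axis"]
    print(f"  {row.reference}: biosimilarity = {row.biosimilarity:+.3f} "
          f"(axis {axis}, induction {row.induction:.1f}%)")
# Induction is the percentage of features shifted by more than 3 control
# MADs; biosimilarity is the Pearson correlation of z profiles. Wells
# sharing the query's phenotype axis should top the ranking with values
# near 1.
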