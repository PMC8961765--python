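"""Simulate a synthetic gene and annotate its variants with the
22-feature catalogue.

Pathogenic variants are planted preferentially at conserved, buried
positions of a toy globular structure; benign variants at variable,
exposed or unmodelled positions. The annotation step recomputes every
feature (volume change, hydrophobicity transition, relative side-chain
solvent accessibility, burial, clustering, ...) from the structure and
the per-position tracks.
"""

import protovar as pv
from protovar.annotate import missingness_report

spec = pv.GeneSimSpec(gene_id="DEMO1", n_pathogenic=80, n_benign=40,
                      seq_length=150, seed=11)
variants, context, pdb_text = pv.simulate_gene_dataset(spec)
features = pv.annotate_gene(variants, context)

print(f"gene {spec.gene_id}: {len(variants)} variants, "
      f"{len(context.modelled_positions)} of {len(context)} residues modelled")
print(f"feature matrix: {features.shape[0]} rows x "
      f"{sum(c in pv.FEATURE_COLUMNS for c in features.columns)} features")

by_class = features.groupby("label")[
    ["conservation_grade", "rel_sasa_sidechain", "cluster3d_count"]
].mean(numeric_only=True)
print("\nclass-conditional feature means (the planted signal):")
print(by_class.round(2).to_string())
print("\nper-feature missingness (unmodelled variants lack structure "
      "features):")
print(missingness_report(features).loc[
    ["rel_sasa_sidechain", "burial", "cluster3d_count", "conservation_grade"]
].round(3).to_string())
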