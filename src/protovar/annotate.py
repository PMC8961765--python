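"""Assembly of the per-variant feature matrix.

The full catalogue holds 22 features per variant, split between
sequence-derived values available for every variant and structure/
annotation-derived values that exist only where a model or track covers
the position. Unmodelled variants keep their sequence features and get
explicit missing values for everything structural.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import seqfeat, structfeat
from .datamodel import ProteinContext, VariantRecord
from .seqfeat import DEFAULT_PROPERTIES, ResiduePropertyTable

ID_COLUMNS = ["gene", "position", "ref", "alt", "label"]

#: The 22-feature catalogue, in canonical column order.
FEATURE_COLUMNS = [
    "conservation_grade",
    "volume_change",
    "volume_change_category",
    "hydro_transition",
    "charge_change",
    "rel_sasa_sidechain",
    "burial",
    "goodness_of_fit_violation",
    "disorder_prob",
    "disordered_flag",
    "stability_effect",
    "ppi_effect",
    "proline_into_strand",
    "glycine_core_change",
    "cysteine_extracellular_change",
    "modelled",
    "secondary_structure",
    "functional_site_flag",
    "domain_id",
    "topology",
    "cluster3d_count",
    "cluster1d_count",
]

CATEGORICAL_FEATURES = {
    "volume_change_category": ["large_decrease", "small", "large_increase"],
    "hydro_transition": ["none", "hydrophobic_to_polar", "polar_to_hydrophobic"],
    "burial": ["buried", "intermediate", "exposed"],
    "secondary_structure": ["H", "E", "C"],
    "topology": ["extracellular", "transmembrane", "cytoplasmic", "unknown"],
    "domain_id": None,  # open vocabulary, coded per gene
}

#: Numeric features subject to supervised discretization.
NUMERIC_FEATURES = [
    "conservation_grade", "volume_change", "rel_sasa_sidechain",
    "disorder_prob", "stability_effect", "ppi_effect",
    "cluster3d_count", "cluster1d_count",
]

BOOLEAN_FEATURES = {
    "charge_change", "goodness_of_fit_violation", "disordered_flag",
    "proline_into_strand", "glycine_core_change",
    "cysteine_extracellular_change", "modelled", "functional_site_flag",
}


def annotate_gene(
    variants: list[VariantRecord],
    context: ProteinContext,
    properties: ResiduePropertyTable = DEFAULT_PROPERTIES,
) -> pd.DataFrame:
    """Annotate every variant of one gene with the 22-feature catalogue.

    Returns a DataFrame with the identifier columns, the 22 feature
    columns and an ``n_missing`` bookkeeping column. Structure features
    for unmodelled variants and values from absent tracks are NA.
    The pathogenic variants in ``variants`` define the clustering
    neighbourhoods (each variant's own record is excluded from its own
    counts).
    """
    context.validate()
    ss_map = structfeat.assign_secondary_structure(context)
    pathogenic = [v for v in variants if v.label == "pathogenic"]

    rows = []
    for v in variants:
        if v.gene_id != context.gene_id:
            raise ValueError(
                f"variant gene {v.gene_id!r} does not match context "
                f"{context.gene_id!r}"
            )
        seq_aa = context.residue(v.position)
        if seq_aa != v.ref_aa:
            warnings.warn(
                f"{v.gene_id} p.{v.position}: reference residue {v.ref_aa} "
                f"disagrees with sequence residue {seq_aa}", stacklevel=2,
            )
        delta, category = seqfeat.volume_change(v.ref_aa, v.alt_aa, properties)
        modelled = structfeat.modelled_status(v.position, context)
        rel_sasa = structfeat.compute_rel_sasa(context, v.position)
        burial = structfeat.burial_category(rel_sasa)
        ss = ss_map.get(v.position)
        flags = seqfeat.special_rules(v, context, ss, burial)
        cluster3d = (
            structfeat.cluster3d_count(v, pathogenic, context.coords)
            if modelled else None
        )
        row = {
            "gene": v.gene_id,
            "position": v.position,
            "ref": v.ref_aa,
            "alt": v.alt_aa,
            "label": v.label,
            "conservation_grade": seqfeat.conservation_lookup(v.position, context),
            "volume_change": delta,
            "volume_change_category": category,
            "hydro_transition": seqfeat.hydrophobicity_transition(
                v.ref_aa, v.alt_aa, properties
            ),
            "charge_change": seqfeat.charge_change(v.ref_aa, v.alt_aa, properties),
            "rel_sasa_sidechain": rel_sasa,
            "burial": burial,
            "goodness_of_fit_violation": structfeat.goodness_of_fit(
                v.ref_aa, v.alt_aa, burial, delta
            ),
            "disorder_prob": context.track_value("disorder_prob", v.position),
            "disordered_flag": structfeat.disordered_flag(v.position, context),
            "stability_effect": context.track_value("stability_effect", v.position),
            "ppi_effect": context.track_value("ppi_effect", v.position),
            **flags,
            "modelled": modelled,
            "secondary_structure": ss,
            "functional_site_flag": context.track_value(
                "functional_site", v.position
            ),
            "domain_id": context.track_value("domain_id", v.position),
            "topology": context.track_value("topology", v.position),
            "cluster3d_count": cluster3d,
            "cluster1d_count": structfeat.cluster1d_count(v, pathogenic),
        }
        row["n_missing"] = sum(
            1 for c in FEATURE_COLUMNS if row[c] is None
        )
        rows.append(row)

    df = pd.DataFrame(rows, columns=ID_COLUMNS + FEATURE_COLUMNS + ["n_missing"])
    return df


def missingness_report(features: pd.DataFrame) -> pd.Series:
    """Fraction of missing values per feature column."""
    return features[FEATURE_COLUMNS].isna().mean()


def encode_features(
    features: pd.DataFrame,
    columns: list[str] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    """Encode the feature DataFrame as a numeric matrix for the classifiers.

    Booleans become 0/1, fixed-vocabulary categoricals their index in
    the canonical order, open-vocabulary categoricals (domain_id) codes
    in first-seen order, and missing values NaN. Returns
    ``(X, feature_names, category_maps)``.
    """
    columns = list(columns) if columns is not None else list(FEATURE_COLUMNS)
    n = len(features)
    X = np.full((n, len(columns)), np.nan)
    category_maps: dict[str, list] = {}
    for j, col in enumerate(columns):
        series = features[col]
        if col in BOOLEAN_FEATURES:
            X[:, j] = series.map(
                lambda b: np.nan if pd.isna(b) else float(bool(b))
            ).to_numpy(dtype=float)
        elif col in CATEGORICAL_FEATURES:
            vocab = CATEGORICAL_FEATURES[col]
            if vocab is None:
                vocab = [v for v in series.dropna().unique()]
            category_maps[col] = list(vocab)
            lookup = {v: i for i, v in enumerate(vocab)}
            X[:, j] = series.map(
                lambda v: np.nan if pd.isna(v) else float(lookup.get(v, np.nan))
            ).to_numpy(dtype=float)
        else:
            X[:, j] = pd.to_numeric(series, errors="coerce").to_numpy(dtype=float)
    return X, columns, category_maps


def encoded_labels(features: pd.DataFrame) -> np.ndarray:
    """Binary labels (pathogenic=1, benign=0); unknown-label rows are dropped
    by :func:`training_frame` before this is called."""
    return (features["label"] == "pathogenic").to_numpy(dtype=int)


def training_frame(features: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for supervised training (known labels only)."""
    return features[features["label"].isin(["pathogenic", "benign"])].reset_index(
        drop=True
    )
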