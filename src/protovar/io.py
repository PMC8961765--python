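"""Readers, writers and dataset-level filters for the external formats.

Formats (all plain text):

* variant TSV — columns ``gene  position  ref  alt  label``;
* track TSV — wide format, column ``position`` plus one column per
  annotation track (missing values left empty or ``NA``);
* score TSV — columns ``gene  position  ref  alt  score``;
* structures — PDB ``ATOM`` records, one chain used per protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .aminoacids import AA3_TO_1
from .datamodel import LABELS, TRACK_NAMES, ProteinContext, ScoreTable, VariantRecord

_PROB_TRACKS = ("disorder_prob", "stability_effect", "ppi_effect")
_SS_VALUES = {"H", "E", "C"}
_TOPOLOGY_VALUES = {"extracellular", "transmembrane", "cytoplasmic", "unknown"}


class TableFormatError(ValueError):
    """Raised when an input table violates the expected format."""


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() in {"", "NA", "NaN", "."}
    )


def read_variant_table(path) -> list[VariantRecord]:
    """Parse a variant TSV into validated :class:`VariantRecord` objects.

    Duplicate (gene, position, ref, alt) keys, non-canonical residues and
    synonymous rows are rejected with the offending line number; order is
    preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "position", "ref", "alt", "label"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    records: list[VariantRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            label = str(row.label).strip().lower()
            if label not in LABELS:
                raise ValueError(f"unknown label {row.label!r}")
            rec = VariantRecord(
                gene_id=str(row.gene).strip(),
                position=int(row.position),
                ref_aa=str(row.ref),
                alt_aa=str(row.alt),
                label=label,
                source=str(path.name),
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
        if rec.key in seen:
            raise TableFormatError(
                f"{path}, line {i}: duplicate variant key {rec.key}"
            )
        seen.add(rec.key)
        records.append(rec)
    return records


def write_variant_table(records: list[VariantRecord], path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.position, r.ref_aa, r.alt_aa, r.label) for r in records],
        columns=["gene", "position", "ref", "alt", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    """Bookkeeping of what :func:`apply_dataset_filters` removed."""

    overlap_removed: list[tuple] = field(default_factory=list)
    genes_excluded: list[str] = field(default_factory=list)
    genes_retained: list[str] = field(default_factory=list)


def apply_dataset_filters(
    variants_p: list[VariantRecord],
    variants_b: list[VariantRecord],
    min_pathogenic: int = 70,
) -> tuple[dict[str, list[VariantRecord]], FilterReport]:
    """Apply the cohort-level curation rules to a pathogenic/benign pair.

    Benign variants whose key also appears in the pathogenic set are
    dropped (the two cohorts must be disjoint), and genes with fewer
    than ``min_pathogenic`` pathogenic variants are excluded entirely.
    Returns ``{gene_id: [records]}`` for the surviving genes plus a
    report of every removal.
    """
    report = FilterReport()
    p_keys = {r.key for r in variants_p}
    kept_b = []
    for r in variants_b:
        if r.key in p_keys:
            report.overlap_removed.append(r.key)
        else:
            kept_b.append(r)

    per_gene: dict[str, list[VariantRecord]] = {}
    for r in list(variants_p) + kept_b:
        per_gene.setdefault(r.gene_id, []).append(r)

    out: dict[str, list[VariantRecord]] = {}
    for gene in sorted(per_gene):
        n_path = sum(1 for r in per_gene[gene] if r.label == "pathogenic")
        if n_path >= min_pathogenic:
            out[gene] = per_gene[gene]
            report.genes_retained.append(gene)
        else:
            report.genes_excluded.append(gene)
    return out, report


def read_structure(path, chain: str | None = None, residue_offset: int = 0):
    """Read per-residue atom coordinates from a PDB file.

    Returns ``(coords, residue_names)`` where ``coords`` maps residue
    position -> {atom name: xyz} and ``residue_names`` maps position to
    the one-letter residue type. ``residue_offset`` is added to PDB
    residue numbers to reconcile them with protein positions. Altloc
    conflicts resolve to the highest-occupancy conformer (Biopython's
    convention, which matches ours).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"{path}: {len(chains)} chains present; select one explicitly"
            )
        chain_obj = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise ValueError(f"{path}: chain {chain!r} not found")
        chain_obj = chains[chain]

    coords: dict[int, dict[str, np.ndarray]] = {}
    names: dict[int, str] = {}
    for residue in chain_obj:
        hetflag, resseq, _icode = residue.id
        if hetflag.strip():
            continue  # skip waters/ligands
        pos = resseq + residue_offset
        one = AA3_TO_1.get(residue.get_resname())
        if one is None:
            continue
        atom_map: dict[str, np.ndarray] = {}
        for atom in residue:
            if atom.element == "H":
                continue
            atom_map[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        coords[pos] = atom_map
        names[pos] = one
    if not coords:
        warnings.warn(f"{path}: no standard residues parsed", stacklevel=2)
    return coords, names


def _validate_track_value(name: str, position: int, value):
    if name == "conservation":
        grade = int(value)
        if not 1 <= grade <= 9:
            raise TableFormatError(
                f"conservation grade {value} at position {position} not in 1..9"
            )
        return grade
    if name in _PROB_TRACKS:
        prob = float(value)
        if not 0.0 <= prob <= 1.0:
            raise TableFormatError(
                f"{name} value {value} at position {position} outside [0, 1]"
            )
        return prob
    if name == "secondary_structure":
        ss = str(value).strip().upper()
        if ss not in _SS_VALUES:
            raise TableFormatError(
                f"secondary structure {value!r} at position {position} "
                f"not in {sorted(_SS_VALUES)}"
            )
        return ss
    if name == "topology":
        topo = str(value).strip().lower()
        if topo not in _TOPOLOGY_VALUES:
            raise TableFormatError(
                f"topology {value!r} at position {position} "
                f"not in {sorted(_TOPOLOGY_VALUES)}"
            )
        return topo
    if name == "functional_site":
        s = str(value).strip().lower()
        if s in {"1", "true", "yes"}:
            return True
        if s in {"0", "false", "no"}:
            return False
        raise TableFormatError(
            f"functional_site value {value!r} at position {position} not boolean"
        )
    if name == "domain_id":
        return str(value).strip()
    raise TableFormatError(f"unknown track {name!r}")


def read_tracks(path) -> dict[str, dict[int, object]]:
    """Read a wide-format annotation-track TSV (``position`` + track columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "position" not in df.columns:
        raise TableFormatError(f"{path}: missing 'position' column")
    unknown = [c for c in df.columns if c != "position" and c not in TRACK_NAMES]
    if unknown:
        raise TableFormatError(f"{path}: unknown track columns {unknown}")
    tracks: dict[str, dict[int, object]] = {}
    for name in df.columns:
        if name == "position":
            continue
        track: dict[int, object] = {}
        for pos_str, value in zip(df["position"], df[name]):
            if _missing(value):
                continue
            pos = int(pos_str)
            track[pos] = _validate_track_value(name, pos, value)
        if track:
            tracks[name] = track
    return tracks


def write_tracks(tracks: dict[str, dict[int, object]], path, n_positions: int) -> None:
    rows = {"position": list(range(1, n_positions + 1))}
    for name in TRACK_NAMES:
        if name not in tracks:
            continue
        track = tracks[name]
        col = []
        for pos in rows["position"]:
            value = track.get(pos)
            if value is None:
                col.append("")
            elif isinstance(value, bool):
                col.append("1" if value else "0")
            else:
                col.append(value)
        rows[name] = col
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_score_table(path, tool_name: str = "", default_threshold: float = 0.5) -> ScoreTable:
    """Read an external predictor's score TSV (gene, position, ref, alt, score)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "position", "ref", "alt", "score"}
    if not required.issubset(df.columns):
        raise TableFormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    genes = df["gene"].unique()
    if len(genes) != 1:
        raise TableFormatError(f"{path}: expected a single gene, got {list(genes)}")
    entries: dict[tuple, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        score = float(row.score)
        if not 0.0 <= score <= 1.0:
            raise TableFormatError(
                f"{path}, line {i}: score {score} outside [0, 1]"
            )
        rec = VariantRecord(str(row.gene), int(row.position), row.ref, row.alt)
        if rec.key in entries:
            raise TableFormatError(f"{path}, line {i}: duplicate key {rec.key}")
        entries[rec.key] = score
    return ScoreTable(
        gene_id=str(genes[0]),
        tool_name=tool_name or path.stem,
        entries=entries,
        default_threshold=default_threshold,
    )


def write_score_table(table: ScoreTable, path) -> None:
    rows = [
        (gene, pos, ref, alt, f"{score:.6f}")
        for (gene, pos, ref, alt), score in table.entries.items()
    ]
    pd.DataFrame(rows, columns=["gene", "position", "ref", "alt", "score"]).to_csv(
        path, sep="\t", index=False
    )


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    """Write the per-variant feature matrix as TSV (floats round-trip exactly)."""
    features.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    return df
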