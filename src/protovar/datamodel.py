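"""Core in-memory containers for per-gene variant analysis.

The package revolves around three inputs per gene: a labelled variant
table (pathogenic vs benign missense changes at 1-based protein
positions), a protein context holding the sequence, any available 3D
coordinates and per-position annotation tracks, and score tables from
external predictors. Everything downstream (feature extraction, model
training, threshold optimization) consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .aminoacids import CANONICAL_AA, validate_aa

LABELS = ("pathogenic", "benign", "unknown")

# Annotation tracks a ProteinContext may carry, with their value domains.
TRACK_NAMES = (
    "conservation",      # ConSurf-style grade, integer 1..9 (9 = most conserved)
    "disorder_prob",     # per-residue disorder probability in [0, 1]
    "stability_effect",  # probability the site affects protein stability, [0, 1]
    "ppi_effect",        # probability the site affects a protein interaction, [0, 1]
    "secondary_structure",  # H / E / C
    "domain_id",         # free-text domain name, or missing
    "topology",          # extracellular / transmembrane / cytoplasmic / unknown
    "functional_site",   # boolean
)


@dataclass(frozen=True)
class VariantRecord:
    """One missense substitution on a protein."""

    gene_id: str
    position: int          # 1-based protein residue index
    ref_aa: str
    alt_aa: str
    label: str = "unknown"
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "ref_aa", validate_aa(self.ref_aa))
        object.__setattr__(self, "alt_aa", validate_aa(self.alt_aa))
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"{self.gene_id} p.{self.position}: ref and alt residues are "
                f"both {self.ref_aa}; not a missense change"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene_id, self.position, self.ref_aa, self.alt_aa)


@dataclass
class ProteinContext:
    """Per-gene container of sequence, structure and annotation tracks.

    ``coords`` maps 1-based residue position to a dict of atom name ->
    xyz coordinate (angstrom, numpy array of shape (3,)). ``tracks`` maps
    track name to a ``{position: value}`` dict; a track may be absent
    entirely, and a present track may lack values at some positions.
    """

    gene_id: str
    sequence: str
    coords: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    tracks: dict[str, dict[int, Any]] = field(default_factory=dict)

    @property
    def modelled_positions(self) -> set[int]:
        return set(self.coords)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside 1..{len(self.sequence)} "
                f"for {self.gene_id}"
            )
        return self.sequence[position - 1]

    def track_value(self, name: str, position: int):
        """Track value at ``position`` or None; raises if out of range."""
        self.residue(position)  # range check
        track = self.tracks.get(name)
        if track is None:
            return None
        return track.get(position)

    def validate(self) -> None:
        n = len(self.sequence)
        for aa in self.sequence:
            if aa not in CANONICAL_AA:
                raise ValueError(f"{self.gene_id}: non-canonical residue {aa!r}")
        bad = [p for p in self.coords if not 1 <= p <= n]
        if bad:
            raise ValueError(
                f"{self.gene_id}: modelled positions {bad} outside 1..{n}"
            )
        for name, track in self.tracks.items():
            out = [p for p in track if not 1 <= p <= n]
            if out:
                raise ValueError(
                    f"{self.gene_id}: track {name!r} has positions {out} "
                    f"outside 1..{n}"
                )


@dataclass
class ScoreTable:
    """Scores from one external predictor for the variants of one gene."""

    gene_id: str
    tool_name: str
    entries: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    default_threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.default_threshold <= 1.0:
            raise ValueError("default threshold must lie in [0, 1]")
        for key, score in self.entries.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score {score} for {key} outside [0, 1]")

    def score_of(self, variant: VariantRecord) -> float | None:
        return self.entries.get(variant.key)


@dataclass
class WeightedDataset:
    """Feature matrix with binary labels and per-instance weights.

    ``X`` is an (n, p) float array; categorical features are integer
    codes, missing values are NaN. ``y`` holds 1 = pathogenic,
    0 = benign. Weights start at 1 and are rescaled by class balancing.
    """

    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.y = np.asarray(self.y, dtype=int)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.X) == len(self.y) == len(self.w)):
            raise ValueError("X, y and w must have equal length")
        if np.any(self.w <= 0):
            raise ValueError("instance weights must be positive")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "WeightedDataset":
        idx = np.asarray(idx)
        return WeightedDataset(
            self.X[idx], self.y[idx], self.w[idx], list(self.feature_names)
        )
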