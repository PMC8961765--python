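"""Sequence-level variant features.

Covers the physicochemical and conservation components of the feature
catalogue: the Richards-scale residue volume change, the strong
hydrophobic/polar transition, formal-charge change, the conservation
grade lookup, and the special residue rules (proline onto a strand,
glycine in the core, cysteine in extracellular regions).
"""

from __future__ import annotations

from dataclasses import dataclass

from .aminoacids import CHARGE, RICHARDS_VOLUME, STRONG_HYDROPHOBIC, validate_aa
from .datamodel import ProteinContext, VariantRecord

#: |volume change| (A^3) at or above which a substitution counts as a
#: large increase/decrease — roughly one aliphatic-carbon step.
VOLUME_CATEGORY_CUTOFF = 40.0


@dataclass(frozen=True)
class ResiduePropertyTable:
    """Overridable physicochemical property tables."""

    volume: dict = None
    hydrophobic_strong: frozenset = STRONG_HYDROPHOBIC
    charge: dict = None

    def __post_init__(self):
        object.__setattr__(self, "volume", dict(self.volume or RICHARDS_VOLUME))
        object.__setattr__(self, "charge", dict(self.charge or CHARGE))
        if len(self.hydrophobic_strong) != 7:
            raise ValueError("the strong hydrophobic set must contain 7 residues")


DEFAULT_PROPERTIES = ResiduePropertyTable()


def volume_change(
    ref_aa: str,
    alt_aa: str,
    table: ResiduePropertyTable = DEFAULT_PROPERTIES,
    cutoff: float = VOLUME_CATEGORY_CUTOFF,
) -> tuple[float, str]:
    """Signed residue-volume difference (alt − ref, A^3) and its category.

    Category is ``large_increase`` / ``large_decrease`` when the absolute
    change reaches ``cutoff``, else ``small``.
    """
    ref_aa, alt_aa = validate_aa(ref_aa), validate_aa(alt_aa)
    delta = table.volume[alt_aa] - table.volume[ref_aa]
    if delta >= cutoff:
        category = "large_increase"
    elif delta <= -cutoff:
        category = "large_decrease"
    else:
        category = "small"
    return delta, category


def hydrophobicity_transition(
    ref_aa: str, alt_aa: str, table: ResiduePropertyTable = DEFAULT_PROPERTIES
) -> str:
    """Transition between the strong hydrophobic set and everything else.

    Returns ``hydrophobic_to_polar``, ``polar_to_hydrophobic`` or ``none``.
    """
    ref_aa, alt_aa = validate_aa(ref_aa), validate_aa(alt_aa)
    ref_h = ref_aa in table.hydrophobic_strong
    alt_h = alt_aa in table.hydrophobic_strong
    if ref_h and not alt_h:
        return "hydrophobic_to_polar"
    if alt_h and not ref_h:
        return "polar_to_hydrophobic"
    return "none"


def charge_change(
    ref_aa: str, alt_aa: str, table: ResiduePropertyTable = DEFAULT_PROPERTIES
) -> bool:
    """True iff the substitution changes the side-chain formal charge class."""
    return table.charge[validate_aa(ref_aa)] != table.charge[validate_aa(alt_aa)]


def conservation_lookup(position: int, context: ProteinContext):
    """Conservation grade (1–9) at ``position``; None when unannotated.

    Raises ``IndexError`` for positions outside the sequence (1-based).
    """
    return context.track_value("conservation", position)


def special_rules(
    variant: VariantRecord,
    context: ProteinContext,
    secondary_structure: str | None,
    burial: str | None,
) -> dict[str, bool]:
    """The three special physicochemical residue rules.

    * proline introduced at a β-strand position,
    * glycine gained or lost at a buried (core) position,
    * cysteine gained or lost in an extracellular region (potential
      disulfide disruption).

    A missing prerequisite (no secondary structure, burial or topology
    annotation) makes the corresponding flag False; missingness is the
    caller's to record.
    """
    topology = context.track_value("topology", variant.position)
    return {
        "proline_into_strand": variant.alt_aa == "P" and secondary_structure == "E",
        "glycine_core_change": (
            ("G" in (variant.ref_aa, variant.alt_aa)) and burial == "buried"
        ),
        "cysteine_extracellular_change": (
            ("C" in (variant.ref_aa, variant.alt_aa))
            and topology == "extracellular"
        ),
    }
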