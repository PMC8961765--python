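"""Structure-derived variant features.

Side-chain relative solvent accessibility (Shrake–Rupley, normalized by
extended-tripeptide reference areas), burial categories, the molecular
goodness-of-fit flag, a dihedral-based secondary-structure fallback,
modelled status, disorder flags and 3D/sequence clustering of pathogenic
variants.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

from .aminoacids import AA1_TO_3, BACKBONE_ATOMS, SIDECHAIN_REF_ASA
from .datamodel import ProteinContext, VariantRecord

PROBE_RADIUS = 1.4      # angstrom, water-sized probe
SASA_N_POINTS = 300     # sphere points per atom (quadrature noise ~1 A^2)
BURIED_MAX = 9.0        # rel SASA (%) below which a site is buried
EXPOSED_MIN = 36.0      # rel SASA (%) above which a site is exposed
CLUSTER_RADIUS = 8.0    # angstrom, C-alpha to C-alpha
CLUSTER_SEQ_WINDOW = 5  # residues, sequence-space clustering window
DISORDER_CUTOFF = 0.5
FIT_VOLUME_CUTOFF = 40.0  # A^3 volume gain that cannot fit a buried site


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _build_entity(coords: dict[int, dict[str, np.ndarray]],
                  residue_names: dict[int, str]):
    """Assemble a Bio.PDB model from a coordinate map for SASA computation."""
    builder = StructureBuilder()
    builder.init_structure("x")
    builder.init_model(0)
    builder.init_chain("A")
    builder.init_seg("    ")
    for pos in sorted(coords):
        resname = AA1_TO_3.get(residue_names.get(pos, "A"), "ALA")
        builder.init_residue(resname, " ", pos, " ")
        for serial, (name, xyz) in enumerate(coords[pos].items(), start=1):
            builder.init_atom(
                name, np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                name.center(4), serial, element=_element_of(name),
            )
    return builder.get_structure()[0]


def _sidechain_areas(coords, residue_names, probe_radius, n_points,
                     warn_missing=False) -> dict[int, float]:
    """Raw Shrake–Rupley side-chain areas (A^2) per residue."""
    model = _build_entity(coords, residue_names)
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(
        model, level="A"
    )
    areas: dict[int, float] = {}
    for residue in model["A"]:
        pos = residue.id[1]
        aa = residue_names.get(pos, "A")
        side = [a for a in residue if a.get_name() not in BACKBONE_ATOMS]
        if aa == "G" or not side:
            if warn_missing and aa != "G" and not side:
                warnings.warn(
                    f"residue {pos} ({aa}) has no side-chain atoms; "
                    "using the C-alpha convention", stacklevel=2,
                )
            side = [a for a in residue if a.get_name() == "CA"]
        if not side:
            continue
        areas[pos] = float(sum(a.sasa for a in side))
    return areas


def sidechain_sasa_percent(
    coords: dict[int, dict[str, np.ndarray]],
    residue_names: dict[int, str],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = SASA_N_POINTS,
    reference: str = "isolated",
) -> dict[int, float]:
    """Relative side-chain solvent accessibility for every modelled residue.

    Shrake–Rupley accessible surface area of the side-chain atoms
    (probe 1.4 A), normalized to percent by a per-residue reference
    accessibility. Glycine (and any residue whose side-chain atoms are
    absent) falls back to the C-alpha convention.

    Two reference conventions are available:

    * ``isolated`` (default) — the same residue's side-chain area with
      all other residues removed, computed by the same engine with the
      same parameters. Self-consistent for any atom representation
      (full side chains or reduced ones), so a residue with no
      neighbours scores 100%.
    * ``tripeptide`` — classic fixed extended Ala-X-Ala reference
      areas; appropriate for full-atom structures only.
    """
    if not coords:
        return {}
    ctx_areas = _sidechain_areas(coords, residue_names, probe_radius,
                                 n_points, warn_missing=True)
    if reference == "tripeptide":
        refs = {
            pos: SIDECHAIN_REF_ASA[
                "G" if "CB" not in coords[pos] else residue_names.get(pos, "A")
            ]
            for pos in ctx_areas
        }
    elif reference == "isolated":
        # one extra computation with residues exploded far apart, so no
        # residue occludes any other
        offsets = {
            pos: np.array([1000.0 * i, 0.0, 0.0])
            for i, pos in enumerate(sorted(coords))
        }
        exploded = {
            pos: {name: xyz + offsets[pos] for name, xyz in atoms.items()}
            for pos, atoms in coords.items()
        }
        refs = _sidechain_areas(exploded, residue_names, probe_radius,
                                n_points)
    else:
        raise ValueError("reference must be 'isolated' or 'tripeptide'")
    out: dict[int, float] = {}
    for pos, area in ctx_areas.items():
        ref = refs.get(pos, 0.0)
        if ref > 0:
            out[pos] = 100.0 * area / ref
    return out


def compute_rel_sasa(context: ProteinContext, position: int,
                     **kwargs) -> float | None:
    """Relative side-chain SASA (%) at one position; None if unmodelled."""
    if position not in context.coords:
        return None
    cache_key = "_sasa_cache"
    cache = getattr(context, cache_key, None)
    if cache is None:
        names = {p: context.sequence[p - 1] for p in context.coords
                 if p <= len(context.sequence)}
        cache = sidechain_sasa_percent(context.coords, names, **kwargs)
        setattr(context, cache_key, cache)
    return cache.get(position)


def burial_category(
    rel_sasa: float | None,
    buried_max: float = BURIED_MAX,
    exposed_min: float = EXPOSED_MIN,
) -> str | None:
    """Map relative SASA to buried (<9%), intermediate (9–36%], exposed (>36%)."""
    if rel_sasa is None:
        return None
    if rel_sasa < 0:
        raise ValueError(f"relative SASA cannot be negative: {rel_sasa}")
    if rel_sasa < buried_max:
        return "buried"
    if rel_sasa <= exposed_min:
        return "intermediate"
    return "exposed"


def goodness_of_fit(
    ref_aa: str,
    alt_aa: str,
    burial: str | None,
    volume_delta: float,
    cutoff: float = FIT_VOLUME_CUTOFF,
) -> bool:
    """Molecular goodness-of-fit violation: a larger residue in a buried site.

    True iff the site is buried and the substitution adds more than
    ``cutoff`` cubic angstroms of side-chain volume. Missing burial
    yields False (missingness is the caller's to record).
    """
    return burial == "buried" and volume_delta > cutoff


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


_H_PHI, _H_PSI = (-100.0, -30.0), (-80.0, -5.0)
_E_PHI, _E_PSI = (-180.0, -80.0), (60.0, 180.0)


def assign_secondary_structure(context: ProteinContext) -> dict[int, str]:
    """Per-position secondary structure {H, E, C}.

    The annotation track wins when present. Otherwise a simple
    geometric fallback classifies each residue from its backbone
    phi/psi dihedrals: helical windows sustained over runs of >= 4
    residues become H, extended windows over runs of >= 3 become E,
    everything else C. Positions without both flanking residues (or
    without coordinates at all) are left unassigned.
    """
    track = context.tracks.get("secondary_structure")
    if track:
        return dict(track)
    coords = context.coords
    if not coords:
        return {}

    raw: dict[int, str] = {}
    for pos in sorted(coords):
        prev, here, nxt = coords.get(pos - 1), coords[pos], coords.get(pos + 1)
        if prev is None or nxt is None:
            raw[pos] = "C"
            continue
        try:
            phi = dihedral(prev["C"], here["N"], here["CA"], here["C"])
            psi = dihedral(here["N"], here["CA"], here["C"], nxt["N"])
        except KeyError:
            raw[pos] = "C"
            continue
        if _H_PHI[0] < phi < _H_PHI[1] and _H_PSI[0] < psi < _H_PSI[1]:
            raw[pos] = "H"
        elif _E_PHI[0] < phi < _E_PHI[1] and _E_PSI[0] < psi < _E_PSI[1]:
            raw[pos] = "E"
        else:
            raw[pos] = "C"

    # enforce minimum run lengths (H >= 4, E >= 3); short runs revert to C
    min_run = {"H": 4, "E": 3}
    out: dict[int, str] = {}
    positions = sorted(raw)
    i = 0
    while i < len(positions):
        j = i
        while (
            j + 1 < len(positions)
            and positions[j + 1] == positions[j] + 1
            and raw[positions[j + 1]] == raw[positions[i]]
        ):
            j += 1
        label = raw[positions[i]]
        run = j - i + 1
        final = label if run >= min_run.get(label, 1) else "C"
        for k in range(i, j + 1):
            out[positions[k]] = final
        i = j + 1
    return out


def modelled_status(position: int, context: ProteinContext) -> bool:
    """True iff the position is present in the structural model."""
    return position in context.modelled_positions


def cluster3d_count(
    variant: VariantRecord,
    pathogenic_variants: list[VariantRecord],
    coords: dict[int, dict[str, np.ndarray]],
    radius: float = CLUSTER_RADIUS,
) -> int | None:
    """Pathogenic neighbours within ``radius`` angstrom of the variant's C-alpha.

    Counts the distinct positions of *other* pathogenic variants (the
    variant's own record is always excluded, so the feature never
    encodes its own label). Returns None for unmodelled variants.
    """
    own = coords.get(variant.position)
    if own is None or "CA" not in own:
        return None
    own_ca = own["CA"]
    positions = {
        v.position
        for v in pathogenic_variants
        if v.key != variant.key and v.position in coords
        and "CA" in coords[v.position]
    }
    count = 0
    for pos in positions:
        if np.linalg.norm(coords[pos]["CA"] - own_ca) <= radius:
            count += 1
    return count


def cluster1d_count(
    variant: VariantRecord,
    pathogenic_variants: list[VariantRecord],
    window: int = CLUSTER_SEQ_WINDOW,
) -> int:
    """Pathogenic neighbours within ±``window`` residues along the sequence."""
    positions = {
        v.position for v in pathogenic_variants if v.key != variant.key
    }
    return sum(
        1 for pos in positions if abs(pos - variant.position) <= window
    )


def disordered_flag(
    position: int, context: ProteinContext, cutoff: float = DISORDER_CUTOFF
) -> bool | None:
    """True iff the disorder probability at ``position`` reaches ``cutoff``."""
    prob = context.track_value("disorder_prob", position)
    if prob is None:
        return None
    return prob >= cutoff
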