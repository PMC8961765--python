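"""Synthetic per-gene fixtures: structures, variant datasets, score tables.

Nothing here is downloaded or biophysically realistic; the generator
targets the *statistical* structure of real per-gene variant cohorts:

* toy PDB structures with controllable burial (ideal helices and
  strands built from textbook dihedrals, and a packed pseudo-globule
  whose interior residues are genuinely solvent-inaccessible);
* class-conditional variant datasets in which pathogenic variants sit
  preferentially at conserved, buried, clustered positions and benign
  variants at variable, exposed or unmodelled ones — with a null mode
  where the two classes are indistinguishable;
* external-predictor score tables drawn from class-conditional Beta
  distributions whose analytic density-crossing point is recorded as
  the ground-truth optimal threshold.

Everything is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from .aminoacids import AA1_TO_3, CANONICAL_AA
from .datamodel import ProteinContext, ScoreTable, VariantRecord
from .structfeat import sidechain_sasa_percent, burial_category

# ---------------------------------------------------------------------------
# toy structures

_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.53}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}

FOLDS = ("helix", "strand", "packed_globule")
_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-120.0, 130.0)}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF internal-to-Cartesian placement of atom d bonded to c."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * math.cos(angle),
        bond * math.cos(torsion) * math.sin(angle),
        bond * math.sin(torsion) * math.sin(angle),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_chain(n_residues: int, phi: float, psi: float, omega: float = 180.0):
    """Ideal backbone (N, CA, C, O, CB) with uniform phi/psi torsions."""
    coords: dict[int, dict[str, np.ndarray]] = {}
    # seed the first three backbone atoms
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(_ANGLE["N-CA-C"])
    C = CA + _BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(N, CA, C)]
    for _ in range(1, n_residues):
        prevN, prevCA, prevC = backbone[-1]
        Nn = _place_atom(prevN, prevCA, prevC, _BOND["C-N"],
                         _ANGLE["CA-C-N"], psi)
        CAn = _place_atom(prevCA, prevC, Nn, _BOND["N-CA"],
                          _ANGLE["C-N-CA"], omega)
        Cn = _place_atom(prevC, Nn, CAn, _BOND["CA-C"],
                         _ANGLE["N-CA-C"], phi)
        backbone.append((Nn, CAn, Cn))
    for i, (Ni, CAi, Ci) in enumerate(backbone, start=1):
        atoms = {"N": Ni, "CA": CAi, "C": Ci}
        # carbonyl oxygen in the peptide plane, CB roughly tetrahedral
        if i < n_residues:
            next_n = backbone[i][0]
            atoms["O"] = _place_atom(next_n, CAi, Ci, _BOND["C-O"],
                                     _ANGLE["CA-C-O"], 180.0)
        else:
            atoms["O"] = _place_atom(Ni, CAi, Ci, _BOND["C-O"],
                                     _ANGLE["CA-C-O"], 0.0)
        atoms["CB"] = _place_atom(Ci, Ni, CAi, _BOND["CA-CB"], 110.5, 122.5)
        coords[i] = atoms
    return coords


def _globule_chain(n_residues: int, seed: int, spacing: float = 5.2):
    """Residues packed onto a lattice ball so interior sites are buried."""
    rng = np.random.default_rng(seed)
    radius = spacing * ((3.0 * n_residues) / (4.0 * math.pi)) ** (1.0 / 3.0) + spacing
    pts = []
    r = int(math.ceil(radius / spacing))
    for ix in range(-r, r + 1):
        for iy in range(-r, r + 1):
            for iz in range(-r, r + 1):
                p = spacing * np.array([ix, iy, iz], dtype=float)
                if np.linalg.norm(p) <= radius:
                    pts.append(p)
    pts.sort(key=lambda p: (np.linalg.norm(p), p[0], p[1], p[2]))
    pts = pts[:n_residues]
    if len(pts) < n_residues:
        raise ValueError("lattice ball too small; increase radius")
    order = rng.permutation(n_residues)
    coords: dict[int, dict[str, np.ndarray]] = {}
    for pos, idx in enumerate(order, start=1):
        c = pts[idx]
        jitter = rng.normal(0.0, 0.15, size=(5, 3))
        coords[pos] = {
            "N": c + np.array([-1.2, 0.0, 0.0]) + jitter[0],
            "CA": c + jitter[1],
            "C": c + np.array([1.2, 0.0, 0.0]) + jitter[2],
            "O": c + np.array([1.8, 1.0, 0.0]) + jitter[3],
            "CB": c + np.array([0.0, 1.4, 0.8]) + jitter[4],
        }
    return coords


def coords_to_pdb(coords: dict[int, dict[str, np.ndarray]],
                  residue_names: dict[int, str], chain: str = "A") -> str:
    """Render a coordinate map as PDB ATOM records."""
    lines = []
    serial = 1
    for pos in sorted(coords):
        res3 = AA1_TO_3[residue_names[pos]]
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in coords[pos]:
                continue
            x, y, z = coords[pos][name]
            element = name[0]
            name_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {name_field} {res3} {chain}{pos:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_structure(n_residues: int, fold: str = "helix", seed: int = 0,
                       sequence: str | None = None):
    """Generate a toy structure; returns ``(pdb_text, coords, sequence)``.

    Folds: ``helix`` (phi −57°, psi −47°), ``strand`` (phi −120°,
    psi 130°) — both with ideal backbone geometry so the dihedral
    fallback recovers them — and ``packed_globule``, a lattice-packed
    ball with genuinely buried interior residues.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    if fold not in FOLDS:
        raise ValueError(f"fold must be one of {FOLDS}")
    rng = np.random.default_rng(seed)
    if sequence is None:
        # glycine-free so every residue keeps its CB side-chain proxy
        alphabet = [aa for aa in CANONICAL_AA if aa != "G"]
        sequence = "".join(rng.choice(alphabet, size=n_residues))
    if fold == "packed_globule":
        coords = _globule_chain(n_residues, seed)
    else:
        phi, psi = _PHI_PSI[fold]
        coords = _backbone_chain(n_residues, phi, psi)
    names = {i + 1: sequence[i] for i in range(n_residues)}
    return coords_to_pdb(coords, names), coords, sequence


# ---------------------------------------------------------------------------
# gene datasets

@dataclass(frozen=True)
class EffectProfile:
    """Class-conditional distributions of the simulated annotation signal.

    Probabilities refer to the position a variant of that class lands
    on; Beta parameters describe per-position track values at those
    positions. The defaults give a clearly separable but imperfect
    signal; :meth:`null` collapses both classes onto the benign
    distributions so downstream models should score MCC ≈ 0.
    """

    cons_high_path: float = 0.9     # P(conservation grade 8-9) at pathogenic sites
    cons_high_benign: float = 0.2
    buried_path: float = 0.6        # P(choosing a buried position)
    buried_benign: float = 0.1
    unmodelled_benign: float = 0.3  # P(benign variant on an unmodelled position)
    unmodelled_path: float = 0.05
    disorder_path: tuple = (1.0, 6.0)    # Beta(a, b) per class
    disorder_benign: tuple = (3.0, 3.0)
    stability_path: tuple = (5.0, 2.0)
    stability_benign: tuple = (2.0, 5.0)
    ppi_path: tuple = (3.0, 3.0)
    ppi_benign: tuple = (2.0, 6.0)
    functional_site_path: float = 0.3
    functional_site_benign: float = 0.05
    #: probability of rejecting a position already owned by the other
    #: class; positional class segregation is what makes the clustering
    #: features informative, so the null profile removes it entirely
    position_coherence: float = 0.9

    def null(self) -> "EffectProfile":
        """Identical class distributions (no signal)."""
        return EffectProfile(
            position_coherence=0.0,
            cons_high_path=self.cons_high_benign,
            cons_high_benign=self.cons_high_benign,
            buried_path=self.buried_benign,
            buried_benign=self.buried_benign,
            unmodelled_benign=self.unmodelled_benign,
            unmodelled_path=self.unmodelled_benign,
            disorder_path=self.disorder_benign,
            disorder_benign=self.disorder_benign,
            stability_path=self.stability_benign,
            stability_benign=self.stability_benign,
            ppi_path=self.ppi_benign,
            ppi_benign=self.ppi_benign,
            functional_site_path=self.functional_site_benign,
            functional_site_benign=self.functional_site_benign,
        )


@dataclass(frozen=True)
class GeneSimSpec:
    """Recipe for one synthetic gene."""

    gene_id: str = "SYNG1"
    n_pathogenic: int = 80
    n_benign: int = 40
    seq_length: int = 200
    unmodelled_fraction: float = 0.2
    effect: EffectProfile = field(default_factory=EffectProfile)
    score_beta_path: tuple = (8.0, 2.0)
    score_beta_benign: tuple = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_pathogenic, self.n_benign) <= 0:
            raise ValueError("variant counts must be positive")
        if not 0.0 <= self.unmodelled_fraction < 1.0:
            raise ValueError("unmodelled_fraction must be in [0, 1)")


def simulate_gene_dataset(spec: GeneSimSpec):
    """Generate ``(variants, context, pdb_text)`` for one synthetic gene.

    The modelled region is the head of the sequence (a packed globule);
    the tail (``unmodelled_fraction``) has no coordinates, exercising
    the modelled/unmodelled dichotomy. Pathogenic variants favour
    conserved/buried positions, benign variants variable/exposed or
    unmodelled ones, per the effect profile.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length
    n_modelled = max(5, int(round(L * (1.0 - spec.unmodelled_fraction))))
    alphabet = [aa for aa in CANONICAL_AA if aa != "G"]
    sequence = "".join(rng.choice(alphabet, size=L))
    _, coords, _ = make_toy_structure(
        n_modelled, "packed_globule", seed=spec.seed + 1,
        sequence=sequence[:n_modelled],
    )
    names = {p: sequence[p - 1] for p in coords}
    pdb_text = coords_to_pdb(coords, names)

    sasa = sidechain_sasa_percent(coords, names)
    buried = sorted(p for p, s in sasa.items()
                    if burial_category(s) == "buried")
    exposed = sorted(p for p, s in sasa.items()
                     if burial_category(s) == "exposed")
    modelled = sorted(coords)
    unmodelled = [p for p in range(1, L + 1) if p not in coords]

    eff = spec.effect

    def pick_position(is_path: bool) -> int:
        # identical sampling scheme for both classes; only the
        # probabilities differ, so a null profile is exactly null
        unmod_p = eff.unmodelled_path if is_path else eff.unmodelled_benign
        buried_p = eff.buried_path if is_path else eff.buried_benign
        if unmodelled and rng.random() < unmod_p:
            return int(rng.choice(unmodelled))
        if buried and rng.random() < buried_p:
            return int(rng.choice(buried))
        return int(rng.choice(exposed or modelled))

    variants: list[VariantRecord] = []
    used: set[tuple] = set()
    class_of_position: dict[int, str] = {}
    for label, count in (("pathogenic", spec.n_pathogenic),
                         ("benign", spec.n_benign)):
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 100 * count:
                raise RuntimeError("could not place variants; spec too tight")
            pos = pick_position(label == "pathogenic")
            ref = sequence[pos - 1]
            alt = str(rng.choice([aa for aa in CANONICAL_AA if aa != ref]))
            key = (spec.gene_id, pos, ref, alt)
            if key in used:
                continue
            # positions may host variants of both classes (as in real
            # cohorts), but mostly stay class-coherent: the first owner
            # decides the position's annotation tracks, so a variant
            # usually avoids positions owned by the other class
            owner = class_of_position.get(pos)
            if (owner is not None and owner != label
                    and rng.random() < eff.position_coherence):
                continue
            class_of_position.setdefault(pos, label)
            used.add(key)
            variants.append(VariantRecord(spec.gene_id, pos, ref, alt,
                                          label, source="simulated"))
            made += 1

    # per-position tracks, class-conditional at variant positions
    conservation: dict[int, int] = {}
    disorder: dict[int, float] = {}
    stability: dict[int, float] = {}
    ppi: dict[int, float] = {}
    functional: dict[int, bool] = {}
    for pos in range(1, L + 1):
        owner = class_of_position.get(pos)
        if owner == "pathogenic":
            high = rng.random() < eff.cons_high_path
            d_a, d_b = eff.disorder_path
            s_a, s_b = eff.stability_path
            p_a, p_b = eff.ppi_path
            fs = eff.functional_site_path
        else:
            high = rng.random() < eff.cons_high_benign
            d_a, d_b = eff.disorder_benign
            s_a, s_b = eff.stability_benign
            p_a, p_b = eff.ppi_benign
            fs = eff.functional_site_benign
        conservation[pos] = int(rng.integers(8, 10)) if high \
            else int(rng.integers(1, 8))
        disorder[pos] = float(np.clip(rng.beta(d_a, d_b), 0.0, 1.0))
        stability[pos] = float(np.clip(rng.beta(s_a, s_b), 0.0, 1.0))
        ppi[pos] = float(np.clip(rng.beta(p_a, p_b), 0.0, 1.0))
        functional[pos] = bool(rng.random() < fs)

    third = max(1, L // 3)
    topology = {
        pos: ("extracellular" if pos <= third
              else "transmembrane" if pos <= 2 * third else "cytoplasmic")
        for pos in range(1, L + 1)
    }
    domain = {pos: ("DOM1" if pos <= L // 2 else "DOM2")
              for pos in range(1, L + 1)}

    context = ProteinContext(
        gene_id=spec.gene_id,
        sequence=sequence,
        coords=coords,
        tracks={
            "conservation": conservation,
            "disorder_prob": disorder,
            "stability_effect": stability,
            "ppi_effect": ppi,
            "functional_site": functional,
            "topology": topology,
            "domain_id": domain,
        },
    )
    context.validate()
    return variants, context, pdb_text


# ---------------------------------------------------------------------------
# score tables

def beta_crossing_point(beta_path: tuple, beta_benign: tuple) -> float:
    """Interior crossing of the two Beta densities (the Bayes threshold
    under equal priors). Found by root-finding on the log-density
    difference; symmetric pairs cross at 0.5."""
    a1, b1 = beta_path
    a0, b0 = beta_benign

    def logdiff(x):
        return beta_dist.logpdf(x, a1, b1) - beta_dist.logpdf(x, a0, b0)

    lo, hi = 1e-6, 1.0 - 1e-6
    grid = np.linspace(lo, hi, 1001)
    vals = logdiff(grid)
    if np.all(vals == 0.0):
        raise ValueError("identical densities have no crossing point")
    zeros = np.flatnonzero(vals == 0.0)
    sign_changes = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if len(sign_changes) == 0 and len(zeros) == 0:
        raise ValueError("densities do not cross in (0, 1)")
    # prefer the crossing where the pathogenic density overtakes the
    # benign one (log-difference going from negative to positive)
    for i in sign_changes:
        if vals[i] < 0 < vals[i + 1]:
            return float(brentq(logdiff, grid[i], grid[i + 1]))
    if len(zeros):
        return float(grid[zeros[0]])
    i = sign_changes[0]
    return float(brentq(logdiff, grid[i], grid[i + 1]))


def simulate_score_table(
    n_path: int,
    n_benign: int,
    beta_path: tuple = (8.0, 2.0),
    beta_benign: tuple = (2.0, 8.0),
    seed: int = 0,
    gene_id: str = "SYNG1",
    tool_name: str = "synthtool",
    default_threshold: float = 0.5,
):
    """Class-conditional Beta scores with a known optimal threshold.

    Returns ``(table, labels_by_key, crossing)`` where ``crossing`` is
    the analytic density-crossing point recorded as ground truth.
    """
    rng = np.random.default_rng(seed)
    entries: dict[tuple, float] = {}
    labels: dict[tuple, str] = {}
    pos = 1
    for label, count, (a, b) in (
        ("pathogenic", n_path, beta_path),
        ("benign", n_benign, beta_benign),
    ):
        for _ in range(count):
            score = float(np.clip(rng.beta(a, b), 0.0, 1.0))
            key = (gene_id, pos, "A", "V")
            entries[key] = score
            labels[key] = label
            pos += 1
    table = ScoreTable(gene_id=gene_id, tool_name=tool_name,
                       entries=entries, default_threshold=default_threshold)
    try:
        crossing = beta_crossing_point(beta_path, beta_benign)
    except ValueError:
        crossing = None  # indistinguishable classes: no optimal threshold
    return table, labels, crossing


def score_table_for_variants(
    variants: list[VariantRecord],
    beta_path: tuple = (8.0, 2.0),
    beta_benign: tuple = (2.0, 8.0),
    seed: int = 0,
    tool_name: str = "synthtool",
    default_threshold: float = 0.5,
) -> ScoreTable:
    """Beta-distributed predictor scores keyed by real variant records."""
    rng = np.random.default_rng(seed)
    entries: dict[tuple, float] = {}
    for v in variants:
        a, b = beta_path if v.label == "pathogenic" else beta_benign
        entries[v.key] = float(np.clip(rng.beta(a, b), 0.0, 1.0))
    gene_id = variants[0].gene_id if variants else "SYNG1"
    return ScoreTable(gene_id=gene_id, tool_name=tool_name, entries=entries,
                      default_threshold=default_threshold)


def score_arrays_from_table(table: ScoreTable, labels: dict[tuple, str]):
    """Flatten a simulated table into (scores, y) arrays."""
    keys = sorted(table.entries)
    scores = np.array([table.entries[k] for k in keys])
    y = np.array([1 if labels[k] == "pathogenic" else 0 for k in keys])
    return scores, y


# ---------------------------------------------------------------------------
# the default multi-gene panel

def default_panel(n_genes: int = 21, seed: int = 0,
                  effect: EffectProfile | None = None) -> list[GeneSimSpec]:
    """Panel of gene specs spanning a realistic cohort-size envelope:
    pathogenic counts 70–600, benign 15–200 per gene."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_genes):
        n_path = int(rng.integers(70, 601))
        n_benign = int(rng.integers(15, 201))
        seq_length = int(rng.integers(150, 401))
        specs.append(GeneSimSpec(
            gene_id=f"SYNG{i + 1}",
            n_pathogenic=n_path,
            n_benign=n_benign,
            seq_length=seq_length,
            unmodelled_fraction=float(rng.uniform(0.05, 0.35)),
            effect=effect or EffectProfile(),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs


def shuffled_labels(variants: list[VariantRecord], seed: int = 0):
    """Label-permuted copy of a variant list (null-calibration helper)."""
    rng = np.random.default_rng(seed)
    labels = [v.label for v in variants]
    rng.shuffle(labels)
    return [replace(v, label=lab) for v, lab in zip(variants, labels)]
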