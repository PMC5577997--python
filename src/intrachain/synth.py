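"""Seeded synthetic single-chain structures with ground-truth manifests.

These generators are the test substrate for the detectors: two-residue ion
pairs whose minimum charged O..N distance is set by construction, ideal
alpha-helices whose backbone H-bond ladder is known in advance, ortholog
trios with planted conserved/private salt bridges, and random chains for
oracle fuzzing.  Every generated distance keeps a guard band of 0.2 A away
from the default detection cutoffs so floating-point noise can never flip
an expectation.  Generation is a pure function of its arguments and seed.

Side chains use idealized internal geometry (standard bond lengths, planar
zigzag angles); conformational realism beyond charged-group placement is a
non-goal.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from .interactions import ACIDIC_CHARGED, BASIC_CHARGED, SaltBridgeCriteria
from .model import Atom, Chain, Residue, Structure

DEFAULT_SB_CUTOFF = 4.0
GUARD_BAND = 0.2


@dataclass(frozen=True)
class PlantedInteraction:
    kind: str                    # hbond | saltbridge
    residue_pair: tuple[int, int]
    designed_distance: float
    expect_detected: bool


@dataclass
class SyntheticSpec:
    n_residues: int = 30
    planted: list[PlantedInteraction] = field(default_factory=list)
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma >= GUARD_BAND / 3:
            raise ValueError("jitter_sigma must stay below a third of the guard band")


# ---------------------------------------------------------------------------
# Local residue templates.
#
# Frame convention: the "anchor" charged atom sits at the origin and its bond
# from the antecedent points along +x, so that after mirroring through the
# yz-plane two templates face each other head-on and the anchor pair is
# strictly the closest charged contact.

_ZIG = 0.86   # planar zigzag: 1.52 A bonds at ~111 deg give (dx, dy) = (1.25, 0.86)


def _acid_template(name: str) -> dict[str, tuple[float, float, float]]:
    o1 = "OD1" if name == "ASP" else "OE1"
    o2 = "OD2" if name == "ASP" else "OE2"
    carbox = "CG" if name == "ASP" else "CD"
    atoms = {
        o1: (0.0, 0.0, 0.0),
        carbox: (-1.25, 0.0, 0.0),
        o2: (-1.93, 1.05, 0.0),
    }
    x, y = -1.25, 0.0
    chain = ["CG", "CB"] if name == "GLU" else ["CB"]
    sign = -1.0
    for cname in chain:
        x -= 1.25
        y += sign * _ZIG
        atoms[cname] = (x, y, 0.0)
        sign = -sign
    x -= 1.25
    y += sign * _ZIG
    atoms["CA"] = (x, y, 0.0)
    atoms["N"] = (x - 1.20, y - 0.83, 0.0)
    atoms["C"] = (x - 0.51, y - 0.17, 1.43)
    atoms["O"] = (x - 0.51, y - 0.47, 2.60)
    return atoms


def _lys_template() -> dict[str, tuple[float, float, float]]:
    atoms = {"NZ": (0.0, 0.0, 0.0), "CE": (-1.49, 0.0, 0.0)}
    x, y, sign = -1.49, 0.0, -1.0
    for cname in ("CD", "CG", "CB", "CA"):
        x -= 1.25
        y += sign * _ZIG
        atoms[cname] = (x, y, 0.0)
        sign = -sign
    atoms["N"] = (x - 1.20, y - 0.83, 0.0)
    atoms["C"] = (x - 0.51, y - 0.17, 1.43)
    atoms["O"] = (x - 0.51, y - 0.47, 2.60)
    return atoms


def _arg_template() -> dict[str, tuple[float, float, float]]:
    atoms = {
        "NH1": (0.0, 0.0, 0.0),
        "CZ": (-1.33, 0.0, 0.0),
        "NH2": (-2.00, 1.15, 0.0),
        "NE": (-2.00, -1.15, 0.0),
        "CD": (-3.25, -1.90, 0.0),
    }
    x, y, sign = -3.25, -1.90, 1.0
    for cname in ("CG", "CB", "CA"):
        x -= 1.25
        y += sign * _ZIG
        atoms[cname] = (x, y, 0.0)
        sign = -sign
    atoms["N"] = (x - 1.20, y - 0.83, 0.0)
    atoms["C"] = (x - 0.51, y - 0.17, 1.43)
    atoms["O"] = (x - 0.51, y - 0.47, 2.60)
    return atoms


def _his_template() -> dict[str, tuple[float, float, float]]:
    # imidazole as a regular pentagon, circumradius 1.16 (side ~1.37);
    # ring order NE2-CE1-ND1-CG-CD2, anchor NE2 pointing +x
    cx = -1.16
    ring = {}
    for aname, deg in (("NE2", 0), ("CE1", 72), ("ND1", 144),
                       ("CG", 216), ("CD2", 288)):
        ring[aname] = (cx + 1.16 * math.cos(math.radians(deg)),
                       1.16 * math.sin(math.radians(deg)), 0.0)
    gx, gy, _ = ring["CG"]
    atoms = dict(ring)
    atoms["CB"] = (gx - 1.23, gy - 0.90, 0.0)
    atoms["CA"] = (gx - 2.48, gy - 0.04, 0.0)
    atoms["N"] = (gx - 3.68, gy - 0.87, 0.0)
    atoms["C"] = (gx - 2.99, gy - 0.21, 1.43)
    atoms["O"] = (gx - 2.99, gy - 0.51, 2.60)
    return atoms


def _ala_template() -> dict[str, tuple[float, float, float]]:
    return {
        "N": (0.0, 0.0, 0.0),
        "CA": (1.46, 0.0, 0.0),
        "C": (2.06, 1.37, 0.0),
        "O": (3.27, 1.50, 0.20),
        "CB": (2.26, -1.20, 0.50),
    }


_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "ASP": _acid_template("ASP"),
    "GLU": _acid_template("GLU"),
    "LYS": _lys_template(),
    "ARG": _arg_template(),
    "HIS": _his_template(),
    "ALA": _ala_template(),
    "GLY": {k: v for k, v in _ala_template().items() if k != "CB"},
    "SER": {**_ala_template(), "OG": (2.40, -2.45, 1.20)},
}

#: charged atom placed at the template origin, facing the partner
_ANCHOR = {"ASP": "OD1", "GLU": "OE1", "LYS": "NZ", "ARG": "NH1", "HIS": "NE2"}


def _build_residue(name: str, number: int,
                   offset: np.ndarray, mirror: bool = False) -> Residue:
    template = _TEMPLATES[name]
    atoms = []
    for aname, xyz in template.items():
        coords = np.array(xyz, dtype=float)
        if mirror:
            coords = coords * np.array([-1.0, 1.0, -1.0])  # proper rotation
        atoms.append(Atom(name=aname, element=aname[0], coords=coords + offset))
    return Residue(name=name, number=number, atoms=atoms)


# ---------------------------------------------------------------------------
# Generators

def make_ion_pair(separation: float, acidic: str = "GLU", basic: str = "LYS",
                  cutoff: float = DEFAULT_SB_CUTOFF,
                  ) -> tuple[Structure, list[PlantedInteraction]]:
    """Two-residue chain whose minimum charged O..N distance is `separation`.

    The acidic side chain faces +x, the basic side chain faces -x, so the
    facing anchor atoms are the unique closest charged pair by construction.
    """
    acidic, basic = acidic.upper(), basic.upper()
    if separation <= 2.0:
        raise ValueError("separation below 2.0 A is sterically meaningless")
    if acidic not in ACIDIC_CHARGED:
        raise ValueError(f"acidic residue must be Asp or Glu, got {acidic}")
    if basic not in BASIC_CHARGED:
        raise ValueError(f"basic residue must be Lys, Arg or His, got {basic}")
    res_a = _build_residue(acidic, 1, np.zeros(3))
    res_b = _build_residue(basic, 2, np.array([separation, 0.0, 0.0]), mirror=True)
    chain = Chain(id="A", residues=[res_a, res_b])
    structure = Structure(chains=[chain], source=f"synthetic:ion_pair:{separation:.2f}")

    # construction check: the designed contact must be the minimum
    acid_atoms = [a for a in res_a.atoms if a.name in ACIDIC_CHARGED[acidic]]
    base_atoms = [a for a in res_b.atoms if a.name in BASIC_CHARGED[basic]]
    dmin = min(x.distance(y) for x in acid_atoms for y in base_atoms)
    assert abs(dmin - separation) < 0.01, "anchor pair is not the closest contact"

    manifest = [PlantedInteraction(
        kind="saltbridge", residue_pair=(1, 2),
        designed_distance=separation,
        expect_detected=separation <= cutoff)]
    return structure, manifest


# ideal backbone internal coordinates
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def _place(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension reference frame placement of a fourth atom."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * math.cos(angle),
                  bond * math.sin(angle) * math.cos(torsion),
                  bond * math.sin(angle) * math.sin(torsion)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def make_helix(n_residues: int, phi: float = _PHI, psi: float = _PSI,
               ) -> tuple[Structure, list[PlantedInteraction]]:
    """Ideal poly-alanine alpha-helix; manifest lists the i -> i-4 backbone
    amide-to-carbonyl H-bond ladder (residues 5..n as donors)."""
    if n_residues < 5:
        raise ValueError("a helix fixture needs at least 5 residues")
    # stream N, CA, C positions by NeRF
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = bb[-1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        bb.append({"N": n_i, "CA": ca_i, "C": c_i})
    residues = []
    for i, atoms in enumerate(bb):
        o_i = _place(atoms["N"], atoms["CA"], atoms["C"], _B_C_O, _A_CA_C_O,
                     psi + 180.0)
        cb_i = _place(atoms["C"], atoms["N"], atoms["CA"], 1.521, 110.4, -122.5)
        residues.append(Residue(
            name="ALA", number=i + 1,
            atoms=[Atom("N", "N", atoms["N"]), Atom("CA", "C", atoms["CA"]),
                   Atom("C", "C", atoms["C"]), Atom("O", "O", o_i),
                   Atom("CB", "C", cb_i)]))
    structure = Structure(chains=[Chain(id="A", residues=residues)],
                          source=f"synthetic:helix:{n_residues}")
    manifest = []
    for i in range(5, n_residues + 1):
        donor_n = residues[i - 1].atom("N")
        acceptor_o = residues[i - 5].atom("O")
        manifest.append(PlantedInteraction(
            kind="hbond", residue_pair=(i, i - 4),
            designed_distance=round(donor_n.distance(acceptor_o), 3),
            expect_detected=True))
    return structure, manifest


def make_ortholog_trio(spec: SyntheticSpec | None = None,
                       shared: int = 2,
                       private_per_species: tuple[int, int, int] = (1, 1, 1),
                       decoys: int = 0,
                       species: tuple[str, str, str] = ("sp1", "sp2", "sp3"),
                       ) -> tuple[dict[str, Structure], dict]:
    """Three single-chain 'orthologs' with planted salt bridges.

    `shared` bridges are planted identically (same residue types, numbers and
    geometry) in all three chains; each species additionally gets its own
    private bridges; `decoys` plants identical above-cutoff ion pairs that no
    detector should report.  Residue numbering is shared across the trio.
    Returns the structures and the ground-truth partition
    {"conserved": [...], "unique": {species: [...]}} as pair-label texts.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n_pairs = shared + sum(private_per_species) + decoys
    if 2 * n_pairs > spec.n_residues:
        raise ValueError("not enough residues to host the planted pairs")

    spacing = 16.0
    slots = list(range(0, 2 * n_pairs, 2))   # consecutive residue-index pairs

    def draw_pair_types() -> tuple[str, str]:
        return (str(rng.choice(["ASP", "GLU"])),
                str(rng.choice(["LYS", "ARG", "HIS"])))

    def draw_sep(detectable: bool) -> float:
        if detectable:
            return float(rng.uniform(2.8, DEFAULT_SB_CUTOFF - GUARD_BAND))
        return float(rng.uniform(DEFAULT_SB_CUTOFF + GUARD_BAND, 6.0))

    # plan: slot -> (kind, owner) where owner is None for shared/decoys
    plan: list[tuple[str, str | None, tuple[str, str], float]] = []
    for _ in range(shared):
        plan.append(("shared", None, draw_pair_types(), draw_sep(True)))
    for sp, count in zip(species, private_per_species):
        for _ in range(count):
            plan.append(("private", sp, draw_pair_types(), draw_sep(True)))
    for _ in range(decoys):
        plan.append(("decoy", None, draw_pair_types(), draw_sep(False)))

    structures: dict[str, Structure] = {}
    truth = {"conserved": [], "unique": {sp: [] for sp in species}}
    three_letter_title = {"ASP": "Asp", "GLU": "Glu",
                          "LYS": "Lys", "ARG": "Arg", "HIS": "His"}
    for i, (kind, owner, (acid, base), sep) in enumerate(plan):
        if kind == "decoy":
            continue
        label = (f"{three_letter_title[acid]}{slots[i] + 1}"
                 f"||{three_letter_title[base]}{slots[i] + 2}")
        if kind == "shared":
            truth["conserved"].append(label)
        else:
            truth["unique"][owner].append(label)

    for sp in species:
        residues: list[Residue] = []
        planted_here: dict[int, tuple[str, str, float]] = {}
        for slot_idx, (kind, owner, types, sep) in enumerate(plan):
            if kind == "private" and owner != sp:
                continue
            planted_here[slots[slot_idx]] = (*types, sep)
        idx = 0
        while idx < spec.n_residues:
            base_pos = np.array([spacing * idx, 0.0, 0.0])
            if idx in planted_here:
                acid, base, sep = planted_here[idx]
                residues.append(_build_residue(acid, idx + 1, base_pos))
                residues.append(_build_residue(
                    base, idx + 2, base_pos + np.array([sep, 0.0, 0.0]),
                    mirror=True))
                idx += 2
            else:
                residues.append(_build_residue("ALA", idx + 1, base_pos))
                idx += 1
        chain = Chain(id="A", residues=residues, species_tag=sp)
        st = Structure(chains=[chain], source=f"synthetic:trio:{sp}:{spec.seed}")
        if spec.jitter_sigma > 0:
            st = perturb(st, spec.jitter_sigma, seed=spec.seed + 1)
        structures[sp] = st
    return structures, truth


#: residue pool for oracle-fuzzing chains; charged types over-represented so
#: that contacts actually occur
_RANDOM_POOL = ["ASP", "GLU", "LYS", "ARG", "HIS",
                "ASP", "GLU", "LYS", "ARG", "ALA", "GLY", "SER"]


def make_random_chain(seed: int, n_residues: int = 30,
                      density: float = 5.0) -> Structure:
    """Seeded random chain for detector-vs-oracle comparison.

    Residues are randomly typed and randomly rotated/translated inside a box
    sized for roughly `density` A per residue per axis.  The geometry is not
    physically meaningful; it exists to exercise every code path of the
    geometric detectors against an exhaustive reference implementation.
    """
    rng = np.random.default_rng(seed)
    box = density * n_residues ** (1.0 / 3.0)
    residues = []
    for i in range(n_residues):
        name = str(rng.choice(_RANDOM_POOL))
        # random proper rotation from QR decomposition
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        offset = rng.uniform(0.0, box, size=3)
        template = _TEMPLATES[name]
        atoms = [Atom(aname, aname[0], q @ np.array(xyz) + offset)
                 for aname, xyz in template.items()]
        residues.append(Residue(name=name, number=i + 1, atoms=atoms))
    chain = Chain(id="A", residues=residues)
    return Structure(chains=[chain], source=f"synthetic:random:{seed}")


def perturb(structure: Structure, sigma: float, seed: int = 0) -> Structure:
    """Isotropic Gaussian coordinate noise of scale sigma (A), seeded."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return structure
    rng = np.random.default_rng(seed)
    from dataclasses import replace
    chains = []
    for ch in structure.chains:
        residues = []
        for res in ch.residues:
            atoms = [replace(a, coords=a.coords + rng.normal(0.0, sigma, 3))
                     for a in res.atoms]
            residues.append(replace(res, atoms=atoms))
        chains.append(replace(ch, residues=residues))
    return replace(structure, chains=chains)


def write_manifest(path, planted: list[PlantedInteraction]) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(p) for p in planted], fh, indent=2)
        fh.write("\n")


def default_criteria() -> SaltBridgeCriteria:
    return SaltBridgeCriteria(max_no_distance=DEFAULT_SB_CUTOFF)
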