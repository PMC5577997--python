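"""Geometric enumeration of intrachain hydrogen bonds and salt bridges.

Salt bridges follow the classical side-chain criterion: a bridge exists
between an Asp/Glu and a Lys/Arg/His residue when the minimum distance
between any charged carboxylate oxygen and any charged amine/guanidinium/
imidazolium nitrogen is at or below a cutoff (4.0 A by default, the
Barlow-Thornton convention).  One record is emitted per residue pair.

Hydrogen bonds are counted per donor-atom/acceptor-atom pair.  Homology
models and most crystal structures carry no hydrogens, so polar hydrogens
with unambiguous geometry (backbone amides, Arg/Asn/Gln/Trp/His side-chain
N-H) are inferred in-plane; rotatable donors (Ser/Thr/Tyr hydroxyls, Lys
NZ, Cys SG) are evaluated with a stricter heavy-atom-only criterion.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, Chain, Residue

# ---------------------------------------------------------------------------
# Criteria

@dataclass(frozen=True)
class HBondCriteria:
    """Distance/angle thresholds for hydrogen-bond acceptance.

    max_da          donor..acceptor heavy-atom distance ceiling (A)
    max_ha          hydrogen..acceptor distance ceiling (A), when H is known
    min_dha_angle   donor-H-acceptor angle floor (degrees)
    min_daa_angle   donor-acceptor-antecedent angle floor (degrees), used in
                    the heavy-atom-only fallback for ambiguous donors
    heavy_only_max_da  stricter D..A ceiling for the fallback (A)
    """

    max_da: float = 3.9
    max_ha: float = 2.5
    min_dha_angle: float = 90.0
    min_daa_angle: float = 90.0
    heavy_only_max_da: float = 3.5

    def __post_init__(self) -> None:
        for name in ("max_da", "max_ha", "heavy_only_max_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_dha_angle", "min_daa_angle"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must lie in [0, 180] degrees")


@dataclass(frozen=True)
class SaltBridgeCriteria:
    max_no_distance: float = 4.0
    include_his: bool = True
    include_termini: bool = False

    def __post_init__(self) -> None:
        if self.max_no_distance <= 0:
            raise ValueError("max_no_distance must be positive")


# ---------------------------------------------------------------------------
# Interaction records

AtomRef = tuple[Residue, Atom]


@dataclass(frozen=True)
class HBond:
    donor: tuple[str, int, str, str]      # (resname, resnum, icode, atom)
    acceptor: tuple[str, int, str, str]
    hydrogen: tuple[str, int, str, str] | None
    d_da: float
    d_ha: float | None
    angle_dha: float | None


@dataclass(frozen=True)
class SaltBridge:
    acidic: tuple[str, int]   # (resname, resnum)
    basic: tuple[str, int]
    min_distance: float
    closest_atom_pair: tuple[str, str]


# ---------------------------------------------------------------------------
# Chemistry tables

ACIDIC_CHARGED = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_CHARGED = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

#: side-chain donor heavy atoms per residue type
SIDECHAIN_DONORS = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

#: side-chain acceptor heavy atoms (N/O lone-pair bearers)
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

#: rotatable donors whose hydrogen position cannot be inferred from heavy atoms
ROTATABLE_DONORS = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("LYS", "NZ"), ("CYS", "SG"),
}

#: heavy-atom antecedents (covalent neighbours) of polar atoms, within a residue
_ANTECEDENTS = {
    "O": ("C",), "OXT": ("C",),
    "OD1": ("CG",), "OD2": ("CG",), "ND2": ("CG",),
    "OE1": ("CD",), "OE2": ("CD",), "NE2": ("CD",),  # GLN; HIS overrides below
    "OG": ("CB",), "OG1": ("CB",), "SG": ("CB",),
    "OH": ("CZ",),
    "NZ": ("CE",),
    "NE": ("CD", "CZ"), "NH1": ("CZ",), "NH2": ("CZ",),
    "NE1": ("CD1", "CE2"),
}
_ANTECEDENTS_BY_RES = {
    ("HIS", "ND1"): ("CG", "CE1"),
    ("HIS", "NE2"): ("CD2", "CE1"),
}


def antecedent_names(resname: str, atom_name: str) -> tuple[str, ...]:
    if (resname, atom_name) in _ANTECEDENTS_BY_RES:
        return _ANTECEDENTS_BY_RES[(resname, atom_name)]
    if atom_name == "N":
        return ("CA",)  # the preceding C is handled positionally
    return _ANTECEDENTS.get(atom_name, ())


def charged_atoms(residue: Residue, criteria: SaltBridgeCriteria) -> list[str]:
    """Names of the residue's charged side-chain atoms that are present."""
    if residue.name in ACIDIC_CHARGED:
        wanted = ACIDIC_CHARGED[residue.name]
    elif residue.name == "HIS":
        wanted = BASIC_CHARGED["HIS"] if criteria.include_his else ()
    elif residue.name in BASIC_CHARGED:
        wanted = BASIC_CHARGED[residue.name]
    else:
        wanted = ()
    present = {a.name for a in residue.atoms}
    return [n for n in wanted if n in present]


# ---------------------------------------------------------------------------
# Geometry helpers

def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = a - b
    v2 = c - b
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0:
        return 0.0
    cosang = float(np.clip(np.dot(v1, v2) / denom, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _is_basic(res: Residue, criteria: SaltBridgeCriteria) -> bool:
    if res.name == "HIS":
        return criteria.include_his
    return res.name in BASIC_CHARGED


# ---------------------------------------------------------------------------
# Salt-bridge detection

def detect_salt_bridges(chain: Chain, criteria: SaltBridgeCriteria | None = None) -> list[SaltBridge]:
    """All intrachain salt bridges, one record per (acidic, basic) residue pair.

    A pair qualifies when the minimum charged O..N distance is at or below
    ``criteria.max_no_distance``.  Output is sorted by (acidic number,
    basic number).  A chain lacking acidic or basic residues yields [].
    """
    criteria = criteria or SaltBridgeCriteria()
    acidics: list[tuple[Residue, list[Atom]]] = []
    basics: list[tuple[Residue, list[Atom]]] = []
    for res in chain.residues:
        names = charged_atoms(res, criteria)
        if not names:
            continue
        atoms = [a for a in res.atoms if a.name in names]
        if res.name in ACIDIC_CHARGED:
            acidics.append((res, atoms))
        else:
            basics.append((res, atoms))
    if criteria.include_termini and chain.residues:
        first, last = chain.residues[0], chain.residues[-1]
        n_atom = first.atom("N")
        if n_atom is not None:
            basics.append((first, [n_atom]))
        oxt = last.atom("OXT")
        if oxt is not None:
            acidics.append((last, [oxt]))
    if not acidics or not basics:
        return []

    basic_atoms = [(bi, a) for bi, (_, atoms) in enumerate(basics) for a in atoms]
    tree = cKDTree(np.array([a.coords for _, a in basic_atoms]))

    best: dict[tuple[int, int], tuple[float, str, str]] = {}
    for ai, (ares, aatoms) in enumerate(acidics):
        for aatom in aatoms:
            for idx in tree.query_ball_point(aatom.coords, criteria.max_no_distance):
                bi, batom = basic_atoms[idx]
                if basics[bi][0] is ares:
                    continue  # a terminal group cannot bridge to its own residue
                d = aatom.distance(batom)
                if d > criteria.max_no_distance:
                    continue
                key = (ai, bi)
                if key not in best or d < best[key][0]:
                    best[key] = (d, aatom.name, batom.name)

    bridges = [
        SaltBridge(
            acidic=(acidics[ai][0].name, acidics[ai][0].number),
            basic=(basics[bi][0].name, basics[bi][0].number),
            min_distance=round(d, 6),
            closest_atom_pair=(an, bn),
        )
        for (ai, bi), (d, an, bn) in best.items()
    ]
    bridges.sort(key=lambda b: (b.acidic[1], b.basic[1], b.acidic[0], b.basic[0]))
    return bridges


# ---------------------------------------------------------------------------
# Hydrogen inference

def infer_polar_hydrogens(chain: Chain) -> tuple[Chain, dict[tuple[int, str, str], str]]:
    """Add inferable polar hydrogens; flag every donor 'placed' or 'ambiguous'.

    Backbone amide H sits in the C(prev)-N-CA plane on the external bisector
    at N-H = 1.0 A; side-chain N-H with rigid geometry are placed the same
    way (bisector for two antecedents, anti to the single antecedent for
    terminal amide/guanidinium N).  Rotatable donors are left without H.
    Returns (chain copy with H appended, {(resnum, icode, donor): flag}).
    """
    flags: dict[tuple[int, str, str], str] = {}
    new_residues: list[Residue] = []
    prev_c: np.ndarray | None = None
    for res in chain.residues:
        atoms = list(res.atoms)
        placed: list[Atom] = []

        def place(donor: Atom, refs: list[np.ndarray], h_name: str) -> None:
            vecs = [donor.coords - r for r in refs]
            norms = [np.linalg.norm(v) for v in vecs]
            if any(n == 0 for n in norms):
                flags[(res.number, res.icode, donor.name)] = "ambiguous"
                return
            direction = np.sum([v / n for v, n in zip(vecs, norms)], axis=0)
            dn = np.linalg.norm(direction)
            if dn == 0:
                flags[(res.number, res.icode, donor.name)] = "ambiguous"
                return
            placed.append(Atom(name=h_name, element="H",
                               coords=donor.coords + direction / dn * 1.0))
            flags[(res.number, res.icode, donor.name)] = "placed"

        # backbone amide
        n_atom = res.atom("N")
        if n_atom is not None and res.name != "PRO":
            ca = res.atom("CA")
            if prev_c is None or ca is None:
                flags[(res.number, res.icode, "N")] = "ambiguous"
            else:
                place(n_atom, [prev_c, ca.coords], "H")

        # side-chain donors
        for dname in SIDECHAIN_DONORS.get(res.name, ()):
            donor = res.atom(dname)
            if donor is None:
                continue
            if (res.name, dname) in ROTATABLE_DONORS:
                flags[(res.number, res.icode, dname)] = "ambiguous"
                continue
            ants = [res.atom(a) for a in antecedent_names(res.name, dname)]
            ants = [a for a in ants if a is not None]
            if not ants:
                flags[(res.number, res.icode, dname)] = "ambiguous"
                continue
            place(donor, [a.coords for a in ants], "H" + dname[1:] if dname != "N" else "H")

        c_atom = res.atom("C")
        prev_c = c_atom.coords if c_atom is not None else None
        new_residues.append(replace(res, atoms=atoms + placed))
    return replace(chain, residues=new_residues), flags


# ---------------------------------------------------------------------------
# Hydrogen-bond detection

def _bond_graph(chain: Chain) -> dict[int, set[int]]:
    """Covalent adjacency over heavy atoms, inferred from distance (< 1.8 A,
    2.1 A when sulfur is involved).  Atom identity = index into the flat list."""
    flat: list[Atom] = [a for res in chain.residues for a in res.atoms
                        if a.element != "H"]
    if not flat:
        return {}
    coords = np.array([a.coords for a in flat])
    tree = cKDTree(coords)
    adj: dict[int, set[int]] = {i: set() for i in range(len(flat))}
    for i, j in tree.query_pairs(2.1):
        cutoff = 2.1 if "S" in (flat[i].element, flat[j].element) else 1.8
        if math.dist(coords[i], coords[j]) <= cutoff:
            adj[i].add(j)
            adj[j].add(i)
    return adj


def detect_hbonds(chain: Chain, criteria: HBondCriteria | None = None) -> list[HBond]:
    """All intrachain hydrogen bonds, one record per donor-atom/acceptor-atom pair.

    With a known or inferred H: accept when d(D,A) <= max_da, d(H,A) <= max_ha
    and angle D-H-A >= min_dha_angle.  For ambiguous donors: accept when
    d(D,A) <= heavy_only_max_da and every donor-acceptor-antecedent angle is
    >= min_daa_angle.  Covalent and 1-3 pairs and intra-residue pairs are
    excluded.
    """
    criteria = criteria or HBondCriteria()
    if not chain.residues:
        return []

    has_h = any(a.element == "H" for res in chain.residues for a in res.atoms)
    if has_h:
        work, flags = chain, {}
    else:
        work, flags = infer_polar_hydrogens(chain)

    # flat indexing of heavy atoms for the covalent-exclusion graph
    heavy: list[tuple[Residue, Atom]] = [(res, a) for res in work.residues
                                         for a in res.atoms if a.element != "H"]
    index = {id(a): i for i, (_, a) in enumerate(heavy)}
    adj = _bond_graph(work)

    def excluded(i: int, j: int) -> bool:
        if j in adj[i]:
            return True
        return bool(adj[i] & adj[j])  # 1-3: shared covalent neighbour

    # donors with their hydrogens
    donors: list[tuple[Residue, Atom, list[Atom], bool]] = []
    for res in work.residues:
        donor_names = []
        if res.name != "PRO" and res.atom("N") is not None:
            donor_names.append("N")
        donor_names += [d for d in SIDECHAIN_DONORS.get(res.name, ())
                        if res.atom(d) is not None]
        for dname in donor_names:
            datom = res.atom(dname)
            hs = [a for a in res.atoms
                  if a.element == "H" and a.distance(datom) <= 1.25]
            if has_h:
                ambiguous = not hs
            else:
                ambiguous = flags.get((res.number, res.icode, dname)) != "placed"
                if ambiguous:
                    hs = []
            donors.append((res, datom, hs, ambiguous))

    # acceptors
    acceptors: list[tuple[Residue, Atom]] = []
    for res in work.residues:
        names = ["O"] + (["OXT"] if res.atom("OXT") is not None else [])
        names += list(SIDECHAIN_ACCEPTORS.get(res.name, ()))
        for aname in names:
            aatom = res.atom(aname)
            if aatom is not None:
                acceptors.append((res, aatom))
    if not donors or not acceptors:
        return []

    acc_tree = cKDTree(np.array([a.coords for _, a in acceptors]))
    out: list[HBond] = []
    seen: set[tuple[int, int]] = set()
    for dres, datom, hs, ambiguous in donors:
        for ai in acc_tree.query_ball_point(datom.coords, criteria.max_da):
            ares, aatom = acceptors[ai]
            if ares is dres:
                continue
            di, aj = index[id(datom)], index[id(aatom)]
            if (di, aj) in seen or excluded(di, aj):
                continue
            d_da = datom.distance(aatom)
            if d_da > criteria.max_da:
                continue
            hit: HBond | None = None
            if not ambiguous and hs:
                best = None
                for h in hs:
                    d_ha = h.distance(aatom)
                    ang = _angle(datom.coords, h.coords, aatom.coords)
                    if d_ha <= criteria.max_ha and ang >= criteria.min_dha_angle:
                        if best is None or d_ha < best[0]:
                            best = (d_ha, ang, h)
                if best is not None:
                    d_ha, ang, h = best
                    hit = HBond(
                        donor=(dres.name, dres.number, dres.icode, datom.name),
                        acceptor=(ares.name, ares.number, ares.icode, aatom.name),
                        hydrogen=(dres.name, dres.number, dres.icode, h.name),
                        d_da=round(d_da, 6), d_ha=round(d_ha, 6),
                        angle_dha=round(ang, 6))
            else:
                if d_da <= criteria.heavy_only_max_da:
                    ants = [ares.atom(n) for n in antecedent_names(ares.name, aatom.name)]
                    ants = [a for a in ants if a is not None]
                    if ants and all(
                        _angle(datom.coords, aatom.coords, a.coords) >= criteria.min_daa_angle
                        for a in ants
                    ):
                        hit = HBond(
                            donor=(dres.name, dres.number, dres.icode, datom.name),
                            acceptor=(ares.name, ares.number, ares.icode, aatom.name),
                            hydrogen=None, d_da=round(d_da, 6),
                            d_ha=None, angle_dha=None)
            if hit is not None:
                seen.add((di, aj))
                out.append(hit)
    out.sort(key=lambda b: (b.donor[1], b.donor[2], b.donor[3],
                            b.acceptor[1], b.acceptor[2], b.acceptor[3]))
    return out


def count_profile(chain: Chain,
                  hb: HBondCriteria | None = None,
                  sb: SaltBridgeCriteria | None = None) -> tuple[int, int]:
    """(hydrogen-bond count, salt-bridge count) for one chain."""
    return (len(detect_hbonds(chain, hb)), len(detect_salt_bridges(chain, sb)))


# ---------------------------------------------------------------------------
# Export

def interactions_to_rows(hbonds: Iterable[HBond],
                         bridges: Iterable[SaltBridge]) -> list[dict]:
    rows = []
    for hb in hbonds:
        rows.append({
            "type": "hbond",
            "residue_1": f"{hb.donor[0]}{hb.donor[1]}{hb.donor[2]}",
            "residue_2": f"{hb.acceptor[0]}{hb.acceptor[1]}{hb.acceptor[2]}",
            "atom_1": hb.donor[3], "atom_2": hb.acceptor[3],
            "distance_A": f"{hb.d_da:.3f}",
        })
    for sb in bridges:
        rows.append({
            "type": "saltbridge",
            "residue_1": f"{sb.acidic[0]}{sb.acidic[1]}",
            "residue_2": f"{sb.basic[0]}{sb.basic[1]}",
            "atom_1": sb.closest_atom_pair[0], "atom_2": sb.closest_atom_pair[1],
            "distance_A": f"{sb.min_distance:.3f}",
        })
    return rows


def write_interactions_tsv(path, hbonds, bridges) -> None:
    rows = interactions_to_rows(hbonds, bridges)
    header = ["type", "residue_1", "residue_2", "atom_1", "atom_2", "distance_A"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in header) + "\n")


def write_interactions_json(path, hbonds, bridges,
                            hb_criteria: HBondCriteria,
                            sb_criteria: SaltBridgeCriteria) -> None:
    payload = {
        "criteria": {"hbond": asdict(hb_criteria), "saltbridge": asdict(sb_criteria)},
        "interactions": interactions_to_rows(hbonds, bridges),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
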