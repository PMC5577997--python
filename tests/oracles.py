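"""Independent reference implementations used only to cross-check the package.

Everything here is written against the stated detection rules from scratch:
exhaustive all-pairs loops, no spatial indexing, plain-math angles (law of
cosines rather than vector arccos), and its own chemistry tables.  Shared
code with the package is limited to the data model and, for hydrogen-bond
checks, the hydrogen-placement preprocessing (the oracle verifies pair
enumeration and geometry, not H inference).
"""
from __future__ import annotations

import math
from functools import lru_cache

from intrachain.model import Chain

_ACID = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASE = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",), "SER": ("OG",), "THR": ("OG1",),
    "TRP": ("NE1",), "TYR": ("OH",), "CYS": ("SG",),
}
_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "HIS": ("ND1", "NE2"), "SER": ("OG",), "THR": ("OG1",),
    "TYR": ("OH",),
}
_ANTS = {
    ("*", "O"): ("C",), ("*", "OXT"): ("C",),
    ("ASP", "OD1"): ("CG",), ("ASP", "OD2"): ("CG",),
    ("GLU", "OE1"): ("CD",), ("GLU", "OE2"): ("CD",),
    ("ASN", "OD1"): ("CG",), ("GLN", "OE1"): ("CD",),
    ("SER", "OG"): ("CB",), ("THR", "OG1"): ("CB",), ("TYR", "OH"): ("CZ",),
    ("HIS", "ND1"): ("CG", "CE1"), ("HIS", "NE2"): ("CD2", "CE1"),
}


def _dist(a, b) -> float:
    return math.dist(tuple(a.coords), tuple(b.coords))


def _angle_law_of_cosines(a, b, c) -> float:
    """Angle at b from the three side lengths."""
    ab, bc, ac = _dist(a, b), _dist(b, c), _dist(a, c)
    if ab == 0 or bc == 0:
        return 0.0
    cosv = (ab * ab + bc * bc - ac * ac) / (2 * ab * bc)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def salt_bridges(chain: Chain, cutoff: float = 4.0,
                 include_his: bool = True) -> set[tuple]:
    """Exhaustive scan: {((acid name, num), (base name, num), min dist)}."""
    out = set()
    for ra in chain.residues:
        if ra.name not in _ACID:
            continue
        for rb in chain.residues:
            if rb.name not in _BASE:
                continue
            if rb.name == "HIS" and not include_his:
                continue
            dists = [
                _dist(x, y)
                for x in ra.atoms if x.name in _ACID[ra.name]
                for y in rb.atoms if y.name in _BASE[rb.name]
            ]
            if dists and min(dists) <= cutoff:
                out.add(((ra.name, ra.number), (rb.name, rb.number),
                         round(min(dists), 6)))
    return out


def _covalent_pairs(chain: Chain) -> set[frozenset]:
    heavy = [(res, a) for res in chain.residues for a in res.atoms
             if a.element != "H"]
    bonds = set()
    for i, (ri, ai) in enumerate(heavy):
        for rj, aj in heavy[i + 1:]:
            cut = 2.1 if "S" in (ai.element, aj.element) else 1.8
            if _dist(ai, aj) <= cut:
                bonds.add(frozenset({id(ai), id(aj)}))
    return bonds


def hbonds(chain: Chain, max_da: float = 3.9, max_ha: float = 2.5,
           min_dha: float = 90.0, min_daa: float = 90.0,
           heavy_only_max_da: float = 3.5) -> set[tuple]:
    """Exhaustive H-bond scan on a chain that already carries its polar H.

    Returns {(donor num, donor atom, acceptor num, acceptor atom)}.
    """
    bonds = _covalent_pairs(chain)
    neighbours: dict[int, set[int]] = {}
    for pair in bonds:
        x, y = tuple(pair)
        neighbours.setdefault(x, set()).add(y)
        neighbours.setdefault(y, set()).add(x)

    out = set()
    for rd in chain.residues:
        donor_names = []
        if rd.name != "PRO" and rd.atom("N") is not None:
            donor_names.append("N")
        donor_names += [n for n in _DONORS.get(rd.name, ())
                        if rd.atom(n) is not None]
        for dname in donor_names:
            d = rd.atom(dname)
            hs = [a for a in rd.atoms if a.element == "H" and _dist(a, d) <= 1.25]
            for ra in chain.residues:
                if ra is rd:
                    continue
                acc_names = ["O"] if ra.atom("O") is not None else []
                if ra.atom("OXT") is not None:
                    acc_names.append("OXT")
                acc_names += [n for n in _ACCEPTORS.get(ra.name, ())
                              if ra.atom(n) is not None]
                for aname in acc_names:
                    a = ra.atom(aname)
                    if frozenset({id(d), id(a)}) in bonds:
                        continue
                    if neighbours.get(id(d), set()) & neighbours.get(id(a), set()):
                        continue
                    d_da = _dist(d, a)
                    if d_da > max_da:
                        continue
                    ok = False
                    if hs:
                        for h in hs:
                            if (_dist(h, a) <= max_ha
                                    and _angle_law_of_cosines(d, h, a) >= min_dha):
                                ok = True
                    else:
                        if d_da <= heavy_only_max_da:
                            ant_names = _ANTS.get((ra.name, aname),
                                                  _ANTS.get(("*", aname), ()))
                            ants = [ra.atom(n) for n in ant_names]
                            ants = [x for x in ants if x is not None]
                            if ants and all(
                                _angle_law_of_cosines(d, a, x) >= min_daa
                                for x in ants):
                                ok = True
                    if ok:
                        out.add((rd.number, dname, ra.number, aname))
    return out


def global_alignment_score(seq_a: str, seq_b: str, matrix,
                           gap_open: float = -10.0,
                           gap_extend: float = -0.5) -> float:
    """Optimal global affine-gap alignment score by memoized recursion.

    The first residue of a gap scores gap_open, each further one gap_extend
    (the PairwiseAligner convention).  Feasible for short sequences only.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        options = []
        if i < len(seq_a) and j < len(seq_b):
            options.append(float(matrix[seq_a[i], seq_b[j]])
                           + best(i + 1, j + 1, "M"))
        if i < len(seq_a):   # gap in seq_b
            cost = gap_extend if state == "GB" else gap_open
            options.append(cost + best(i + 1, j, "GB"))
        if j < len(seq_b):   # gap in seq_a
            cost = gap_extend if state == "GA" else gap_open
            options.append(cost + best(i, j + 1, "GA"))
        return max(options)

    return best(0, 0, "M")
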