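"""Cross-species aggregation of interaction counts and salt-bridge pairs.

Per-chain counts are summed into species profiles; salt-bridge residue-pair
labels ("Glu184||Arg211" notation, acidic partner first) are matched across
orthologs by exact residue name + number and partitioned into conserved /
partially-shared / species-unique sets; species are ranked by their
interaction totals as a structural-stability proxy.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .interactions import SaltBridge, SaltBridgeCriteria, detect_salt_bridges
from .model import Chain
from .seqcomp import round_half_up

ACIDIC_NAMES = ("Asp", "Glu")
BASIC_NAMES = ("Lys", "Arg", "His")
CHAIN_TAGS = ("beta1", "beta2", "beta5")

_LABEL_RE = re.compile(
    r"^\s*([A-Za-z]{3})\s*(\d+)\s*\|\|\s*([A-Za-z]{3})\s*(\d+)\s*$")


class PairLabelError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class PairLabel:
    """A salt-bridge residue pair, acidic partner first."""
    acidic_name: str
    acidic_number: int
    basic_name: str
    basic_number: int

    @property
    def text(self) -> str:
        return (f"{self.acidic_name}{self.acidic_number}"
                f"||{self.basic_name}{self.basic_number}")


def parse_pair_label(text: str) -> PairLabel:
    """Parse 'Xxx<N>||Yyy<M>' (case/whitespace tolerant) into a PairLabel.

    Basic-first input is swapped into canonical acidic-first order; a pair
    of two acidic or two basic residues is a chemistry error.
    """
    m = _LABEL_RE.match(text)
    if m is None:
        raise PairLabelError(f"malformed pair label: {text!r}")
    name1, num1, name2, num2 = m.group(1).title(), int(m.group(2)), \
        m.group(3).title(), int(m.group(4))
    for name in (name1, name2):
        if name not in ACIDIC_NAMES and name not in BASIC_NAMES:
            raise PairLabelError(f"{text!r}: {name} is not a charged residue")
    first_acidic = name1 in ACIDIC_NAMES
    second_acidic = name2 in ACIDIC_NAMES
    if first_acidic and second_acidic:
        raise PairLabelError(f"{text!r}: both residues are acidic")
    if not first_acidic and not second_acidic:
        raise PairLabelError(f"{text!r}: both residues are basic")
    if first_acidic:
        return PairLabel(name1, num1, name2, num2)
    return PairLabel(name2, num2, name1, num1)


def pair_label_from_bridge(bridge: SaltBridge) -> PairLabel:
    return PairLabel(bridge.acidic[0].title(), bridge.acidic[1],
                     bridge.basic[0].title(), bridge.basic[1])


@dataclass
class PairSet:
    species: str
    chain: str                      # beta1 | beta2 | beta5 | other
    pairs: frozenset[PairLabel]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SpeciesProfile:
    """Per-chain interaction counts and species totals."""
    species: str
    per_chain: dict[str, tuple[int, int]]   # chain -> (hbonds, saltbridges)

    @property
    def totals(self) -> tuple[int, int]:
        hb = sum(v[0] for v in self.per_chain.values())
        sb = sum(v[1] for v in self.per_chain.values())
        return (hb, sb)

    def total(self, key: str) -> int:
        return self.totals[0] if key == "hbonds" else self.totals[1]


@dataclass
class ConservationPartition:
    species: tuple[str, ...]
    conserved: frozenset[PairLabel]
    unique: dict[str, frozenset[PairLabel]]
    shared_partial: dict[frozenset, frozenset]   # species subset -> pairs
    input_sets: dict[str, frozenset[PairLabel]] = field(default_factory=dict)

    def validate(self) -> None:
        """Disjoint-partition check: each species' set is exactly recovered."""
        for sp in self.species:
            rebuilt = set(self.conserved) | set(self.unique.get(sp, ()))
            for subset, pairs in self.shared_partial.items():
                if sp in subset:
                    rebuilt |= set(pairs)
            if rebuilt != set(self.input_sets[sp]):
                raise AssertionError(
                    f"partition does not recover the input set for {sp!r}")
        buckets = [self.conserved, *self.unique.values(), *self.shared_partial.values()]
        seen: set[PairLabel] = set()
        for b in buckets:
            # a pair may legitimately recur across species *sets*, but each
            # (pair, category) assignment must be unique
            seen |= set(b)

    def category_sizes(self) -> dict:
        return {
            "conserved": len(self.conserved),
            "unique": {sp: len(v) for sp, v in self.unique.items()},
            "shared_partial": {"/".join(sorted(k)): len(v)
                               for k, v in self.shared_partial.items()},
        }


@dataclass
class StabilityRanking:
    key: str                      # hbonds | saltbridges
    order: list[str]              # species labels, most stabilized first
    totals: dict[str, int]
    ties: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------

def ingest_pair_table(path: str | Path) -> list[PairSet]:
    """Read a TSV (species, chain, pair_label) into one PairSet per group.

    '-' or empty label cells are skipped; a duplicated pair within one
    (species, chain) group is an error.
    """
    groups: dict[tuple[str, str], list[PairLabel]] = {}
    order: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        required = {"species", "chain", "pair_label"}
        if not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            label_text = (row["pair_label"] or "").strip()
            if label_text in ("", "-"):
                continue
            label = parse_pair_label(label_text)
            key = (row["species"].strip(), row["chain"].strip())
            if key not in groups:
                groups[key] = []
                order.append(key)
            if label in groups[key]:
                raise ValueError(
                    f"{path}: duplicate pair {label.text} for species "
                    f"{key[0]!r} chain {key[1]!r}")
            groups[key].append(label)
    return [PairSet(species=sp, chain=ch, pairs=frozenset(groups[(sp, ch)]))
            for sp, ch in order]


def ingest_counts_table(path: str | Path) -> list[SpeciesProfile]:
    """Read a TSV (species, chain, hbonds, saltbridges) into SpeciesProfiles."""
    per_species: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"species", "chain", "hbonds", "saltbridges"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            sp = row["species"].strip()
            per_species.setdefault(sp, {})[row["chain"].strip()] = (
                int(row["hbonds"]), int(row["saltbridges"]))
    return [profile_from_counts(sp, chains) for sp, chains in per_species.items()]


def profile_from_counts(species: str,
                        per_chain: Mapping[str, tuple[int, int]]) -> SpeciesProfile:
    """Build a SpeciesProfile; totals are computed by summation."""
    for ch, (hb, sb) in per_chain.items():
        if hb < 0 or sb < 0:
            raise ValueError(f"{species}/{ch}: negative count")
    return SpeciesProfile(species=species, per_chain=dict(per_chain))


def diff_stats(profile_a: SpeciesProfile, profile_b: SpeciesProfile,
               key: str = "hbonds") -> tuple[int, float]:
    """(absolute difference, percent of the larger total, half-up 1 decimal)."""
    a, b = profile_a.total(key), profile_b.total(key)
    diff = abs(a - b)
    larger = max(a, b)
    pct = 0.0 if larger == 0 else round_half_up(100.0 * diff / larger, 1)
    return (diff, pct)


def conserved_partition(sets: Sequence[PairSet]) -> ConservationPartition:
    """Partition one chain's pair sets across >=2 species.

    conserved: present in every species; unique[s]: present only in s;
    shared_partial: present in >=2 species but not all.  Matching is exact
    residue name + number.
    """
    if len(sets) < 2:
        raise ValueError("need pair sets from at least two species")
    chains = {s.chain for s in sets}
    if len(chains) != 1:
        raise ValueError(f"mixed chain tags in partition input: {sorted(chains)}")
    species = tuple(s.species for s in sets)
    if len(set(species)) != len(species):
        raise ValueError("duplicate species in partition input")
    by_species = {s.species: s.pairs for s in sets}

    membership: dict[PairLabel, frozenset] = {}
    for sp, pairs in by_species.items():
        for p in pairs:
            membership[p] = membership.get(p, frozenset()) | {sp}

    all_species = frozenset(species)
    conserved = frozenset(p for p, m in membership.items() if m == all_species)
    unique = {sp: frozenset(p for p, m in membership.items() if m == {sp})
              for sp in species}
    shared: dict[frozenset, set] = {}
    for p, m in membership.items():
        if 1 < len(m) < len(all_species):
            shared.setdefault(m, set()).add(p)
    partition = ConservationPartition(
        species=species,
        conserved=conserved,
        unique=unique,
        shared_partial={k: frozenset(v) for k, v in shared.items()},
        input_sets=by_species,
    )
    partition.validate()
    return partition


def rank_stability(profiles: Sequence[SpeciesProfile],
                   key: str = "saltbridges") -> StabilityRanking:
    """Order species by descending interaction totals; ties broken by label."""
    if not profiles:
        raise ValueError("need at least one species profile")
    if key not in ("hbonds", "saltbridges"):
        raise ValueError("key must be 'hbonds' or 'saltbridges'")
    totals = {p.species: p.total(key) for p in profiles}
    order = sorted(totals, key=lambda sp: (-totals[sp], sp))
    ties = [(a, b) for a, b in zip(order, order[1:]) if totals[a] == totals[b]]
    return StabilityRanking(key=key, order=order, totals=totals, ties=ties)


def crosslink_with_detection(chains: Mapping[str, Chain],
                             sb: SaltBridgeCriteria | None = None,
                             chain_tag: str = "other") -> ConservationPartition:
    """End-to-end pipeline: detect bridges per species chain, label, partition."""
    sets = []
    for species, chain in chains.items():
        bridges = detect_salt_bridges(chain, sb)
        labels = frozenset(pair_label_from_bridge(b) for b in bridges)
        sets.append(PairSet(species=species, chain=chain_tag, pairs=labels))
    return conserved_partition(sets)
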