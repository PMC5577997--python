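"""Pair labels, ingestion, partitioning, diff statistics and ranking."""
import pytest
from hypothesis import given, settings, strategies as st

from intrachain import synth
from intrachain.compare import (
    PairLabel,
    PairLabelError,
    PairSet,
    conserved_partition,
    crosslink_with_detection,
    diff_stats,
    ingest_pair_table,
    parse_pair_label,
    profile_from_counts,
    rank_stability,
)
from intrachain.refdata import load_reported_counts, load_reported_pairs


# ---------------------------------------------------------------------------
# pair labels

def test_parse_canonical_label():
    lab = parse_pair_label("Glu184||Arg211")
    assert (lab.acidic_name, lab.acidic_number) == ("Glu", 184)
    assert (lab.basic_name, lab.basic_number) == ("Arg", 211)
    assert lab.text == "Glu184||Arg211"


def test_parse_tolerates_case_and_spaces():
    assert parse_pair_label("ASP 52||HIS 99") == PairLabel("Asp", 52, "His", 99)


def test_basic_first_input_is_swapped():
    assert parse_pair_label("Arg211||Glu184") == parse_pair_label("Glu184||Arg211")


@pytest.mark.parametrize("bad", ["Glu1||Glu2", "Lys3||Arg4", "Ala5||Lys6",
                                 "Glu1|Arg2", "garbage"])
def test_malformed_or_unchemical_labels_rejected(bad):
    with pytest.raises(PairLabelError):
        parse_pair_label(bad)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(an=st.sampled_from(["Asp", "Glu"]), ai=st.integers(1, 999),
       bn=st.sampled_from(["Lys", "Arg", "His"]), bi=st.integers(1, 999))
def test_label_text_round_trips(an, ai, bn, bi):
    lab = PairLabel(an, ai, bn, bi)
    assert parse_pair_label(lab.text) == lab


# ---------------------------------------------------------------------------
# ingestion of the published tables

def test_reported_pair_sets_have_reported_sizes():
    sizes = {(ps.species, ps.chain): len(ps) for ps in load_reported_pairs()}
    assert sizes[("C. hamatus", "beta1")] == 7
    assert sizes[("D. labrax", "beta1")] == 6
    assert sizes[("T. bernacchii", "beta1")] == 9
    assert sizes[("C. hamatus", "beta2")] == 10
    assert sizes[("D. labrax", "beta2")] == 9
    assert sizes[("T. bernacchii", "beta2")] == 10
    assert sizes[("C. hamatus", "beta5")] == 5
    assert sizes[("D. labrax", "beta5")] == 5
    assert sizes[("T. bernacchii", "beta5")] == 6


def test_pair_set_sizes_agree_with_count_table():
    counts = {p.species: p.per_chain for p in load_reported_counts()}
    for ps in load_reported_pairs():
        assert len(ps) == counts[ps.species][ps.chain][1]


def test_empty_and_duplicate_ingestion(tmp_path):
    empty = tmp_path / "empty.tsv"
    empty.write_text("species\tchain\tpair_label\n")
    assert ingest_pair_table(empty) == []

    dup = tmp_path / "dup.tsv"
    dup.write_text("species\tchain\tpair_label\n"
                   "x\tbeta1\tGlu1||Lys2\n"
                   "x\tbeta1\tGlu1||Lys2\n")
    with pytest.raises(ValueError, match="Glu1\\|\\|Lys2"):
        ingest_pair_table(dup)


def test_dash_cells_skipped(tmp_path):
    p = tmp_path / "dash.tsv"
    p.write_text("species\tchain\tpair_label\n"
                 "x\tbeta1\tGlu1||Lys2\n"
                 "x\tbeta1\t-\n"
                 "y\tbeta1\t\n")
    sets = ingest_pair_table(p)
    assert len(sets) == 1 and len(sets[0]) == 1


# ---------------------------------------------------------------------------
# profiles and diff statistics

def test_species_totals_are_sums():
    prof = profile_from_counts("C. hamatus", {"beta1": (164, 7), "beta2": (151, 10),
                                              "beta5": (168, 5)})
    assert prof.totals == (483, 22)
    assert profile_from_counts("x", {"beta1": (0, 0)}).totals == (0, 0)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        profile_from_counts("x", {"beta1": (-1, 0)})


def test_diff_stats_values_and_symmetry():
    a = profile_from_counts("a", {"c": (483, 0)})
    b = profile_from_counts("b", {"c": (486, 0)})
    assert diff_stats(a, b, "hbonds") == (3, 0.6)
    assert diff_stats(b, a, "hbonds") == diff_stats(a, b, "hbonds")
    assert diff_stats(a, a, "hbonds") == (0, 0.0)
    c = profile_from_counts("c", {"c": (503, 0)})
    assert diff_stats(c, b, "hbonds") == (17, 3.4)


# ---------------------------------------------------------------------------
# conservation partition

def _sets(chain, **species_pairs):
    return [PairSet(species=sp, chain=chain,
                    pairs=frozenset(parse_pair_label(t) for t in labels))
            for sp, labels in species_pairs.items()]


def test_three_identical_sets_fully_conserved():
    sets = _sets("beta1", a=["Glu1||Lys2", "Asp3||Arg4"],
                 b=["Glu1||Lys2", "Asp3||Arg4"],
                 c=["Glu1||Lys2", "Asp3||Arg4"])
    part = conserved_partition(sets)
    assert len(part.conserved) == 2
    assert all(len(v) == 0 for v in part.unique.values())
    assert part.shared_partial == {}


def test_mixed_chain_tags_rejected():
    sets = _sets("beta1", a=["Glu1||Lys2"]) + _sets("beta2", b=["Glu1||Lys2"])
    with pytest.raises(ValueError, match="chain"):
        conserved_partition(sets)


def test_pairwise_partition_two_species():
    sets = _sets("beta5", a=["Glu1||Lys2", "Asp3||Arg4"],
                 b=["Glu1||Lys2", "Asp5||His6"])
    part = conserved_partition(sets)
    assert {p.text for p in part.conserved} == {"Glu1||Lys2"}
    assert {p.text for p in part.unique["a"]} == {"Asp3||Arg4"}
    assert {p.text for p in part.unique["b"]} == {"Asp5||His6"}


@settings(max_examples=50, derandomize=True, deadline=None)
@given(data=st.data())
def test_partition_is_complete_and_disjoint(data):
    universe = [PairLabel("Glu", i, "Lys", i + 1) for i in range(1, 20, 2)]
    sets = []
    for sp in ("a", "b", "c"):
        chosen = data.draw(st.sets(st.sampled_from(universe)))
        sets.append(PairSet(species=sp, chain="beta1", pairs=frozenset(chosen)))
    part = conserved_partition(sets)     # .validate() runs internally
    for ps in sets:
        rebuilt = set(part.conserved) | set(part.unique[ps.species])
        for subset, pairs in part.shared_partial.items():
            if ps.species in subset:
                rebuilt |= set(pairs)
        assert rebuilt == set(ps.pairs)
    # disjointness across categories
    cats = [set(part.conserved), *map(set, part.unique.values()),
            *map(set, part.shared_partial.values())]
    for i, x in enumerate(cats):
        for y in cats[i + 1:]:
            assert not (x & y)


# ---------------------------------------------------------------------------
# ranking

def test_rank_by_saltbridge_totals():
    profiles = [
        profile_from_counts("T. bernacchii", {"c": (503, 25)}),
        profile_from_counts("C. hamatus", {"c": (483, 22)}),
        profile_from_counts("D. labrax", {"c": (486, 20)}),
    ]
    ranking = rank_stability(profiles, "saltbridges")
    assert ranking.order == ["T. bernacchii", "C. hamatus", "D. labrax"]
    assert ranking.ties == []


def test_rank_is_input_order_invariant_and_tie_flagged():
    profiles = [profile_from_counts("b", {"c": (10, 5)}),
                profile_from_counts("a", {"c": (10, 5)})]
    r1 = rank_stability(profiles, "saltbridges")
    r2 = rank_stability(list(reversed(profiles)), "saltbridges")
    assert r1.order == r2.order == ["a", "b"]
    assert r1.ties == [("a", "b")]
    single = rank_stability([profile_from_counts("x", {"c": (1, 1)})])
    assert single.order == ["x"]


# ---------------------------------------------------------------------------
# end-to-end from coordinates

def test_crosslink_recovers_planted_truth(trio_default):
    trio, truth = trio_default
    part = crosslink_with_detection({sp: s.chains[0] for sp, s in trio.items()})
    assert sorted(p.text for p in part.conserved) == sorted(truth["conserved"])
    for sp, labels in truth["unique"].items():
        assert sorted(p.text for p in part.unique[sp]) == sorted(labels)


def test_crosslink_identical_chains_all_conserved():
    st_ = synth.make_random_chain(4)
    chains = {sp: st_.chains[0] for sp in ("a", "b", "c")}
    part = crosslink_with_detection(chains)
    assert all(len(v) == 0 for v in part.unique.values())
    assert part.shared_partial == {}


@pytest.mark.parametrize("seed", range(6))
def test_crosslink_matches_oracle_partition(seed):
    import oracles
    trio, _ = synth.make_ortholog_trio(
        synth.SyntheticSpec(seed=seed), shared=3, private_per_species=(2, 0, 1),
        decoys=1)
    chains = {sp: s.chains[0] for sp, s in trio.items()}
    part = crosslink_with_detection(chains)
    # oracle-derived per-species label sets fed through set algebra
    label_sets = {}
    for sp, chain in chains.items():
        labels = set()
        for (an, ai), (bn, bi), _d in oracles.salt_bridges(chain):
            labels.add(f"{an.title()}{ai}||{bn.title()}{bi}")
        label_sets[sp] = labels
    conserved = set.intersection(*label_sets.values())
    assert {p.text for p in part.conserved} == conserved
    for sp in chains:
        others = set.union(*(v for k, v in label_sets.items() if k != sp))
        assert {p.text for p in part.unique[sp]} == label_sets[sp] - others
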