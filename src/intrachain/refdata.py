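"""Packaged reference tables for the three-species proteasome comparison.

Two small TSVs ship with the package: the published per-chain intrachain
H-bond / salt-bridge counts for the beta1/beta2/beta5 catalytic subunits of
Chionodraco hamatus, Dicentrarchus labrax and Trematomus bernacchii, and
the published salt-bridge residue-pair lists for the same chains.  They are inputs to the aggregation pipeline, not outputs of it.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

from .compare import PairSet, SpeciesProfile, ingest_counts_table, ingest_pair_table

SPECIES = ("C. hamatus", "D. labrax", "T. bernacchii")


def _data_path(name: str) -> Path:
    return Path(resources.files("intrachain") / "data" / name)


def load_reported_counts() -> list[SpeciesProfile]:
    """Per-chain interaction counts for the three species' catalytic subunits."""
    return ingest_counts_table(_data_path("subunit_interaction_counts.tsv"))


def load_reported_pairs() -> list[PairSet]:
    """Salt-bridge residue-pair lists for the three species' catalytic subunits."""
    return ingest_pair_table(_data_path("salt_bridge_pairs.tsv"))
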