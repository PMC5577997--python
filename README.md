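# intrachain

Geometric enumeration of **intrachain hydrogen bonds and salt bridges** in
protein structures, with cross-ortholog conservation analysis — built around
the comparison of the proteasome 20S catalytic subunits (β1, β2, β5) of three
fish species: the Antarctic notothenioids *Trematomus bernacchii* and
*Chionodraco hamatus* and the temperate sea bass *Dicentrarchus labrax*.
Interaction counts act as structural-stability proxies for cold-adapted
versus temperate orthologs: more salt bridges and hydrogen bonds, more
rigidly stabilized chain.

The package is for structural bioinformaticians who want reproducible,
criteria-explicit interaction inventories from single-chain coordinate files
(e.g. homology models) and set-algebraic comparison of the resulting
residue-pair networks across species.

## What it computes

**Salt bridges.** For every Asp/Glu–Lys/Arg/His residue pair in a chain, the
minimum distance between side-chain carboxylate oxygens (OD1/OD2, OE1/OE2)
and charged nitrogens (NZ; NE/NH1/NH2; ND1/NE2) is computed; the pair is a
salt bridge when

&nbsp;&nbsp;&nbsp;&nbsp;min<sub>O∈acidic, N∈basic</sub> d(O, N) ≤ r<sub>c</sub>,&nbsp;&nbsp; r<sub>c</sub> = 4.0 Å by default,

one record per residue pair. His counts as basic by default (the published
pair lists include His partners).

**Hydrogen bonds.** Donors are N/O/S atoms bearing an inferable hydrogen,
acceptors are N/O atoms with a lone pair. Polar hydrogens with rigid
geometry (backbone amides, Arg/Asn/Gln/Trp/His N–H) are placed in-plane at
N–H = 1.0 Å; a bond requires d(D,A) ≤ 3.9 Å, d(H,A) ≤ 2.5 Å and
∠(D,H,A) ≥ 90°. Rotatable donors (Ser/Thr/Tyr hydroxyls, Lys NZ, Cys SG)
fall back to a stricter heavy-atom criterion: d(D,A) ≤ 3.5 Å and
∠(D,A,antecedent) ≥ 90°. Counting unit: donor-atom/acceptor-atom pair.

**Comparison.** Per-chain counts are summed into species totals; salt-bridge
pairs, written in the `Glu184||Arg211` label notation (acidic partner
first), are matched across species by exact residue name + number and
partitioned into *conserved* (all species), *unique* (one species) and
*partially shared* sets; species are ranked by their totals.

All thresholds are configurable and every report embeds the criteria used.

## Worked example

```bash
intrachain compare \
  --counts src/intrachain/data/subunit_interaction_counts.tsv \
  --pairs  src/intrachain/data/salt_bridge_pairs.tsv
```

The packaged TSVs transcribe the published per-chain interaction counts and
salt-bridge pair lists for the three species. The JSON report contains
(abridged):

```json
"totals": {
  "C. hamatus":    {"hbonds": 483, "saltbridges": 22},
  "D. labrax":     {"hbonds": 486, "saltbridges": 20},
  "T. bernacchii": {"hbonds": 503, "saltbridges": 25}
},
"diff_stats": {"hbonds": {"C. hamatus vs D. labrax":
  {"difference": 3, "percent_of_larger": 0.6}}},
"ranking": {"saltbridges": ["T. bernacchii", "C. hamatus", "D. labrax"]},
"conservation": {"beta1": {"sizes": {"conserved": 5,
  "unique": {"C. hamatus": 2, "D. labrax": 1, "T. bernacchii": 4}}}}
```

Reading: the two non-Antarctic-adapted proteomes differ by only three
hydrogen bonds (0.6% of the larger total), while *T. bernacchii* carries
both more H-bonds (503) and more salt bridges (25 vs 22 and 20) — the
salt-bridge totals order the species T. bernacchii > C. hamatus > D. labrax,
and most bridges are conserved across all three orthologs (5 of the β1
pairs, 5 of β2, 3 of β5).

Detection from coordinates works the same way on any single-chain PDB file:

```bash
intrachain detect model.pdb --out-dir results/
intrachain fixtures generate --out-dir fixtures/   # synthetic test structures
intrachain seqcomp orthologs.fasta                  # identity + substitutions
```

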