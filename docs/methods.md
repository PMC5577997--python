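# Methods

## Scope and model

The package treats a protein chain as a rigid set of heavy-atom coordinates
(Å) and enumerates two classes of intrachain stabilizing interactions under
explicit geometric criteria. It then compares the resulting interaction
inventories across orthologous chains from different species. No energetics
are computed; everything is distance/angle geometry, which makes results
exactly reproducible given the same coordinates and thresholds.

## Salt-bridge criterion

A salt bridge is recorded between an acidic residue (Asp, Glu) and a basic
residue (Lys, Arg, His) of the same chain when the minimum distance between
any charged carboxylate oxygen and any charged nitrogen is ≤
`max_no_distance`. Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| `max_no_distance` | 4.0 Å | the classical Barlow–Thornton ion-pair convention |
| `include_his` | true | the published pair lists contain His partners (e.g. Glu31‖His36), so His must count as basic |
| `include_termini` | false | the published lists contain side-chain pairs only; when enabled, the N-terminal amine and C-terminal OXT join the charged sets |

The counting unit is the residue pair: however many O···N contacts a
Glu–Arg pair makes, it contributes one bridge, carrying the minimum distance
and the closest atom pair. Residues with missing side-chain atoms are
evaluated over whatever charged atoms exist; with none present they cannot
bridge. Output is sorted by (acidic number, basic number), so identical
input yields byte-identical output.

## Hydrogen-bond criterion

Donors are N/O/S heavy atoms that carry (or could carry) a hydrogen:
backbone amide N (except proline), Arg NE/NH1/NH2, Asn ND2, Gln NE2,
His ND1/NE2, Trp NE1, Lys NZ, Ser OG, Thr OG1, Tyr OH, Cys SG. Acceptors
are N/O lone-pair bearers: backbone carbonyl O and OXT, carboxylate and
amide O, hydroxyl O, His ring N. His protonation is unknown in models, so
both ring nitrogens act as donor and acceptor candidates — the permissive
conventional choice.

Because homology models carry no hydrogens, polar H positions with rigid
geometry are inferred: the backbone amide H is placed on the external
bisector of C(prev)–N–CA at N–H = 1.0 Å, side-chain N–H analogously
(bisector for two in-plane neighbours, anti to the single neighbour for
terminal amide/guanidinium N). Donors whose H position is rotation-dependent
(hydroxyls, Lys NZ, Cys SG) or whose antecedent atoms are missing (e.g. the
chain's first amide) are flagged *ambiguous*.

Acceptance rules, all thresholds configurable (`HBondCriteria`):

- placed H: d(D,A) ≤ 3.9 Å **and** d(H,A) ≤ 2.5 Å **and** ∠(D,H,A) ≥ 90°
  (HBplus-style defaults);
- ambiguous donor: d(D,A) ≤ 3.5 Å **and** ∠(D,A,antecedent-of-A) ≥ 90° for
  every antecedent — a stricter distance because the angular test is weaker.

Covalently bonded and 1–3-related atom pairs and intra-residue pairs are
excluded; covalency is inferred from distance (≤ 1.8 Å heavy–heavy, 2.1 Å
involving S), which is robust for reasonable geometry and requires no
topology dictionary. The counting unit is the donor-atom/acceptor-atom pair.

Placing a single representative H on donors that really carry two (Arg
NH1/NH2, Asn ND2, Gln NE2) is an approximation: a bond whose true H is the
second proton can be missed when the D–H···A angle via the placed H falls
below the threshold. With the permissive 90° default this is rare, and both
the detector and its validation oracle apply the same placement, so the
approximation is explicit and testable rather than hidden.

## Sequence comparison

Global Needleman–Wunsch alignment (Biopython `PairwiseAligner`), BLOSUM62,
affine gaps −10/−0.5 — unremarkable choices that orthologs at 91–99%
identity are insensitive to; all are configurable. Among co-optimal
alignments the aligner's first canonical traceback is taken; only the score
is contract-tested. Percent identity is 100 × identical columns /
alignment length (denominator configurable to `shorter_seq`; for equal-length
orthologs the choice is moot). Substitutions are classed by the Clustal
convention — *conservative* = same strong group, *semi-conservative* = same
weak group only — and flagged for polarity change under a three-class
scheme: nonpolar {A V L I M F W P G}, polar-uncharged {S T C Y N Q}, charged
{D E K R H}. The scheme is stated explicitly because "polarity change" is
otherwise untestable. Note the two conventions are independent: Ser→Ala is
conservative (Clustal strong group STA) *and* a polarity change.

## Cross-species matching

Pair labels are matched by exact residue name + number. This is valid here
because the orthologs have equal residue counts and shared numbering; an
alignment-based renumbering for unequal-length orthologs can be layered on
via the sequence module but is deliberately not the default. The partition
is complete and disjoint by construction and re-validated on every call:
conserved ∪ partial-shared ∪ unique reproduces each species' input set
exactly. Percent differences between totals are reported against the larger
total, rounded half-up to one decimal (483 vs 486 → 0.6%).

## Synthetic structures and what they do (not) show

The generators produce: two-residue ion pairs whose minimum charged O···N
distance equals a requested separation to within 0.01 Å (side chains face
each other head-on, so the facing atoms are provably the closest pair);
ideal poly-alanine α-helices (φ = −57°, ψ = −47°, standard backbone
geometry) whose i→i−4 amide–carbonyl ladder is known in advance (n − 4
bonds for n residues; the N···O distance comes out at 3.09 Å); ortholog
trios with planted conserved/private/decoy bridges on a 16 Å lattice that
excludes accidental contacts; and random chains (random residue types,
random rigid placements in a box) for fuzzing the detectors against an
exhaustive reference implementation.

Every distance chosen by a generator keeps a **guard band of 0.2 Å** from
the relevant cutoff, and allowed jitter is bounded below a third of the
band, so floating-point noise can never flip an expectation — manifest
checks are exact, not tolerance-based. Side chains use idealized internal
geometry (standard bond lengths, planar zigzags); they are not
conformationally realistic, carry no Ramachandran validity, and random
chains are not even sterically sensible. Passing tests therefore certify
the *detection geometry and set algebra*, not biological realism: on real
structures the counts remain conditional on the chosen criteria, which is
why every report embeds them.

## Validation strategy

- **Oracle equivalence**: on 1000 seeded random chains, both detectors'
  output sets equal an independently written exhaustive all-pairs scan
  (no spatial index, law-of-cosines angles, own chemistry tables) under
  identical criteria — exact set equality including distances.
- **Invariances**: rigid motions leave outputs unchanged (distances to
  1e-6 Å); bridge sets grow monotonically with the cutoff; detection is
  independent of residue record order; identical inputs give identical
  outputs.
- **Manifest recovery**: every generated fixture is recovered with zero
  false positives and zero false negatives at default criteria.
- **Alignment**: scores equal a memoized exhaustive affine-gap recursion on
  all short pairs over a reduced alphabet and random pairs up to length 8.

Aggregation results (species totals 483/486/503 and 22/20/25, the
three-H-bond / 0.6% difference, conserved counts 5/5/3, β1 unique counts
1/2/4, and the T. bernacchii > C. hamatus > D. labrax salt-bridge ranking)
are recomputed from the transcribed per-chain tables shipped as package
data. The per-chain counts themselves are inputs, not reproduction targets:
regenerating them would require the original model coordinates and the
original (unpublished) detection thresholds.

## Numerical and degenerate-input choices

Distances are reported to 1e-6 Å; PDB output is fixed 3-decimal precision,
so round-trips preserve coordinates to 5e-4 Å. Alternate locations resolve
to highest occupancy, ties broken by altloc letter; `first` is available.
Empty chains, chains without charged residues, and missing side-chain atoms
degrade to empty results rather than errors; empty structures, malformed
ATOM lines (reported with their line number), non-standard residues in
sequence extraction, and chemically impossible pair labels (two acidics)
are hard errors. Ranking ties are broken alphabetically and flagged.

## Problem sizes

Default validation sizes — 1000 oracle chains of 25 residues, 500 in the
reproduction script, 200 alignment pairs — were chosen to exercise every
code path many times over while keeping a full run on one CPU around a
minute; all are trivially scalable upward through the same entry points.

## Known limitations

- Single representative H per donor (see above); no explicit protonation
  model for His.
- No π–cation, disulfide, hydrophobic or inter-chain interactions; the
  analysis is intrachain by design.
- Exact-label cross-species matching presumes shared numbering; orthologs
  with indels need the alignment-assisted path.
- Interaction counts are stability *proxies*; the package makes no causal
  claim linking them to measured biochemical stability.
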