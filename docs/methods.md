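# Methods

## Scope and data model

The package operates on homologous rRNA sequences (18S/28S-type), their
multiple alignments, named clades, and labeled column intervals. All
coordinates are 0-based; intervals are half-open. Base pairs on sequences are
`(i, j)` with `i < j`; consensus models pair alignment columns via helices
(two equal-length column intervals, the k-th 5'-side column pairing the
k-th-from-last 3'-side column). `N` is accepted as a residue: it counts
toward every length statistic (lengths are the phylogenetic character here)
but never pairs (pairing is structural evidence, and an ambiguous base is
none). Stockholm with `#=GC SS_cons` is the structure-bearing alignment
dialect; FASTA, Newick (labeled internal nodes = clades), a 4-column rank
table, and small CSVs cover the rest.

## Folding

LVRs are short, hairpin-dominated elements, so folding is base-pair
maximization (Nussinov-style interval DP) rather than nearest-neighbor
free-energy minimization. Scores are lexicographic `(pairs, stacked pairs)`;
the stacking tie-break prefers contiguous helices over scattered isolated
pairs, which is what distinguishes the biologically plausible co-optimum in
practice. Tables: `P[i][j]` (best score with `(i, j)` paired) and `F[i][j]`
(best overall); the stacked continuation is credited when the inner pair
`(i+1, j-1)` is used. Traceback is deterministic: at the leftmost undecided
position pairing beats leaving it unpaired, the smallest admissible partner
is taken first, and inside a pair the stacked continuation wins ties.

* `min_loop` default 3 (steric minimum for a hairpin loop).
* Pairing rules: `canonical` {AU, GC}, `canonical+wobble` (+GU, the default
  everywhere), `extended` (+AG, AC, plus explicitly enabled extras). The
  noncanonical classes never count toward stem retention by default; they are
  annotation, not stem support.
* `enumerate_cooptimal` enumerates by pair count only (each structure arises
  from exactly one derivation, so the enumeration is duplicate-free),
  returns lexicographic order, and is intended for LVR-scale inputs; the
  co-optimal set grows exponentially with length, so collection is capped.
* Correctness is checked against exhaustive enumeration of all valid
  structures for sequences up to length 12 (tests and the acceptance
  script), not against a thermodynamic reference: the package makes no
  free-energy claims. Users wanting thermodynamic structures can parse an
  external folder's dot-bracket output with `parse_dot_bracket`.

## Consensus model selection (co-variation criterion)

The comparative principle — the best model is the one whose stems are least
destroyed across sequences, because compensatory substitutions preserve
pairing — is qualitative; this package fixes a concrete ordering:

1. total retained paired columns, summed over rows (a retained column pair
   has non-gap residues on both sides forming an allowed pair);
2. larger minimum per-row retention (a model that no sequence violates badly
   beats one propped up by a subset);
3. fewer helices (parsimony);
4. input order (stability).

Loop (unpaired-column) conservation is ignored: length variation, not
substitution, is the signal of interest, and the quoted principle concerns
paired regions. Selection is a pure ranking; candidates are never modified.
Projection of a column model onto one row drops gapped column pairs and maps
the rest to sequence positions, flagging (but keeping) residue pairs the
rule disallows — mirroring how curated structure diagrams draw noncanonical
pairs with distinct symbols.

## Pairwise alignment and annotation transfer

`global_align` wraps Biopython's `PairwiseAligner` (global mode, affine
gaps; a gap of length L costs `gap_open + (L-1)·gap_extend`, terminal gaps
included). Defaults `match=+2, mismatch=-1, gap_open=-5, gap_extend=-1`:
conserved-core identity is high, so matches dominate, and cheap extension
lets LVR length differences concentrate in single gaps. The first reported
optimal alignment is used, which is deterministic for fixed inputs.

Region transfer maps each reference region through alignment columns:
query start = number of query residues strictly before the column of the
first reference residue of the region; query end = number of query residues
up to and including the column of the last. Consequences: interior
insertions (query residues between reference residues of the region) are
included — an expanded LVR measures long — while insertions the aligner
places flush against a region boundary fall outside it (conservative: LVR
lengths are never inflated by flanking gaps, at the price of occasionally
attributing a boundary-ambiguous expansion to the neighboring conserved
block; this is alignment ambiguity, not a transfer defect). A region fully
deleted in the query maps to a zero-length interval.

## LVR delimitation

Delimitation is gap-driven: a column is variable when its gap fraction
exceeds `gap_threshold` (default 0.2). Per-column entropy (bits, over
non-gap A/C/G/U) is computed and reported but unused by default —
substitution variability alone does not create length variation. Variable
runs separated by conserved runs shorter than `min_conserved_block`
(default 5; real LVR subregions are interspaced by *short* conserved
stretches) are merged; merged runs spanning fewer than `min_lvr_cols`
(default 2) columns are discarded as scattered single-column indels rather
than bona fide LVRs. Labels: alphabetic starting at B (the small-subunit
convention; A is reserved/absent), `D2, D3, …` for divergent domains, or
`D3-1, D3-2, …` when subdividing a parent domain. LVR lengths are non-gap
residue counts within the region's columns.

## Synapomorphy scan

For every named clade and region, the scan tallies the length distribution
and flags a state L when its in-clade share is ≥ `min_share` and its
frequency among non-clade sequences is ≤ `outside_max_freq`. Defaults 0.9
and 0.5: published synapomorphy tables accept "a few exceptions" inside a
group and describe merely *dominant* states, so strict unanimity would be
wrong, while a state carried by most of the outgroup is no apomorphy.
`min_share` must exceed 0.5 (guaranteeing at most one flagged state per
clade and region). `unique_within_parent` records the stronger
outside-frequency-zero condition under which a state is described as
"unique". Exceptions (`n_in - n_in_state`) are carried through to the
report. The scan is descriptive by design: no ancestral-state
reconstruction and no significance test — flagged states are candidates for
character-based scrutiny, not statistical claims.

## Synthetic data generator

`generate(spec)` builds: alternating conserved core blocks (identical
across sequences up to substitutions; each optionally carries a terminal
stem whose 3' side is the reverse complement of the 5' side) and LVRs whose
ungapped length is a discrete clade state (smallest matching clade key,
else the LVR's default). Noise processes:

* substitutions at per-site rate `sub_rate`; a substituted stem site is
  compensated (partner set to the canonical complement) with probability
  `compensatory_rate`;
* exceptions at per-(sequence, region) rate `lvr_indel_rate`, perturbing the
  state by ±1 nt — matching the "few exceptions" phenomenology of real
  tables while keeping recall measurable; indels never touch the core.

LVR content is a deterministic function of (seed, region, length) — so
zero-noise sequences with identical states are identical — and optionally
hairpin-constrained (3' half = reverse complement of 5' half) so folding
integration tests have foldable cases. In the true alignment each LVR
occupies a window wider than the longest realized state (width
`max(ceil(max_len/0.65), max_len+2)`) and each sequence's gap block is
rotated along the window, so every LVR column carries gap fraction well
above the delimitation threshold and every core column none: delimitation
on the truth alignment recovers planted boundaries exactly. This is a
property of the planted truth, not of real aligner output — real boundary
placement is fuzzier, so exact-boundary results on synthetic data bound the
pipeline's bookkeeping, not its behavior on ClustalW-style alignments.

The default study-scale configuration is 5 families × 6 sequences, five
30-column cores with 7-pair stems, and four LVRs carrying exactly two
planted synapomorphies (an 11 nt LVR B state for families F1+F2; a 4 nt
LVR D state for F4+F5); the remaining LVRs vary between families with no
scan-clade-consistent state, and all states in a synapomorphic region
differ from the planted state by ≥ 2 nt so a ±1 exception cannot collide
with it. A 13-LVR, 14-core configuration (`small_subunit_like_spec`)
exercises delimitation at small-subunit scale. Ground truth includes the
alignment, region map, structure model, length table, per-cell
planted/realized states with exception flags, and the planted synapomorphy
triples (computed by scanning the planted-state table at unanimity).

## Numerical and policy choices

* Problem sizes in the test and acceptance suites — oracle checks at
  lengths ≤ 12 (folding) and ≤ 6 (alignment), 50 generated datasets per
  recovery experiment, 100 model-selection trials × 100 rivals — keep each
  experiment in seconds while the brute-force oracles remain exhaustive.
* Random rival models place helix sides as ordered disjoint intervals with
  random spacings (always a valid pseudoknot-free configuration) and
  preserve the planted helix-length multiset, so the comparison is
  placement-only.
* All randomness flows through `numpy.random.Generator` seeded from a
  single integer; pipeline manifests contain parameters and SHA-256
  checksums but no timestamps, so reruns are byte-identical.
* Degenerate inputs: empty sequences cannot be constructed (validated at
  the type); folding an empty string yields the empty structure; an
  all-conserved alignment yields an empty region map; a zero-length region
  has length 0 for every sequence; a clade covering the whole table has
  outside frequency defined as 0.

## Limitations

* Folding ignores thermodynamics, pseudoknots, and temperature; it is a
  combinatorial stand-in adequate for short hairpin-type LVRs.
* The generator does not simulate branch-length-aware evolution or
  realistic substitution models (GTR etc.); clade states are planted, not
  evolved, so tests quantify the pipeline's recovery of a known signal, not
  inference difficulty on real data.
* Delimitation quality on real data depends on the upstream multiple
  alignment; structure-aware manual curation upstream remains the
  practitioner's responsibility.
* The scan treats sequences as independent draws; shared ancestry inside a
  clade is exactly what makes the statistic interesting but also means
  counts are not independent evidence.
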