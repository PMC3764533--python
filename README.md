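# rrnalvr

Comparative analysis of ribosomal RNA **length-variable regions (LVRs,
a.k.a. expansion segments)** for molecular systematics.

Nuclear rRNA genes (18S, 28S) mix long length-conservative blocks — the
workhorse of higher-level phylogenetics — with short regions whose ungapped
length differs between taxa. When a particular LVR length is (near-)invariant
within a named monophyletic group and rare outside it, that discrete length
state can serve as a **molecular synapomorphy** for the group (classic
examples in true bugs: an 11 nt state of LVR B and a 4 nt state of LVR T
within Pentatomomorpha, a unique 5 nt LVR W shared by Naboidea and
Cimicoidea, and D3 subregion states supporting family pairs such as
Acanthosomatidae+Lestoniidae). `rrnalvr` implements the full desk pipeline
behind such tables:

1. **Folding** (`rrnalvr.fold`) — pseudoknot-free structures for LVR
   subsequences by base-pair maximization (Nussinov-style DP; primary
   objective: pair count; tie-break: stacked pairs), with canonical,
   canonical+wobble (G·U), and extended (A:G/A:C) pairing rules, co-optimal
   enumeration, and dot-bracket I/O.
2. **Consensus model selection** (`rrnalvr.model`) — helices on alignment
   columns, scored by the co-variation / stem-retention criterion: for a
   model with column pairs {(a,b)} and aligned rows r, the retained stem
   length of r is `#{(a,b): r[a], r[b] non-gap and allowed}`; the best model
   maximizes the total over rows, then the per-row minimum, then parsimony.
3. **Annotation transfer** (`rrnalvr.align`) — affine-gap global alignment
   (Needleman–Wunsch–Gotoh via Biopython) and conservative lift-over of
   reference LVR coordinates onto new sequences.
4. **LVR delimitation** (`rrnalvr.delimit`) — gap-fraction column profiles,
   merging of variable runs across short conserved interruptions, alphabetic
   (B, C, …) or divergent-domain (D2…, D3-1…) labeling, and the per-sequence
   LVR length table.
5. **Synapomorphy scan** (`rrnalvr.scan`) — flag (clade, region, length)
   states with in-clade share ≥ `min_share` (default 0.9) and outside
   frequency ≤ `outside_max_freq` (default 0.5); exceptions are counted, not
   hidden; reports render the conventional `"<L>nt <region> (<n>)"` cells.
6. **Synthetic data** (`rrnalvr.simulate`) — a generator with full ground
   truth (conserved cores with compensatory-substitution stems, planted
   clade-specific LVR states, a ±1 nt exception process), so every stage is
   testable without downloads.

## Worked example

```sh
rrnalvr simulate --seed 3 --out-dir sim          # 30 sequences, truth bundle
rrnalvr delimit --msa sim/truth_alignment.sto --msa-format stockholm \
    --out-regions reg.csv --out-lengths len.csv
# -> 4 LVRs -> reg.csv, lengths -> len.csv
rrnalvr scan --lengths len.csv --clades clades.nwk
```

prints

```
Monophyletic group	LVR (number of sequences examined)
CladeA	11nt B (12)
CladeB	4nt D (12)
```

i.e. the scan recovered exactly the two planted synapomorphies: all 12
sequences of CladeA share an 11 nt state in LVR B (absent outside the clade),
and all 12 of CladeB share a 4 nt LVR D. `clades.nwk` is any Newick tree
whose labeled internal nodes name the groups to scan. The same run as one
command: `rrnalvr run --config cfg.yaml`, which also writes a
`manifest.json` with parameter values and input/output checksums (reruns are
byte-identical). Folding a hairpin-type LVR directly:

```
$ rrnalvr fold h.fa
>h1 pairs=4
GGGCAAAGCCC
((((...))))
```

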