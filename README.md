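# mytikit

Discovery and characterization of **mytilin-like CS-αβ antimicrobial peptides**
from marine mussel (Mytilidae) sequence data.

Mytilins are short, cationic, cysteine-rich host-defense peptides stored in
mussel hemocytes. They are produced as tripartite precursors — an N-terminal
signal peptide (~20 aa), the mature cysteine-rich cationic peptide
(32–38 aa), and an anionic C-terminal extension that neutralizes the mature
charge until release. The mature region folds into the cysteine-stabilized
α-helix / β-sheet (CS-αβ) scaffold held by four disulfide bonds in a
C1–C5, C2–C6, C3–C7, C4–C8 arrangement over eight structural cysteines with
the canonical spacing

```
C-x3-C-x3-C-x(2-5)-C-x11-C-x-C-x(0-2)-C-x2-C
```

An *alternative* array displaces C5 (re-routing the C1–C5 bond), and many
*Perna* mytilins insert an extra cysteine between C6 and C7, creating a CCC
triplet whose central residue stays unpaired and is a candidate for
inter-molecular dimerization.

`mytikit` implements the full discovery workflow for this family as a
library, a set of runnable examples, and a thin `mytikit` CLI:

| stage | module | method |
|---|---|---|
| transcript mining | `mytikit.screen` | iterative six-frame translation + Smith–Waterman (BLOSUM62, gap 11/1), Karlin–Altschul-style e-values, cysteine-array acceptance gate, <95 %-identity novelty filter |
| precursor segmentation | `mytikit.precursor_model` | von Heijne-style cleavage heuristic + alignment-mapped mature/C-tail boundary |
| charge profiling | `mytikit.physchem` | net charge (#K+#R −#D−#E), Henderson–Hasselbalch pI by bisection (EMBOSS pKa set), 15-aa sliding pI profiles |
| array classification | `mytikit.cysarray` | spacing-template search for canonical / alternative / CCC arrays, disulfide topology assignment |
| redundancy reduction | `mytikit.redundancy` | Hobohm algorithm 2 over `1 − S(a,b)/min(S(a,a),S(b,b))` BLOSUM62 distances, threshold 0.1 |
| family model | `mytikit.profile_hmm` | profile HMM (match/insert/delete; Henikoff weights; background pseudocounts), Viterbi/forward log-odds scoring, Gumbel-calibrated E-values, paired mytilin-vs-myticin screening |
| phylogeny | `mytikit.phylo` | neighbor joining over p/Poisson MSA distances, Newick output |
| synthetic benchmarks | `mytikit.synthetic_data` | seeded generators for precursors, decoy families, transcript corpora and truth tables |

A reference set of 30 published mytilin mature peptides from *Mytilus
californianus*, *M. coruscus*, *M. galloprovincialis*, *Perna canaliculus*,
*P. viridis* and *Trichomya hirsuta* is bundled
(`mytikit.datasets.load_reference_peptides`), including the reported lengths
and net charges.

## Worked example

```sh
python examples/01_reference_peptides.py
```

```
peptide                len charge     pI  array
Mcal_mytilin_1          34     +9   9.44  canonical
Mcal_mytilin_5          34    +13  10.23  canonical
Mgal_mytilin_L          38     +9   9.44  alternative
Pcan_mytilin_1          34     +2   7.90  canonical+CCC
Pcan_mytilin_8          33    +11   9.62  alternative
...
Perna peptides with a CCC triplet: 13 / 15
Perna net-charge range: +0 to +11
Rows with inconsistent reported lengths:
  Mgal mytilin L: sequence 38 aa, reported 38 / 39 (two conflicting lengths reported)
  Pvir mytilin 3: sequence 34 aa, reported 43 (sequence length differs from reported length)
```

Each line is one mature peptide: its residue count, integer net charge at
neutral pH, isoelectric point, and cysteine-array class. The summary shows
the CCC triplet is a *Perna*-specific feature (13 of 15 peptides) and that
two table rows carry internally inconsistent published lengths, which the
validator surfaces rather than silently accepting.

`examples/04_iterative_screen.py` demonstrates why the transcript screen
iterates: on a corpus where three remote homologs resemble only the close
homologs of the seed, a single pass recovers 5/8 embedded mytilins and the
iterative search recovers 8/8 with no false positives, the remotes entering
on pass two via the hits of pass one.

The same workflow runs from the shell: `mytikit synth`, `mytikit screen`,
`mytikit physchem`, `mytikit cysarray`, `mytikit reduce`, `mytikit align`,
`mytikit hmm-build`, `mytikit hmm-scan`, `mytikit tree`, and `mytikit run`
(the whole pipeline; with no inputs it runs on a seeded synthetic demo
corpus and writes hits, annotations, profiles, reports, the HMM, the tree
and a checksummed manifest).

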