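# subpatterns

Substitution-pattern analysis and visualization for PAML ancestral
reconstructions.

When `baseml` or `codeml` (PAML) is run with ancestral reconstruction
enabled, it writes an auxiliary *rst* file listing every inferred unique
substitution along the phylogenetic tree — a file that is rich but hard to
read, especially for large datasets such as RNA-virus genome surveys.
`subpatterns` parses that file, maps each substitution onto its branch and
alignment site, and classifies it three ways:

* **mutation class** — transition (Ts: A↔G, C↔T) or transversion
  (Tv: A↔C, A↔T, G↔C, G↔T);
* **codon position** — 1, 2 or 3;
* **phenotypic effect** — synonymous or nonsynonymous, judged by
  translating the parent-node codon before and after the change.

The cross of class and effect gives the four canonical categories:
synonymous transitions (**As**), synonymous transversions (**Bs**),
nonsynonymous transitions (**Aa**) and nonsynonymous transversions
(**Ba**). From the classified events the package computes per-site
profiles, sliding-window means with **dS = As + Bs**, **dN = Aa + Ba** and
the dN/dS ratio, cumulative curves including the running total **Kt**, and
a 4×4 Markov matrix of conditional substitution probabilities. It renders
eleven diagnostic plots (PDF), two tabular reports (CSV or XLSX) and two
annotated Newick trees (amino-acid changes and the corresponding
nonsynonymous nucleotide changes, FigTree-compatible).

Note that dN and dS here are raw substitution *counts* averaged over
windows, not site-normalized rates — see `docs/methods.md`.

Input alignments must be protein-coding, gap-free and ambiguity-free; any
other character in a reconstructed sequence is a hard error.

A seeded simulator (`subpatterns simulate` / `subpatterns.simulate`)
evolves codon sequences along a random tree, records an exact event log,
and serializes it in the same *rst* dialect — so every stage of the
pipeline can be validated against known ground truth without running PAML.

## Worked example

Simulate a history (8 taxa, 200 codons, transition/transversion ratio
κ = 4) and analyze it:

```sh
$ subpatterns simulate --tips 8 --length 200 --kappa 4 \
      --events-per-branch 15 --seed 42 --out-dir sim
199 events on 14 branches -> sim

$ subpatterns analyze sim/simulated.rst --out-dir run --window 60 --step 6
199 substitutions -> 11 plots, 2 reports, 2 trees in run
```

`run/` now holds `plot01…plot11` (PDF), `report1_plot_data.csv`,
`report2_tree_data.csv`, the two annotated trees and a
`run_manifest.json`. Inspecting the same run from Python:

```python
from collections import Counter
from subpatterns import (read_rst, build_events, count_matrix,
                         conditional_probabilities, transition_mass)

doc = read_rst("sim/simulated.rst")
events = build_events(doc)
print(dict(Counter(e.category for e in events)))
# {'As': 58, 'Bs': 10, 'Aa': 108, 'Ba': 23}

matrix = conditional_probabilities(count_matrix(events))
print(round(transition_mass(matrix), 3))
# 0.834
print(matrix.conditional_frame().round(3))
#        A      C      G      T
# A  0.000  0.056  0.889  0.056
# C  0.128  0.000  0.085  0.787
# G  0.851  0.060  0.000  0.090
# T  0.082  0.816  0.102  0.000
```

The 199 substitutions split into the four categories (third-position
changes are mostly synonymous, hence the high As count among transitions).
The transition mass — the fraction of all events in the four Ts cells of
the matrix — estimates κ/(κ+1) = 0.8, and each row of the conditional
matrix sums to 1: the probability of each derived base given the ancestral
base.

Branch annotations use the compact grammar `18_1@Ts1_3@Ts2_2@Tv1`:
sequence #18 carries one transition at codon position 1, three transitions
at position 2 and two transversions at position 1. `parse_annotation` and
`format_annotation` are exact inverses on this grammar.

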