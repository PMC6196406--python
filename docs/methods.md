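# Methods

## What the pipeline computes

The unit of analysis is the *inferred substitution*: one base change on
one branch of a phylogeny at one alignment site, as reported by a maximum
likelihood ancestral reconstruction (PAML's `baseml` or `codeml`). The
pipeline parses the reconstruction (*rst*) file, classifies every change,
and derives all downstream summaries from the resulting event list. Every
table and plot is a deterministic view over that list: regenerating the
reports from an exported event list reproduces them byte-identically.

Classification is three-way and orthogonal:

* **Ts/Tv** — a change is a transition iff its unordered base pair is
  {A,G} or {C,T}; the four other pairs are transversions.
* **Codon position** — site *s* (1-based, nucleotides) sits at position
  ((s−1) mod 3) + 1 of codon ⌈s/3⌉. The alignment is assumed to start
  in-frame at its first column.
* **Effect** — synonymous iff the codon before and after the change
  translates to the same amino acid under the standard genetic code
  (Biopython's table id 1; the table is a plain mapping and swappable,
  but alternative codes are out of scope).

The four categories are As = Ts∧syn, Bs = Tv∧syn, Aa = Ts∧nonsyn,
Ba = Tv∧nonsyn; they partition the events.

### Codon context: the parent rule

Reconstruction files report changes parent→child, so the pre-substitution
reading frame is the parent node's sequence. Each event's effect is judged
against the parent codon with *only that event's site* altered. When two
or three sites of one codon change on the same branch, each change is
therefore evaluated independently of its companions; the alternative
(sequential application) would make the classification depend on an
arbitrary within-branch ordering the reconstruction does not provide.
This is a documented simplification: for the rare multi-hit codon the
per-event effect labels need not compose to the net amino-acid change.

### dN/dS as used here

dS = As + Bs and dN = Aa + Ba are **raw counts** (per-window means of
per-site counts). There is no normalization by the number of synonymous
and nonsynonymous *sites* (no NG86- or Goldman–Yang-style site counting),
so the plotted dN/dS is a descriptive profile for comparing regions of
one alignment, not an estimate of ω. Windows with dS = 0 get an undefined
marker (NaN in memory, an empty cell in tables, a gap in plots) — never
±∞.

### Sliding windows and cumulative curves

Windows start at 1, 1+step, … and must fit entirely inside the alignment;
a trailing partial window is dropped so all means average the same number
of sites. Defaults are window = 90 nt and step = 9 nt (30 codons shifted
by 3), a smooth setting for virus-genome-scale coding sequences; both are
user parameters and changing them never recomputes the per-site profile.
Windows are not forced to be codon-aligned — the position-stratified
plots are the codon-aware view. Cumulative series are evaluated at
step, 2·step, …, always including the final site, so the last value of
Kt = As+Bs+Aa+Ba equals the total event count.

### Substitution matrix

The 4×4 count matrix tallies (ancestral base → derived base) over all
events; its diagonal is structurally zero. Two normalizations are
exported side by side because both are in circulation for this object:
*conditional* (each row divided by its row sum — a Markov transition row;
rows with no events stay zero and are flagged rather than NaN-filled) and
*joint* (each cell divided by the total event count — the relative
frequency of that specific change).

### Tree annotation

Branches bearing events are labeled `<seq>_<n>@<Class><pos>…`, e.g.
`18_1@Ts1_3@Ts2_2@Tv1`: sequence #18, one Ts at codon position 1, three
Ts at position 2, two Tv at position 1. Segment order (Ts before Tv,
positions ascending, zero cells omitted) is a fixed convention of this
package; the parser is its exact inverse. `seq` is the child node's
number in the reconstruction file, which for external branches is the
tip's sequence number. Amino-acid changes are written
`<fromAA><codon_index><toAA>` (1-based codon index) and nonsynonymous
nucleotide changes `<from><site><to>` in lower case (1-based nucleotide
site); both are package conventions. Two Newick trees are exported — one
labeled with amino-acid changes, one with the corresponding nucleotide
changes — as FigTree-style `[&aa_subs="..."]` / `[&nt_subs="..."]`
bracket comments on the child node, via dendropy, and both round-trip
through a Newick parser.

## The rst dialect

The parser fixes one concrete dialect of the reconstruction file, closed
by the package's own writer: a `Supplemental results for BASEML|CODEML`
header; a numbered-node Newick tree (`k_name` tips, bare internal
numbers, tips 1..n, internal n+1..2n−1 with the root at n+1); `node #k`
sequence lines; and `Branch N: a..b` blocks whose change lines are
`site base prob -> base` (baseml) or `site codon (aa) prob -> codon (aa)`
(codeml). Sites are 1-based nucleotide positions in **both** dialects.
Posterior probabilities are parsed and carried but not used analytically
unless a threshold is requested (default 0.0 — all inferred changes
count). Lines that merely fall outside the grammar are skipped with a
logged warning (tolerating cosmetic drift between PAML versions); lines
that start like a branch header or change line but fail to parse raise a
hard error with the line number. codeml's printed amino acids are
cross-checked against our own translation; a disagreement warns rather
than errors.

## The simulator

The simulator exists to close the contract: it produces histories whose
every substitution is known exactly, serialized in the same dialect the
parser reads, so parser, classifier and all tallies can be checked for
*exact* equality rather than statistical agreement.

Model: a random rooted binary topology (tips 1..n, internal nodes
renumbered in preorder from n+1); root sequence uniform over the 61 sense
codons; per branch a Poisson(λ) number of substitutions at distinct
sites; the derived base drawn with relative weights κ (the transition)
and 0.5, 0.5 (the two transversions), so the expected transition fraction
is κ/(κ+1). A proposal is rejected and redrawn if it would create a stop
codon either in the parent-context codon (the classifier's view) or in
the accumulating child sequence — the second check matters because two
hits in one codon on one branch can jointly form a stop even when neither
does alone, and it guarantees no node sequence ever contains an in-frame
stop. Posteriors on emitted change lines are drawn uniformly in
[0.90, 1.00] and are never used analytically. Everything is reproducible
from a single integer seed.

What the simulator is *not*: a biological codon model. There is no ω, no
rate heterogeneity, no branch lengths, and site choice is uniform. Tests
passing on simulated data therefore certify format fidelity, bookkeeping
and the algebra of the summaries — not that any biological signal (e.g.
selection) would be recovered from real alignments. Stop-codon rejection
slightly tilts the realized transition fraction away from κ/(κ+1)
(empirically ≲ 0.005 at κ = 4), well inside the three-standard-error
band used when checking recovery.

Default study conditions used in validation: 10 tips, 300 codons, κ = 2,
~20 events per branch for exact-equivalence checks; 10 tips, 1500 codons,
κ = 4, 600 events per branch (≈ 10,800 events expected) for
transition-fraction recovery; 12 tips, 800 codons, 60 events per branch
(> 1,000 events) for the large-run check.

## Numerical and degenerate-input choices

* A run with zero events is not an error: plots render with all-zero
  series, tables are empty views, trees carry no labels.
* Conditional-matrix rows sum to 1 within 1e−12 on populated rows.
* The default table format is CSV — each report is one file whose
  sections are delimited by `## <name>` lines — because the analytical
  content, not the container, is what matters; an XLSX writer (one
  workbook per report, one sheet per section) is available behind
  `--format xlsx`.
* The CLI maps each structured error class to a distinct exit code and
  prints a diagnostic; identical input and configuration give
  byte-identical tables and trees.

## Known limitations

* Multi-hit codons on one branch are classified per-event against the
  parent context (see above).
* Only the standard genetic code; only gap-free, ambiguity-free
  protein-coding alignments; only the nucleotide-alphabet reconstruction
  output (amino-acid baseml runs are out of scope).
* The parser consumes whatever single reconstruction the file prints; it
  does not distinguish joint from marginal reconstruction or weight
  alternative ancestral states by their posteriors.
* dN/dS is count-based, as stated; do not compare its absolute value
  across datasets with different codon composition.
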