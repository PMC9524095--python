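# Methods

## Scope and model of the data

`sodnox` classifies predicted proteomes into SOD and NOX family members
and subfamilies using three kinds of evidence: domain architecture
(Pfam-style accessions from a HMMER3 per-domain scan), a reference-
numbered sequence motif, and relative placement among labelled exemplars
in a distance tree, supplemented by sequence features (signal peptide,
transmembrane helices, EF-hands, long disorder, localization). The
pipeline assumes protein-level input (no gene models or splice-variant
reasoning), 1-based inclusive residue coordinates at every interface, and
treats the domain scan as given: profile-HMM scoring itself is out of
scope, and hits are consumed from standard `domtblout` tables.

## Stages and the decisions they make

**Architecture normalisation.** Hits with independent e-value above
`i_evalue_max` (default 1e-3, common Pfam practice; the scan threshold is
not part of the published criteria) are dropped. Overlaps greater than
`overlap_tolerance` (default 10 residues; small envelope overlaps are
alignment artifacts, true Pfam domains rarely overlap) are resolved by a
fixed dominance order — higher bit score, then lower i-evalue, then lower
envelope start — so annotation is deterministic and idempotent, and the
retained-domain count is monotone in the e-value cutoff.

**Family filters.** Expressed in a small rule grammar over named domain
classes (each Pfam accession belongs to exactly one class). A CuZnSOD
candidate carries at least one Cu/Zn-binding domain; an MnSOD candidate
carries both the N- and C-terminal Mn/Fe domains (one terminal alone is
rejected); a NOX candidate carries the ferric-reductase transmembrane
domain plus at least one of the FAD- or NAD-binding domains. A sequence
matching both SOD signatures is flagged and routed to the metalloform
with the larger summed bit score.

**Superoxide-motif gate.** NOX candidates are aligned to the NOX2
reference with affine gaps (BLOSUM62, gap open -10, extend -1; a gap of
length k costs open + (k-1)·extend). End gaps are free so that long
N-terminal extensions (EF-hands, peroxidase, the DspNOX sensory region)
cannot distort mapping of the C-terminal oxidase core. All four reference
positions (101/115/209/222) must map to histidine exactly; conservative
substitutions and deletions both fail. The packaged reference is a
*synthetic* NOX2 stand-in constructed so its own numbering puts the four
histidines at exactly those coordinates; only the numbering convention,
not any database sequence, is assumed.

**Features.** External predictor tables always win over heuristics and
provenance is recorded per feature. The built-in stand-ins are simple by
design: signal peptide = a hydrophobic window (mean Kyte–Doolittle >= 2.0
over 8 residues) within the first 30 residues preceded by a basic
residue; transmembrane = merged >= 17-residue windows with mean
hydropathy >= 1.6; disorder = runs of >= 30 residues with external score
>= 0.5, or a smoothed composition rule (fraction of D/E/K/R/S/P/Q/G/N in
a 7-residue window) without scores; EF-hands are counted from domain hits
with a canonical calcium-loop pattern fallback (the published scan also
needed a fallback route for four sponge sequences). Localization takes
every compartment whose probability meets the per-class threshold
(default 0.5 for all nine classes; the external tool's published
thresholds are not printed anywhere usable), else the single closest
label; without a table: signal peptide → Extracellular, any TM → Cell
membrane, else Cytoplasm.

**Subfamily decision order.** SOD (CuZn): Rsod architecture rule first
(>= `rsod_min_cu_domains` Cu/Zn domains, default 3), then clade label
(SOD1 or Rsod), then signal peptide + extracellular → "SOD3-like", else
CuZnSOD-other. Observed Rsod architectures span 2–6 Cu/Zn domains but the
hard criterion is >= 3; the 2-domain case is therefore evidence-flagged
("Rsod-possible") without being called — placement can still label it
Rsod. SOD (Mn): clade label SOD2 or SOD2X, else MnSOD-other; the
SOD2/SOD2X distinction is purely placement-driven, with localization
treated as corroborating, not defining. NOX: DspNOX composite rule first
(core confined to the C-terminal fraction, default midpoint, of the
sequence; PAS or PAS_9 N-terminal of the core; >= 1 long disordered tract
N-terminal of the core; >= `dspnox_min_extra_tm` = 3 extra TM helices
before the core — 3 being the smallest count seen in the freshwater
variant; EF-hand NOT required, DUF2427/cytochrome-b561 hits recorded as
evidence only, and a peroxidase-bearing architecture is asserted never to
be DspNOX), then EF-hand + peroxidase → Duox, EF-hand → NOX5, then clade
label NOX1-3 or NOX4. NOX1, NOX2 and NOX3 are reported as the single
placement group "NOX1-3" because they resolve as one clade; "SOD3-like"
is deliberately never "SOD3" because those sequences are paraphyletic.

**Placement.** A documented substitute for maximum-likelihood inference
with model selection, chosen to keep the artifact self-contained and
deterministic: progressive profile alignment (average-linkage guide tree
over normalised edit distances; profiles merged by the same affine DP,
column score = frequency-weighted BLOSUM62 expectation), trimming of
columns with *more than* `trim_max_gap_fraction` = 0.5 gaps (a column at
exactly 50% is retained), Poisson-corrected distances with pairwise gap
deletion (p capped at 0.99), neighbor joining (smallest Q, ties broken
lexicographically by current matrix index; NJ is exact on additive
matrices and path lengths reproduce them; negative branch estimates are
clamped to zero for output), and nonparametric bootstrap by column
resampling (`bootstrap_reps` default 1000 per the published setting;
tests and the acceptance script use 100, which the support resolution of
a >= 70% cutoff does not need more of). Trees are midpoint rooted for
clade reading only — the trees are unrooted statements, and the rooting
is a convention, not an ancestry claim. A query takes the unique
reference label of the smallest clade with support >= `min_support`
(default 70; the published support cutoff for classification is not
stated, so it is configurable and recorded in output) that contains it
and references of one label only; nodes without references or below the
support cutoff are skipped; mixed labels → unclassified.

One further guard is the package's own design: the **placement margin**.
A clade label is kept only if the query's distance to the nearest
exemplar of that label is at most `placement_margin_ratio` (default 0.7)
times its distance to the nearest exemplar of any other label. Reading
trees by eye, a curator would not assign a query that sits as far from
every exemplar as the subfamilies sit from each other; without this
guard, deep-topology artifacts can hand a novel lineage the label of
whatever reference clade it happens to attach beside (exactly the
situation of paraphyletic "SOD3" sequences and lineage-specific
radiations). The ratio is scale-free, so it behaves consistently across
divergence levels.

Placement runs per evidence group — CuZn candidates not already called
Rsod, Mn candidates, and NOX candidates not decided by architecture —
each against its own exemplar panel, producing three trees. Groups of
fewer than four taxa fall back to nearest-exemplar assignment.

## Reference material

Exemplar panels (SOD1/Rsod, SOD2/SOD2X, NOX1-3/NOX4/NOX5/Duox; four per
label) are synthetic consensus-like sequences: lightly diverged (2%
substitution) copies of each subfamily's template, generated
deterministically from a fixed internal seed. They are never database
extracts. Panels and the synthetic cohort share one canonical template
library — deliberately, because real exemplars are homologous to real
candidates; without shared templates neither motif mapping nor placement
would be meaningful.

## The synthetic cohort generator

The generator is first-class, tested code. It emulates: multi-species
cohorts whose per-species subfamily compositions mirror a published
19-species, 10-phylum survey (including its per-species exact-duplicate
counts — 113 CuZnSOD and 50 MnSOD in total when duplicates are included);
subfamily architectures as concatenated template blocks with linkers
(Rsod draws 3–6 Cu/Zn domains; Duox = peroxidase + EF-hand + core;
DspNOX = 5 TM helices + PAS + 200-residue disordered tract + EF-hand +
core, with the core in the C-terminal half); point substitutions and
short (1–3 residue) indels at configurable rates with a complete edit
script, so every planted domain, motif position and feature interval is
known exactly in final coordinates; hydrophobic signal peptides
(randomised per protein — real signal peptides share hydropathy, not
sequence), polar inter-helix loops, disorder-promoting tract composition;
matching domtblout tables (true hits plus Poisson(1) sub-threshold
decoys with i-evalues between 0.03 and 3, which exercise the e-value
filter without flakiness); external-format feature tables reflecting
planted truth; motif ablation (an explicit His→Tyr substitution, flagged
in truth); and byte-deterministic emission per seed.

Functional conservation of the motif is emulated by never substituting
the four planted histidines at random and keeping indels at least 8
residues away from them; ablation is the only way a motif breaks. This
mirrors purifying selection on heme-ligand residues and is what makes the
motif filter's removal count exact rather than stochastic.

Not emulated: site-rate heterogeneity or any realistic substitution
process (mutations are uniform over the 19 non-identical residues),
realistic HMM score/e-value distributions, splice isoforms or fragmented
gene models, compositional biases of real proteomes, and real
subfamily-specific sequence signatures (subfamilies are separable because
each carries a distinctive 120-residue template region — a stand-in for
genuinely diagnostic sequence, not a claim about its information
content). Passing tests therefore demonstrate that the *procedure* is
implemented correctly and is robust to substitution/indel noise of the
stated magnitude — not that the heuristic feature stand-ins match neural
predictors, nor that a distance tree resolves what maximum likelihood
resolves on real genomes.

## Numerical and degenerate-input choices

Alignment traceback prefers diagonal over up over left everywhere, making
tied optima deterministic; with free ends, the end cell scan prefers the
corner. The alignment score of equal-length sequences is never below the
gap-free diagonal pairing. NJ requires n >= 3 and symmetric zero-diagonal
input; star-like (all-equal) matrices resolve deterministically via the
lexicographic tie-break. Distance computation raises on pairs with zero
comparable columns; trimming raises if it would delete every column
(advising a larger `trim_max_gap_fraction`). Bootstrap replicates that
produce an incomparable pair are skipped. All run-level randomness
derives from one seed (placement groups get spawned sub-seeds), and the
manifest stores a config hash and seed but no timestamps, so identical
runs are byte-identical.

## Problem sizes used in tests and acceptance

The full synthetic survey (19 pseudo-species, 321 sequences of which 283
are family members) runs end-to-end, including all three placement trees
with 100 bootstrap replicates, in a few seconds; the acceptance script
repeats it at substitution rates 0/0.05/0.15 across five seeds, checks
the motif-ablation filter exactly, and validates the primitives against
independent oracles (exhaustive alignment-path enumeration at lengths
<= 8, exhaustive least-squares topology search over all 15 five-taxon
trees on additive matrices, 100 cases each).

## Known limitations

Progressive alignment has no iterative refinement, so deep-divergence
alignments are cruder than MAFFT's; NJ with nonparametric bootstrap is a
stand-in for ML with model selection and ultrafast bootstrap; midpoint
rooting can misread clades if rate variation is extreme; the DspNOX
"C-terminal half" boundary is a crude, configurable fraction; the
EF-hand accession list is configurable because the published scan does
not name the model it matched; and the heuristics for signal peptide,
TM, disorder and localization are labelled stand-ins — on real data the
corresponding external predictor tables should always be supplied.
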