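# Methods

## The protein inference problem

Shotgun proteomics identifies proteins indirectly: proteins are digested
to peptides, the peptides are identified from tandem mass spectra, and
the protein content of the sample must then be deduced from the peptide
list.  In higher eukaryotes a substantial fraction of peptides is
*shared* (degenerate) — the same sequence occurs in homologous proteins,
isoforms or redundant database entries — so the peptide-to-protein step
is ambiguous.  Rather than discarding ambiguous proteins by an Occam's
razor minimal-list rule, or apportioning shared peptides
probabilistically, this package keeps every protein and *tags* it with
an evidence category, so that downstream analysis can decide what to
trust.

## Evidence model

The input is reduced to a bipartite evidence graph: distinct peptide
sequences on one side, protein accessions on the other, an edge where
the peptide occurs in the protein.  Peptide identity is the amino-acid
sequence alone; records differing only in modification state merge into
one peptide with several PTM *variants*.  This is deliberate — the
classification operates on the peptide-to-protein mapping, and treating
each modified form as its own peptide would manufacture spurious
"unique" evidence from a single tryptic site.  Two consequences users
should know: leucine/isoleucine are not equated (sequences compare
byte-wise), and accessions are opaque strings (no UniProt parsing, no
gene-model reasoning).

Peptides take one of three types:

* **unique** — maps to exactly one protein;
* **discriminating** — shared, but its protein set is not a strict
  superset of any other observed peptide's set: it genuinely constrains
  which proteins are present;
* **non-discriminating** — shared and strictly contains another
  peptide's protein set, so it adds no information beyond what the
  contained peptide already provides.

Proteins then fall into four categories: **conclusive** (≥ 1 unique
peptide), **non-conclusive** (only non-discriminating peptides),
**indistinguishable** (a group with identical peptide sets, including at
least one discriminating peptide) and **ambiguous group** (a connected
set of proteins jointly explaining discriminating peptides).  A fifth
bucket, **filtered**, holds proteins whose every peptide was removed by
the score or replicate filters; they are reported, never dropped.

## Classification procedure

1. Mark all peptides discriminating; single-protein peptides become
   unique; their proteins become conclusive; non-unique peptides whose
   protein set contains a conclusive protein become non-discriminating.
2. Iterate over the peptides still marked discriminating, in
   lexicographic sequence order.  The current peptide's protein set is a
   temporary group; every other still-discriminating peptide whose
   protein set strictly contains that group is re-marked
   non-discriminating.  The pass continues until the last discriminating
   peptide has served as seed.
3. Proteins with only non-discriminating peptides become non-conclusive.
   The remaining proteins are grouped as connected components of the
   relation "co-occur in some discriminating peptide's protein set"
   (transitive closure, so two proteins that never directly share a
   peptide can be merged through an intermediary).  A component whose
   members all carry exactly the same peptide set is indistinguishable;
   any mixed component is an ambiguous group.

The iteration order in step 2 is not specified by the procedure itself;
lexicographic order is used for reproducibility, and the order-invariance
property test demonstrates the outcome does not depend on it.  A
closed-form characterisation is implemented independently as a test
oracle (`oracle_classify`): a shared peptide is non-discriminating iff
some other peptide's protein set is a strict subset of its own.  The two
routes are compared peptide-for-peptide on 1000 seeded random graphs.
Step 2 performs at most |peptides|² subset tests; at the scale of
interest (thousands of peptides) this is negligible.

Group numbering and member ordering are canonical: members sorted
lexicographically, groups numbered 1..n by their smallest member.  All
outputs are byte-deterministic.

## Replicate-run integration

Technical replicates are integrated with a *runs threshold*: a peptide
enters inference only if observed in at least that many distinct runs.
Two named settings: **merging** (threshold 1, every peptide counts) and
**voting** (threshold `floor(n/2) + 1`, a strict majority — 3 of 5 runs,
2 of 3).  "Half plus one" is rounded down for odd n; a strict majority is
the only reading consistent with both reference configurations the
package reproduces (threshold 3 for five replicates; a peptide present
in two of three runs passing the vote).  Merging yields more conclusive
proteins; voting is conservative and shifts proteins toward
non-conclusive and ambiguous categories.  Run identity is positional:
the i-th input file on the command line is run i.

Score filtering (green/yellow/red confidence bands, cutoffs from a log
file or flags) is applied before the runs filter; both report the
accessions they emptied into the filtered bucket.

## Worked examples and the synthetic generator

No external dataset is needed; the fixtures module generates every
input.

* **All-scenarios graph** (9 proteins A–I, 6 peptides): pep1→{A},
  pep2→{A,B,I}, pep3→{C,D}, pep4→{E,F}, pep5→{F,G}, pep6→{C,D,H}.
  Classification: A conclusive; B, H, I non-conclusive; {C,D}
  indistinguishable; {E,F,G} one ambiguous group (E and G merge through
  F).  All three peptide types and all four protein categories appear at
  once.  This wiring is frozen (golden-tested) as the package's
  canonical example: it is the smallest graph we found that exercises
  every category simultaneously, including transitive ambiguous-group
  merging.
* **Replicate example** (4 proteins A–D, 6 peptides, 3 runs): protein
  A's unique peptide is seen in runs 1–2 only, so A is conclusive in
  single-run analyses 1–2 and non-conclusive in run 3; protein C's
  unique peptide is seen only in run 2, so merging keeps C conclusive
  while voting (2 of 3) demotes it to non-conclusive.  Six peptides are
  the minimum here: each of the two behaviours (A's run-dependent status,
  C's merging/voting flip) needs its own conclusive partner protein with
  a shared and a unique peptide, and no 4-protein/5-peptide wiring
  satisfies both simultaneously.
* **Random generator**: each peptide draws a protein set of
  truncated-Poisson size (mean degree ~2, matching the moderate sharing
  of a eukaryotic search space) and is observed per run with probability
  1 − dropout (default dropout 0 — real replicate dropout is emulated
  explicitly in tests at 0.2–0.35, a plausible range for run-to-run
  peptide irreproducibility).  Scores are uniform on [0, 10].  Output is
  deterministic per seed.

What the generator does **not** emulate: realistic score distributions
(no target/decoy structure, so score filtering is exercised mechanically,
not statistically), spectra and retention times, database redundancy
patterns (protein sets are drawn independently per peptide), and
correlated dropout across runs.  Passing tests therefore demonstrate the
combinatorial correctness of classification, grouping and filtering —
not identification accuracy on real spectra, which depends entirely on
the upstream search engine.

## Problem sizes and numerical choices

Property tests run on graphs up to 12 proteins × 20 peptides (1000 seeds
for oracle equivalence, 100–200 for order invariance and partition
checks); these sizes already cover every subset/superset topology the
algorithm distinguishes, and the whole suite completes in seconds.  There
is no floating-point numerics in the classifier itself; scores are only
compared against cutoffs with `>=`.  Degenerate inputs are defined
explicitly: an empty record list is an error; a runs threshold above the
run count empties the evidence and yields an all-filtered result with no
groups; duplicated records are idempotent.

## mzIdentML specifics

Reading accepts the 1.0.0 and 1.1.0 namespaces (1.0.0 inline peptide
evidences included); writing always emits 1.1.0.  Each inferred group
becomes a `ProteinAmbiguityGroup`; each member hypothesis carries exactly
one MS:1001600 "Protein Inference Confidence Category" param valued
`conclusive` / `non-conclusive` / `indistinguishable` / `ambiguous
group`.  The bundled validator checks structure (namespace, required
sections, full reference resolution, the one-param rule); full XSD
validation is available by passing a local copy of the official schema,
which is not bundled.

## Known limitations

* No probabilistic apportionment of shared peptides and no protein-level
  FDR: categories are combinatorial statements about peptide evidence,
  not probabilities.
* Decoy handling is minimal (decoy evidences are excluded on read);
  decoy filtering is assumed to have happened upstream.
* Vendor PLGS files must be converted to the documented dialect.
* Multiple rank-1 peptides per spectrum are all accepted; no attempt is
  made to arbitrate between them.
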