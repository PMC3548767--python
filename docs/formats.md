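# Input and output formats

## mzIdentML (read: 1.0.0 and 1.1.0; write: 1.1.0)

The HUPO-PSI standard for peptide/protein identification results.
Reading resolves, for every `SpectrumIdentificationItem`:

* the peptide sequence through `peptide_ref` → `Peptide/PeptideSequence`;
* protein accessions through the item's peptide evidences
  (`PeptideEvidenceRef` children in 1.1.0, inline `PeptideEvidence`
  elements in 1.0.0) → `DBSequence/@accession`;
* modifications from `Modification/@location` and the first `cvParam`
  name;
* the peptide score from the first `cvParam` whose name ends in "score".

Items with `passThreshold="false"` are dropped when
`respect_pass_threshold` is on (the CLI always respects it), and
decoy-flagged evidences (`isDecoy="true"`) are always excluded.

Writing replaces the `ProteinDetectionList` with one
`ProteinAmbiguityGroup` per inferred group.  Every
`ProteinDetectionHypothesis` carries the PSI-MS controlled-vocabulary
param **MS:1001600 "Protein Inference Confidence Category"** whose value
is one of `conclusive`, `non-conclusive`, `indistinguishable`,
`ambiguous group`.  mzIdentML output requires a single-run analysis with
a single mzIdentML input, because the output document carries the source's
sequence collection and spectrum identifications.

## PLGS-like XML dialect (read)

The vendor schema of ProteinLynx Global Server is proprietary, so this
package defines a documented equivalent dialect
(schema: [`plgs_dialect.xsd`](plgs_dialect.xsd)):

```xml
<results>
  <protein accession="P12345" description="Example kinase">
    <peptide sequence="ELVISLIVESK" score="7.2">
      <modification position="3" name="Oxidation"/>
    </peptide>
  </protein>
</results>
```

* A peptide sequence may appear under any number of proteins; occurrences
  are merged during graph construction.
* Each `<peptide>` element is one modification variant; the same sequence
  listed twice with different `<modification>` children yields one peptide
  with two variants.
* `score` is optional; it is required only when filtering at the yellow or
  green confidence band.

Support for genuine vendor files is an extension point: any converter that
emits this dialect plugs in.

## Score-threshold log (read)

Confidence bands follow the vendor's traffic-light convention: **green**
(high), **yellow** (medium), **red** (low).  The two numeric cutoffs are
read from a log file containing, anywhere, one line each matching
(case-insensitive, `:` or `=` as separator):

```
Green threshold: 6.0
Yellow threshold: 4.5
```

A score `>= green` is green; `>= yellow` is yellow; anything lower is red.
Filtering at *red* keeps every peptide.  `--green`/`--yellow` flags
override or replace the log.

## CSV report (write)

RFC 4180, UTF-8, CRLF line endings.  One row per (group, member protein):

| column | content |
| --- | --- |
| `group_id` | 1-based group number (canonical order) |
| `category` | evidence category label |
| `accession` | protein accession |
| `description` | protein description if the source carried one |
| `peptides` | semicolon-separated peptides; `*` marks discriminating, `**` non-discriminating |
| `runs_presence` | peptides of this protein seen in each run, e.g. `2/3/3` |
| `n_unique` / `n_discriminating` / `n_non_discriminating` | per-category peptide counts |

Category statistics follow as `#`-prefixed comment lines.

## HTML report (write)

A single self-contained HTML5 file with three sections linked by
intra-page anchors: configuration and per-category statistics (group
counts in parentheses for indistinguishable/ambiguous categories); a
group summary whose protein links jump to the details; and per-protein
details with peptides, evidence markers, run occupancy ("runs: 1,2,3")
and modification variants.

Both reports are deterministic: identical inputs produce byte-identical
files.
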