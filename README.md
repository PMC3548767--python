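# protinfer

Peptide-evidence protein inference for shotgun proteomics.

Protein identification in shotgun proteomics is indirect: the mass
spectrometer identifies peptides, and the proteins must be inferred from
them.  Peptides shared between homologous proteins, isoforms or redundant
database entries make that step ambiguous.  `protinfer` keeps every
identified protein and groups it transparently by peptide evidence, instead
of discarding ambiguous proteins (Occam's-razor minimal lists) or
apportioning shared peptides probabilistically.  It is aimed at
proteomics practitioners — in particular users of data-independent
acquisition (MS^E) searches — who need a defensible, reportable protein
list with technical-replicate support.

## The model

Peptides are classified into three types:

* **unique** — assignable to a single protein;
* **discriminating** — shared, with a protein set that is not a strict
  superset of any other peptide's set (it constrains the inference);
* **non-discriminating** — shared, with a protein set that strictly
  contains another peptide's set (it adds nothing).

Formally, with P(p) the protein set of peptide p: p is unique iff
|P(p)| = 1, non-discriminating iff ∃q: P(q) ⊊ P(p), otherwise
discriminating.  Proteins then land in four evidence categories:
**conclusive** (≥ 1 unique peptide), **non-conclusive** (only
non-discriminating peptides), **indistinguishable** (identical peptide
sets with ≥ 1 discriminating peptide) and **ambiguous group** (a
connected component of proteins sharing discriminating peptides).  A
*runs threshold* integrates technical replicates: a peptide must appear
in at least that many runs ("merging" = 1, "voting" = strict majority
⌊n/2⌋+1); proteins that lose all their peptides are reported as
**filtered**.

Inputs: mzIdentML 1.0.0/1.1.0 or a documented PLGS-like XML dialect
(`docs/formats.md`), several files acting as replicate runs.  Outputs:
CSV, HTML and — for a single mzIdentML input — mzIdentML 1.1.0 whose
`ProteinAmbiguityGroup` entries carry the PSI-MS term MS:1001600
"Protein Inference Confidence Category" on every detection hypothesis.

## Worked example

Generate the bundled worked-example inputs and run a three-replicate
voting analysis:

```sh
protinfer --seed-fixtures demo --log-level WARNING
protinfer demo/replicate_run1.mzid demo/replicate_run2.mzid \
          demo/replicate_run3.mzid --voting --out-csv mr1.csv
```

The log reports the chosen threshold and the category statistics:

```
INFO protinfer: runs threshold: 2 (of 3 run(s))
INFO protinfer: runs threshold 2 removed 1 peptide(s); 0 protein(s) filtered
INFO protinfer: conclusive: 3 protein(s) in 3 group(s)
INFO protinfer: non-conclusive: 1 protein(s) in 1 group(s)
```

and `mr1.csv` contains one row per protein (`*` marks discriminating
peptides, `**` non-discriminating ones; `runs_presence` counts this
protein's peptides seen in each of the three runs):

```
group_id,category,accession,description,peptides,runs_presence,n_unique,n_discriminating,n_non_discriminating
1,conclusive,A,Protein A,AAGILK;CCNGYK**,2/2/1,1,0,1
2,conclusive,B,Protein B,CCNGYK**;DDFWSK,2/2/2,1,0,1
3,non-conclusive,C,Protein C,FFQVPR**,1/1/1,0,0,1
4,conclusive,D,Protein D,FFQVPR**;GGKDER,2/2/2,1,0,1
```

Protein C's only surviving peptide (FFQVPR) is also explained by protein
D, which has a unique peptide — so C is non-conclusive under voting.
Rerun with `--merging` and C's run-2-only unique peptide is kept, making
all four proteins conclusive: the two strategies bracket how much
run-to-run fluctuation you are willing to trust.

The same pipeline is available as a library:

```python
from protinfer import read_mzid, infer

records = [r for i, p in enumerate(paths, 1) for r in read_mzid(p, run_index=i)]
result = infer(records, n_runs=len(paths), runs_threshold=2)
for group in result.groups:
    print(group.group_id, group.category.label, group.members)
```

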