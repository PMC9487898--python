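# structannot

Desk-scale structural annotation of protein positions and variants. Given
protein sequences, a variant/position list and a directory of PDB-format
template structures, the pipeline:

1. finds candidate templates (built-in exact k-mer search, pluggable with an
   external similarity-search tool),
2. aligns query to template ATOM-derived sequences with a free-end-gap
   Needleman–Wunsch/Gotoh aligner (BLOSUM62, gap open 10, extension 0.5) and
   keeps annotations with core sequence identity ≥ 0.35,
3. structurally analyzes every annotated complex per residue: Shrake–Rupley
   solvent accessibility and RSA, typed interaction scores/degrees from a
   distance-weighted residue interaction network, contact counts, 10 Å
   neighborhood profiles, secondary structure, backbone geometry, B-factor
   statistics and graph centralities (a 100-entry feature registry),
4. aggregates features across all mapped structures by a quality-weighted
   mean (quality = identity × coverage × resolution factor; undefined values
   are skipped; accessibility weights are additionally multiplied by squared
   coverage),
5. classifies each position (interaction type by partner priority, else
   surface/core at RSA 0.16) and selects recommended / maximum-identity
   structures,
6. decomposes in-frame indels into flank/indel regions of wild-type and
   mutant (6 region sets) and emits 123-entry SAV and 600-entry indel
   feature vectors.

Everything runs offline: a fixture module generates synthetic template
structures (helices, dimers with designed interfaces, ligand/ion and
nucleic-acid complexes) with construction-derived ground truth.

## CLI

```bash
# write the four synthetic fixture structures to a template directory
structannot fixtures -o templates/ --seed 1

# annotate a mutation list against the library
printf 'FIXH:A\n' > input.smlf
structannot annotate -i input.smlf -t templates/ -o out/ [--lite] \
    [--chunk-size N] [--workers N] [--config cfg.yaml] [--seed N] \
    [--verbosity info]
```

Input formats:

* **mutation list** (tab-separated): `protein-id [variant] [tag,tag,...]`,
  e.g. `P1<TAB>D833A<TAB>pathogenic`. A bare id annotates all positions.
  Variant grammar: SAV `D833A`, deletion `del10-13`, insertion `ins7GS`
  (after position 7), delins `delins10-12GSW`.
* **FASTA**: header token = protein id, further header tokens are variants.
  Bare identifiers are resolved against the template library
  (`ENTRY:CHAIN` or an entry with a single protein chain).

Outputs in the run directory: `classification.tsv` (28 columns per queried
position), `features.tsv` (123 feature columns per SAV/position),
`indel_features.tsv` (600 columns per indel), `feature_manifest.tsv`,
`tag_summary.tsv`, `skipped_inputs.tsv` and `run.log`. Undefined values are
rendered as `-`.

Default mode persists per-structure analyses to an on-disk cache
(never-compute-anything-twice); `--lite` computes everything on the fly
without persisting. Both modes, any chunk size and any worker count produce
identical tables.

## Library use

```python
from structannot.config import AnalysisConfig
from structannot.pipeline_cli import Job, ProteinInput, run_pipeline

job = Job()
job.add(ProteinInput("P1", "MKTAYIAKQR...", annotate_all=True))
result = run_pipeline(job, "templates/", "out/", AnalysisConfig())
```

Module layout: `structures_io` (PDB parsing/writing, entity typing,
fixtures), `search_align` (k-mer candidates, Gotoh aligner, position
mapping), `residue_analysis` (SASA, contacts, RIN, per-residue features),
`aggregation_classify` (weighted aggregation, decision-tree classes,
evidence), `variants_indels` (variant grammar, indel decomposition,
vectors), `pipeline_cli` (orchestration, cache, outputs, CLI).
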