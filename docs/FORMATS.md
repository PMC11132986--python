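# File formats

All tables are tab-separated UTF-8 with a header row. Missing intensities
are empty cells, never 0.

## Protein-group table (`pg*.tsv` + `*_meta.tsv`)

Wide matrix: first column `protein_id` (unique), optional `molar_mass_da`
and `gene_name` columns, then one column per sample with linear-scale LFQ
intensities. The side-car metadata table maps each sample column:

| column | meaning |
|---|---|
| `sample_id` | matches an intensity column name |
| `model` | cell model (e.g. SGBS, hAPC) |
| `timepoint_days` | day of differentiation; empty for fractionation runs |
| `replicate` | positive integer |
| `condition` | grouping key for statistics |
| `fraction_index` | gradient position, 0 = top (LD fraction); empty for temporal runs |

Every sample needs either timepoint or fraction semantics.

## Marker table (`markers.tsv`)

Optional first line `# compartments: A,B,...` declaring the vocabulary
(defaults to the 12-compartment set), then columns `protein_id`,
`compartment`.

## Localization map (`map.tsv`)

Columns `protein_id, first_organelle, confidence, high_confidence,
second_organelle, alpha, best_mix_correlation`. Unassigned proteins have an
empty `first_organelle`; an empty `alpha` means "not evaluated", while
`alpha = 0` states single-compartment specificity.

## Annotation table

Columns `term_id`, `term_name`, `members` (`;`-separated protein ids).

## Cohort table

Columns `r` (correlation), `n` (cohort size).

## Config (`cfg.yaml`)

YAML/JSON mapping of tunables (see `spatmap.config.RunConfig`); unspecified
keys take the defaults (σ = 0.2, C = 8, downshift 1.8, width 0.3,
FDR 0.01, DNA mass 6.5 pg, α grid 0.05). Unknown keys are an error. Stages
write the fully resolved config as `resolved_config.json`.

## Manifest (`manifest.json`)

Written by `spatmap demo` before and after execution: package version,
global seed, per-stage derived seeds, resolved config, stage list, status
and output inventory.
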