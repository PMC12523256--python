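# prostaging

Automated AJCC 8th-edition prostate-cancer staging for structured
radical-prostatectomy pathology data: a prioritized rule engine with
explicit missing-data semantics, a property-graph representation with
consistency-validation rules and descriptive error codes, a pluggable
report-extraction layer with a deterministic offline baseline, and the
evaluation statistics used to score extraction and staging — all
exercisable on a seeded synthetic report corpus.

## Modules

| Module | Purpose |
| --- | --- |
| `prostaging.record_model` | Domain types (TNM codes, three-kind missing values, Gleason/grade-group arithmetic), JSON (de)serialization, value normalization for scoring |
| `prostaging.staging_engine` | Nine prioritized staging rules over T/N/M/grade group/PSA, M0 imputation for missing M-stage, `Unknown (Missing ...)` labeling |
| `prostaging.consistency_validator` | Five rule families (T-stage vs EPE/SVI, N-stage vs node counts, Gleason vs grade group) emitting machine-readable error codes |
| `prostaging.knowledge_graph` | In-memory property graph (Patient, Pathology_Report, TNM_Stage, Grade, PSA_Value, AJCC_Stage) with GraphML / Cypher / JSON export |
| `prostaging.extraction` | Extraction contract, tolerant LLM-JSON parsing, deterministic pattern-based baseline extractor, typed bridge to records |
| `prostaging.synthetic_data` | Seeded generator of coherent records, three report dialects (narrative / synoptic / tabulated grade grid), noise mode, targeted inconsistency injection |
| `prostaging.evaluation_stats` | Field and staging metrics (micro/macro), Wilson intervals, Fisher's exact test (r×2), Pearson chi-squared, workbook export |
| `prostaging.cli` | `prostaging` subcommand CLI tying the pipeline together |

## CLI

```sh
# generate a synthetic corpus, run the full pipeline, export everything
prostaging pipeline --config config.json --seed 1 --out out/

# individual steps
prostaging simulate --config config.json
prostaging extract  --config config.json     # baseline or external payloads
prostaging stage    --config config.json
prostaging validate --config config.json
prostaging evaluate --config config.json
prostaging export-graph --config config.json --format cypher
```

A config file (JSON or YAML; unknown keys rejected):

```json
{
  "seed": 1,
  "out_dir": "out",
  "corpus": "out/corpus.jsonl",
  "extractor": "baseline",
  "pmx_blocks": false,
  "generator": {"n_patients": 150, "noise_rate": 0.0}
}
```

The pipeline writes `corpus.jsonl`, `extractions.jsonl`, `staging.jsonl`,
`results.xlsx` (sheets `field_metrics`, `staging_metrics`, `classification`,
`consistency_errors`, `error_summary` with CSV mirrors under `csv/`), and
`graph.json` / `graph.cypher`. Everything is deterministic under `--seed`.

## Notes

- Missing values are typed: `not_mentioned`, `dash`, and `x_code` (`pNx` /
  `pMx`). X-codes block definitive staging yet score as concrete values when
  comparing extraction output with ground truth.
- Missing M-stage is imputed to M0 (radical prostatectomy implies localized
  disease). Whether `pMx` also gets imputed is configurable (`pmx_blocks`).
- The synthetic generator enforces cross-field coherence strictly so that
  injected corruptions are identifiable; `loose_coherence` relaxes the
  EPE/SVI coupling for realism studies.
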