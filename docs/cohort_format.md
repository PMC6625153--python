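# Cohort file format

Delimited text (comma by default; any single-character delimiter such as
tab is accepted via the `delimiter` argument / `--delimiter` flag), one
row per subject, with a header row. Category tokens are lower-case and
matched case-insensitively on input; a missing value is an empty cell or
`NA`. Unknown columns are preserved verbatim and round-trip through
`read_cohort`/`write_cohort` as `record.extras`.

| column | type | tokens / units | notes |
|---|---|---|---|
| `subject_id` | string | — | required, unique within a file |
| `group` | category | `case`, `control` | required, never missing |
| `gstm1` | category | `present`, `null` | deletion assay: `present` includes heterozygotes |
| `gstt1` | category | `present`, `null` | as above |
| `gstp1` | category | `aa`, `ag`, `gg` | Ile105Val (c.313A>G) genotype |
| `smoking` | category | `smoker`, `nonsmoker` | smoker = at least one pack/day; nonsmoker = never |
| `sex` | category | `male`, `female` | |
| `age` | number | years, ≥ 0 | |
| `mcyr_3m` | category | `yes`, `no` | major cytogenetic response at 3 months |
| `ccyr_6m` | category | `yes`, `no` | complete cytogenetic response at 6 months |
| `bcrabl_3m` | category | `le10pct`, `gt10pct` | BCR-ABL1 transcript level at 3 months |
| `bcrabl_6m` | category | `lt1pct`, `ge1pct` | BCR-ABL1 transcript level at 6 months |
| `mmr_time` | number | months, ≥ 0 | time to major molecular response or censoring |
| `mmr_event` | category | `yes`, `no` | `yes` = MMR achieved (requires `mmr_time`) |
| `efs_time` | number | months, ≥ 0 | event-free survival time or censoring |
| `efs_event` | category | `yes`, `no` | composite event: loss of CCyR/MMR, progression to AP/BP, or death (pre-coded; requires `efs_time` when `yes`) |

Response and survival columns are meaningful for cases only and may be
absent entirely. Validation errors name the offending row, column and
token. Records with a missing value for a given analysis are excluded
from that analysis only (complete-case per table), with the exclusion
count reported.
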