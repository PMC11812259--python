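# Harmonized data dictionary

Column dictionary for the CSV + JSON-sidecar survey datasets produced by
`crossprev.synthetic_data` and consumed by every estimator. This mapping is
**reconstructed** for the synthetic instrument: it documents this package's
own harmonization, not any survey's published item-by-item crosswalk.

## Design columns

| column    | type   | notes |
|-----------|--------|-------|
| `person_id` | int  | key into the generating population table |
| `stratum` | str    | probability survey only (e.g. `S003`) |
| `psu`     | str    | probability survey only (e.g. `S003-P012`); bootstrap replicates suffix `~k` |
| `weight`  | float > 0 | analytic weight (base × nonresponse adjustment, or raked) |
| `wave`    | int {1,2} | opt-in panel only; two pooled panel waves |

The JSON sidecar records: design kind (`probability_clustered` /
`optin_panel`), the stratum/PSU/weight column names, the draw seed, sample
sizes, and (for raked panels) raking convergence metadata.

## Outcome columns

| column | levels | notes |
|--------|--------|-------|
| `heroin_recency` | `none`, `months_2_12`, `past_month` | most recent heroin use |
| `imf_recency`    | same | most recent illicitly manufactured fentanyl use |
| `either_recency` | same | derived: max of the two under none < months_2_12 < past_month |

`past_year` use means `recency != none`.

## Covariates

| column | levels |
|--------|--------|
| `age_group` | `18-25`, `26-34`, `35-49`, `50-64`, `65+` |
| `sex` | `male`, `female` |
| `race_ethnicity` (raw) | `non-Hispanic White`, `non-Hispanic Black`, `Hispanic`, `Asian`, `Native American`, `Native Hawaiian`, `Multiple races`, `Other` |
| `race4` (harmonized) | raw collapsed: last five raw levels → `another non-Hispanic race` |
| `income` | `<$50,000`, `$50,000-$74,999`, `>=$75,000` |
| `education` | `no college degree`, `college graduate` |
| `marital` | `married`, `never married`, `other` |
| `employment` | `worked past week`, `no past-week employment` |
| `insurance` | `private`, `not private` |
| `cigarette_use` | `every day`, `some days`, `not at all` (+ raw `missing`, resolved to `not at all` by harmonization) |
| `cannabis_py` | `yes`, `no` (past-year cannabis) |
| `stimulant_py` | `yes`, `no` (past-year cocaine/methamphetamine) |
| `benzo_py` | `yes`, `no` (past-year nonmedical benzodiazepine) |
| `heavy_alcohol` | `yes`, `no` (≥ 15 drinks/week men, ≥ 8 women, if derived from `drinks_per_week`) |
| `moud_py` | `yes`, `no` (past-year methadone or buprenorphine; adjuvant/"other" medications excluded) |
| `hospitalization_py` | `yes`, `no` (any overnight hospital stay, past year) |
| `health` | `Fair/Poor`, `Good`, `Very Good`, `Excellent` |
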