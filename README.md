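# ethnoconsensus

Quantitative analysis of ethnobotanical use-report surveys: the
consensus and importance indices used in ethnopharmacology, literature
cross-referencing against reference floras, and species co-use
association networks — packaged as a tested, reproducible pipeline with
a synthetic survey generator for validation.

## Who this is for

Field ethnobotanists and ethnopharmacologists who collect long-format
interview data — *informant × plant species × ailment × plant part ×
preparation × route* — and need the standard quantitative summaries of
such surveys, computed the same way every time and checkable against
known ground truth.

## The statistics

With N included informants, a *use report* being one informant citing
one species for one ailment:

- **Use value** `UV = ΣUi / N` — total use reports for a species per
  informant (an informant citing a species for two ailments contributes
  Ui = 2).
- **Frequency of citation** `FC` — distinct informants citing the
  species; **RFC** `= FC / N`.
- **Factor of informant consensus**
  `Fic = (Nur − Nt) / (Nur − 1)` per ICPC disease category, where `Nur`
  is the category's use-report count and `Nt` its distinct cited taxa.
  Fic → 1 when informants converge on a few taxa, 0 when every report
  names a different taxon; a category with `Nur ≤ 1` takes the
  configured degenerate value (default 0).
- **Co-use rules** — for species pairs across informant "baskets",
  *support* (co-citing informants) and *confidence* (conditional
  probability of the consequent given the antecedent), collapsed into
  an undirected co-use network.

Cross-referencing compares the survey checklist and its use records
against published floras/catalogues: overlap percentages, shared-use
agreement, novel species and novel uses, and annotation tallies such as
red-list status counts. Display rounding is half-up (configurable
digits); raw exact fractions are kept alongside every rounded value.

## Worked example

```python
from ethnoconsensus import (
    SimConfig, generate_survey, compute_species_indices,
    compute_fic, demographic_summary,
)

ds, truth = generate_survey(SimConfig(seed=42))
print(ds.n_informants, len(ds.species), len(ds.reports))
# 80 83 463

for r in compute_fic(ds, truth.ailment_map)[:3]:
    print(f"{r.icpc_category}: Nur={r.nur} Nt={r.nt} Fic={r.fic}")
# Respiratory diseases: Nur=149 Nt=17 Fic=0.89
# Musculoskeletal diseases: Nur=50 Nt=7 Fic=0.88
# Eye diseases: Nur=36 Nt=6 Fic=0.86

top = compute_species_indices(ds)[0]
print(top.canonical_name, top.sum_ui, top.uv, top.fc, top.rfc)
# Genusbh sylvestris 56 0.7 50 0.63

print(round(demographic_summary(ds).female_male_ratio, 2))
# 1.49
```

The simulated survey has 80 included informants and 83 species in 48
families. The respiratory category draws 149 use reports onto only 17
taxa, so its consensus is high (Fic = 0.89); the top species collects
56 reports from 50 distinct informants (UV = 56/80 = 0.70,
RFC = 50/80 = 0.63). Women were simulated to know 6 species on average
versus 4 for men, and the estimated ratio recovers that (1.49 ≈ 1.5).

The same run from a shell:

```sh
ethnoconsensus simulate --preset kinmen --seed 42 --out survey/
ethnoconsensus run --input survey/ --out results/
```

which writes `indices.csv`, `fic.csv`, `consensus_report.json`,
`crossref.csv`, `novelty.csv`, `network.graphml`, `summary.md` and a
`manifest.json` with input digests for auditability.

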