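"""Per-species importance indices, category consensus, and tabulations.

Definitions (N = number of included informants):

* ``UV = ΣUi / N`` — use value: total use reports for a species per
  informant.  Each (informant, species, ailment) triple is one report,
  so an informant citing a species for two ailments contributes Ui = 2.
* ``FC`` — frequency of citation: distinct informants citing a species;
  ``RFC = FC / N``.
* ``Fic = (Nur − Nt) / (Nur − 1)`` — factor of informant consensus per
  ICPC category, where Nur is the number of use reports in the category
  and Nt the number of distinct taxa cited for it.  Fic is 1 when all
  informants converge on a single taxon and 0 when every report names a
  different taxon; a category with Nur ≤ 1 has no defined denominator
  and takes the configured degenerate value (default 0).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .survey_model import (
    AilmentMap,
    AnalysisConfig,
    SurveyDataset,
    round_half_up,
)

__all__ = [
    "SpeciesIndexRow",
    "CategoryConsensusRow",
    "FrequencyTable",
    "compute_species_indices",
    "compute_fic",
    "tabulate_attribute",
    "demographic_summary",
    "DemographicSummary",
]


@dataclass(frozen=True)
class SpeciesIndexRow:
    species_id: str
    canonical_name: str
    family: str
    sum_ui: int
    fc: int
    uv_raw: Fraction
    rfc_raw: Fraction
    uv: float
    rfc: float


@dataclass(frozen=True)
class CategoryConsensusRow:
    icpc_category: str
    nur: int
    nt: int
    fic_raw: Fraction | None  # None when Nur <= 1 (degenerate denominator)
    fic: float


@dataclass(frozen=True)
class FrequencyTable:
    attribute: str
    rows: tuple[tuple[str, int, float], ...]  # (value, count, pct)
    denominator: int


def compute_species_indices(
    ds: SurveyDataset,
    config: AnalysisConfig | None = None,
    include_uncited: bool = False,
) -> list[SpeciesIndexRow]:
    """One index row per species, sorted by UV descending.

    Ties are broken by FC descending, then canonical name, so the table
    order is deterministic.  ``include_uncited`` adds zero rows for
    species in the checklist that no informant cited.
    """
    config = config or AnalysisConfig()
    n = ds.n_informants
    if n <= 0:
        raise ValueError("cannot compute indices with zero included informants")
    digits = config.rounding_digits
    sum_ui: dict[str, int] = defaultdict(int)
    citers: dict[str, set[str]] = defaultdict(set)
    for rep in ds.reports:
        sum_ui[rep.species_id] += 1
        citers[rep.species_id].add(rep.informant_id)
    rows = []
    for sp in ds.species:
        ui = sum_ui.get(sp.species_id, 0)
        if ui == 0 and not include_uncited:
            continue
        fc = len(citers.get(sp.species_id, ()))
        uv_raw = Fraction(ui, n)
        rfc_raw = Fraction(fc, n)
        rows.append(
            SpeciesIndexRow(
                species_id=sp.species_id,
                canonical_name=sp.canonical_name,
                family=sp.family,
                sum_ui=ui,
                fc=fc,
                uv_raw=uv_raw,
                rfc_raw=rfc_raw,
                uv=round_half_up(uv_raw, digits),
                rfc=round_half_up(rfc_raw, digits),
            )
        )
    rows.sort(key=lambda r: (-r.uv_raw, -r.fc, r.canonical_name))
    return rows


def compute_fic(
    ds: SurveyDataset,
    ailment_map: AilmentMap,
    config: AnalysisConfig | None = None,
) -> list[CategoryConsensusRow]:
    """Consensus row per ICPC category present in the reports.

    Nt counts distinct *taxa* cited for the category.  Rows are sorted
    by Fic descending, ties by Nur descending then category name.
    """
    config = config or AnalysisConfig()
    digits = config.rounding_digits
    nur: dict[str, int] = defaultdict(int)
    taxa: dict[str, set[str]] = defaultdict(set)
    for rep in ds.reports:
        category = ailment_map[rep.ailment_text]  # KeyError names the ailment
        nur[category] += 1
        taxa[category].add(rep.species_id)
    rows = []
    for category in nur:
        n_ur = nur[category]
        n_t = len(taxa[category])
        if n_ur <= 1:
            fic_raw: Fraction | None = None
            fic = round_half_up(config.fic_degenerate_value, digits)
        else:
            fic_raw = Fraction(n_ur - n_t, n_ur - 1)
            fic = round_half_up(fic_raw, digits)
        rows.append(CategoryConsensusRow(category, n_ur, n_t, fic_raw, fic))
    rows.sort(key=lambda r: (-(r.fic_raw if r.fic_raw is not None else Fraction(-1)), -r.nur, r.icpc_category))
    return rows


_SPECIES_LEVEL_ATTRS = {
    "part": lambda rep: rep.parts(),
    "preparation": lambda rep: rep.preparations(),
    "route": lambda rep: rep.routes(),
}


def tabulate_attribute(
    ds: SurveyDataset,
    attribute: str,
    config: AnalysisConfig | None = None,
) -> FrequencyTable:
    """Frequency table for a survey attribute.

    Multi-count semantics follow the field convention for species-level
    attributes: a species recorded with two distinct parts contributes
    two to the parts denominator, so a parts table over 83 species can
    have denominator 91.  ``family`` counts each species once;
    ``knowledge_source`` counts each (informant, source) pair once, so
    the denominator can exceed the number of informants.
    """
    config = config or AnalysisConfig()
    digits = config.rounding_digits
    counts: dict[str, int] = defaultdict(int)
    if attribute in _SPECIES_LEVEL_ATTRS:
        getter = _SPECIES_LEVEL_ATTRS[attribute]
        per_species: dict[str, set[str]] = defaultdict(set)
        for rep in ds.reports:
            per_species[rep.species_id].update(getter(rep))
        for values in per_species.values():
            for v in values:
                counts[v] += 1
    elif attribute == "family":
        # denominator is the number of collected species, not of families
        for sp in ds.species:
            counts[sp.family] += 1
    elif attribute == "knowledge_source":
        for inf in ds.informants:
            if not inf.included:
                continue
            for src in set(inf.knowledge_sources):
                counts[src] += 1
    else:
        raise ValueError(f"unknown attribute {attribute!r}")
    denom = sum(counts.values())
    rows = tuple(
        (value, count, round_half_up(Fraction(100 * count, denom), digits) if denom else 0.0)
        for value, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return FrequencyTable(attribute=attribute, rows=rows, denominator=denom)


@dataclass(frozen=True)
class DemographicSummary:
    mean_species_by_gender: dict[str, float]
    female_male_ratio: float | None
    gender: FrequencyTable
    age_band: FrequencyTable
    education: FrequencyTable
    township: FrequencyTable
    knowledge_source: FrequencyTable


def demographic_summary(ds: SurveyDataset, config: AnalysisConfig | None = None) -> DemographicSummary:
    """Respondent statistics: who knows how many plants.

    The headline number is the per-gender mean count of distinct species
    cited and their female/male ratio (the survey's "women know 1.5×
    more plants" statistic).  Frequency tables report raw fractions;
    display rounding is left to the caller.
    """
    config = config or AnalysisConfig()
    included = [i for i in ds.informants if i.included]
    if not included:
        raise ValueError("no included informants")
    species_per_informant: dict[str, set[str]] = defaultdict(set)
    for rep in ds.reports:
        species_per_informant[rep.informant_id].add(rep.species_id)
    by_gender: dict[str, list[int]] = defaultdict(list)
    for inf in included:
        by_gender[inf.gender].append(len(species_per_informant.get(inf.informant_id, ())))
    means = {g: sum(v) / len(v) for g, v in by_gender.items()}
    if "female" in means and "male" in means and means["male"] > 0:
        ratio: float | None = means["female"] / means["male"]
    else:
        ratio = None

    def _table(attr: str) -> FrequencyTable:
        counts: dict[str, int] = defaultdict(int)
        for inf in included:
            counts[getattr(inf, attr)] += 1
        denom = len(included)
        rows = tuple(
            (v, c, round_half_up(Fraction(100 * c, denom), config.rounding_digits))
            for v, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        return FrequencyTable(attribute=attr, rows=rows, denominator=denom)

    return DemographicSummary(
        mean_species_by_gender=means,
        female_male_ratio=ratio,
        gender=_table("gender"),
        age_band=_table("age_band"),
        education=_table("education"),
        township=_table("township"),
        knowledge_source=tabulate_attribute(ds, "knowledge_source", config),
    )
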