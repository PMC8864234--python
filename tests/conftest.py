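"""Shared fixtures: programmatic builders for small survey datasets."""

from __future__ import annotations

import pytest

from ethnoconsensus.survey_model import (
    AilmentMap,
    Informant,
    SpeciesRecord,
    SurveyDataset,
    UseReport,
)


def make_informant(i: int, gender: str = "female", included: bool = True) -> Informant:
    return Informant(
        informant_id=f"I{i:03d}",
        gender=gender,
        age_band=">60",
        township="Jincheng",
        education="elementary",
        knowledge_sources=("oral-transmission",),
        included=included,
    )


def make_species(j: int, family: str = "FamA", name: str | None = None, status: str | None = None) -> SpeciesRecord:
    return SpeciesRecord(
        species_id=f"S{j:03d}",
        canonical_name=name or f"Genus{chr(ord('a') + j)} communis",
        family=family,
        red_list_status=status,
    )


def build_dataset(
    n_informants: int,
    species: list[SpeciesRecord],
    citations: list[tuple[int, int, str]],
    n_excluded: int = 0,
    part: str = "Wp",
) -> SurveyDataset:
    """Dataset from (informant index, species index, ailment) triples."""
    informants = [make_informant(i) for i in range(n_informants)]
    informants += [make_informant(1000 + k, included=False) for k in range(n_excluded)]
    reports = [
        UseReport(
            informant_id=f"I{i:03d}",
            species_id=species[j].species_id,
            ailment_text=ailment,
            part=part,
            preparation="decoction-fresh",
            route="oral",
        )
        for i, j, ailment in citations
    ]
    return SurveyDataset(informants=tuple(informants), species=tuple(species), reports=tuple(reports))


def dataset_for_counts(n: int, counts: list[tuple[int, int]]) -> SurveyDataset:
    """Dataset realizing per-species (ΣUi, FC) against N informants.

    Species k is cited by its first ``fc`` informants once, then the
    first ``sum_ui - fc`` of those informants cite it for one extra
    ailment each (requires sum_ui <= 2*fc).
    """
    species = [make_species(k) for k in range(len(counts))]
    citations: list[tuple[int, int, str]] = []
    for k, (sum_ui, fc) in enumerate(counts):
        assert fc <= n and fc <= sum_ui <= 2 * fc
        for i in range(fc):
            citations.append((i, k, f"ailment-{k}-a"))
        for i in range(sum_ui - fc):
            citations.append((i, k, f"ailment-{k}-b"))
    return build_dataset(n, species, citations)


def dataset_for_category_counts(counts: dict[str, tuple[int, int]]) -> tuple[SurveyDataset, AilmentMap]:
    """Dataset realizing per-category (Nur, Nt) pairs.

    Category c gets ``nt`` distinct species; its ``nur`` reports are
    spread round-robin over those species, each report from a distinct
    informant so report multiplicity never collapses.
    """
    species: list[SpeciesRecord] = []
    citations: list[tuple[int, int, str]] = []
    mapping: dict[str, str] = {}
    n_informants = max(nur for nur, _ in counts.values())
    for c_idx, (category, (nur, nt)) in enumerate(counts.items()):
        assert 1 <= nt <= nur
        base = len(species)
        species += [make_species(base + k, family=f"Fam{c_idx}") for k in range(nt)]
        ailment = f"ailment-cat{c_idx}"
        mapping[ailment] = category
        for r in range(nur):
            citations.append((r % n_informants, base + (r % nt), ailment))
    # distinct informant per report within a (species, ailment) pair:
    # round-robin informants above can repeat a pair; disambiguate ailments
    seen: dict[tuple[int, int, str], int] = {}
    fixed: list[tuple[int, int, str]] = []
    extra_map: dict[str, str] = {}
    for i, j, a in citations:
        rep = seen.get((i, j, a), 0)
        seen[(i, j, a)] = rep + 1
        if rep:
            a2 = f"{a}-r{rep}"
            extra_map[a2] = mapping[a]
            fixed.append((i, j, a2))
        else:
            fixed.append((i, j, a))
    mapping.update(extra_map)
    ds = build_dataset(n_informants, species, fixed)
    return ds, AilmentMap(mapping)


@pytest.fixture
def tiny_dataset() -> SurveyDataset:
    """3 informants, 3 species, 5 reports; informant 0 cites species 0 twice."""
    species = [make_species(0), make_species(1), make_species(2)]
    citations = [
        (0, 0, "cough"),
        (0, 0, "fever"),
        (1, 0, "cough"),
        (1, 1, "joint pain"),
        (2, 1, "joint pain"),
    ]
    return build_dataset(3, species, citations)


@pytest.fixture
def tiny_ailment_map() -> AilmentMap:
    return AilmentMap(
        {
            "cough": "Respiratory diseases",
            "fever": "General and unspecified diseases",
            "joint pain": "Musculoskeletal diseases",
        }
    )
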