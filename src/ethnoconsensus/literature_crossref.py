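"""Cross-referencing the survey against published floras and catalogues.

A regional survey is interpreted against reference works — a local
flora, a national medicinal-plant catalogue, a materia medica from a
neighbouring region, or membership-only regulatory lists.  This module
computes the standard comparisons: species overlap percentages,
shared-use agreement (species whose recorded efficacy matches every
reference), novelty detection (species and uses absent from all
references), and annotation tallies such as red-list status counts.

Matching is at the level of the authority-free canonical binomial; no
live taxonomic service is consulted, so results are reproducible from
the input tables alone.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .indices import FrequencyTable
from .survey_model import (
    AnalysisConfig,
    MULTI_SEP,
    SurveyDataset,
    canonicalize_name,
    round_half_up,
)

__all__ = [
    "ReferenceFlora",
    "OverlapResult",
    "NoveltyResult",
    "overlap",
    "shared_use",
    "detect_novelty",
    "annotation_counts",
    "load_reference_flora",
    "write_reference_flora",
]


@dataclass(frozen=True)
class ReferenceFlora:
    """A published species list, optionally with species→use-term maps."""

    name: str
    species: frozenset[str]
    uses: Mapping[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.uses is not None:
            stray = set(self.uses) - set(self.species)
            if stray:
                raise ValueError(f"use-map keys not in species list: {sorted(stray)[:5]}")

    @staticmethod
    def from_names(
        name: str,
        species: Iterable[str],
        uses: Mapping[str, Iterable[str]] | None = None,
    ) -> "ReferenceFlora":
        canon = frozenset(canonicalize_name(s) for s in species)
        canon_uses = (
            {canonicalize_name(k): frozenset(v) for k, v in uses.items()} if uses is not None else None
        )
        return ReferenceFlora(name=name, species=canon, uses=canon_uses)


@dataclass(frozen=True)
class OverlapResult:
    reference: str
    n_survey: int
    n_matched: int
    pct: float


@dataclass(frozen=True)
class NoveltyResult:
    novel_species: frozenset[str]
    novel_uses: tuple[tuple[str, str], ...]  # (canonical_name, use term)

    @property
    def n_novel_species(self) -> int:
        return len(self.novel_species)

    @property
    def n_novel_uses(self) -> int:
        return len(self.novel_uses)


def overlap(
    survey_species: Iterable[str],
    ref: ReferenceFlora,
    config: AnalysisConfig | None = None,
) -> OverlapResult:
    """Fraction of survey species listed in the reference.

    Exact set intersection on canonical binomials; the percentage is
    over the survey species count (e.g. 78 of 83 matched → 93.98).
    """
    config = config or AnalysisConfig()
    survey = {canonicalize_name(s) for s in survey_species}
    if not survey:
        raise ValueError("empty survey species set")
    matched = survey & ref.species
    pct = round_half_up(Fraction(100 * len(matched), len(survey)), config.rounding_digits)
    return OverlapResult(reference=ref.name, n_survey=len(survey), n_matched=len(matched), pct=pct)


def survey_use_sets(ds: SurveyDataset, use_map: Mapping[str, str]) -> dict[str, set[str]]:
    """Map each surveyed species to its set of controlled use terms.

    ``use_map`` translates free-text ailments to the controlled use
    vocabulary shared with the references; an ailment missing from the
    map is an error (silent drops would understate agreement).
    """
    out: dict[str, set[str]] = defaultdict(set)
    names = {s.species_id: s.canonical_name for s in ds.species}
    for rep in ds.reports:
        if rep.ailment_text not in use_map:
            raise KeyError(f"ailment {rep.ailment_text!r} missing from use vocabulary map")
        out[names[rep.species_id]].add(use_map[rep.ailment_text])
    return dict(out)


def shared_use(
    ds: SurveyDataset,
    refs: Sequence[ReferenceFlora],
    use_map: Mapping[str, str],
    config: AnalysisConfig | None = None,
) -> tuple[int, float]:
    """Species whose survey uses agree with EVERY listed reference.

    A species counts as shared when its surveyed use-term set intersects
    the use-term set recorded for it in each reference.  Returns the
    count and the percentage over all surveyed species.
    """
    config = config or AnalysisConfig()
    for ref in refs:
        if ref.uses is None:
            raise ValueError(f"reference {ref.name!r} has no use map")
    uses = survey_use_sets(ds, use_map)
    n_survey = len({s.canonical_name for s in ds.species})
    if n_survey == 0:
        raise ValueError("empty survey species set")
    n_shared = 0
    for name, survey_terms in uses.items():
        if all(survey_terms & ref.uses.get(name, frozenset()) for ref in refs):
            n_shared += 1
    pct = round_half_up(Fraction(100 * n_shared, n_survey), config.rounding_digits)
    return n_shared, pct


def detect_novelty(
    ds: SurveyDataset,
    refs: Sequence[ReferenceFlora],
    use_map: Mapping[str, str] | None = None,
    include_novel_species_uses: bool = False,
) -> NoveltyResult:
    """Species and uses absent from every reference.

    ``novel_species`` are survey species in no reference's species list.
    ``novel_uses`` are (species, use) pairs found in no reference use
    map; by default the uses of novel species are reported only through
    ``novel_species`` (the convention that separates "new plant" from
    "new use of a known plant"), switchable with
    ``include_novel_species_uses``.
    """
    survey = {s.canonical_name for s in ds.species}
    all_ref_species: set[str] = set()
    for ref in refs:
        all_ref_species |= ref.species
    novel_species = frozenset(survey - all_ref_species)
    novel_uses: list[tuple[str, str]] = []
    if use_map is not None:
        uses = survey_use_sets(ds, use_map)
        for name in sorted(uses):
            if name in novel_species and not include_novel_species_uses:
                continue
            for term in sorted(uses[name]):
                known = any(term in ref.uses.get(name, frozenset()) for ref in refs if ref.uses is not None)
                if not known:
                    novel_uses.append((name, term))
    return NoveltyResult(novel_species=novel_species, novel_uses=tuple(novel_uses))


def annotation_counts(ds: SurveyDataset, annotation_field: str = "red_list_status") -> FrequencyTable:
    """Tally species per annotation value (e.g. red-list status).

    Species without the annotation land in an explicit ``unannotated``
    bucket, so the counts always sum to the species total.
    """
    if annotation_field not in {"red_list_status", "source"}:
        raise ValueError(f"unknown annotation field {annotation_field!r}")
    counts: dict[str, int] = defaultdict(int)
    for sp in ds.species:
        value = getattr(sp, annotation_field)
        counts[value if value else "unannotated"] += 1
    denom = sum(counts.values())
    rows = tuple(
        (v, c, round_half_up(Fraction(100 * c, denom), 2))
        for v, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return FrequencyTable(attribute=annotation_field, rows=rows, denominator=denom)


# ---------------------------------------------------------------------------
# Reference-flora CSV I/O  (columns: canonical_name[,uses])
# ---------------------------------------------------------------------------

def load_reference_flora(path: str | Path, name: str | None = None) -> ReferenceFlora:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, encoding="utf-8", keep_default_na=False)
    if "canonical_name" not in df.columns:
        raise ValueError(f"{path.name}: missing 'canonical_name' column")
    species = [canonicalize_name(s) for s in df["canonical_name"] if s.strip()]
    uses: dict[str, frozenset[str]] | None = None
    if "uses" in df.columns:
        uses = {}
        for raw_name, cell in zip(df["canonical_name"], df["uses"]):
            terms = frozenset(t.strip() for t in str(cell).split(MULTI_SEP) if t.strip())
            if terms:
                uses[canonicalize_name(raw_name)] = terms
    return ReferenceFlora(name=name or path.stem, species=frozenset(species), uses=uses)


def write_reference_flora(ref: ReferenceFlora, path: str | Path) -> None:
    rows = []
    for sp in sorted(ref.species):
        terms = sorted(ref.uses.get(sp, frozenset())) if ref.uses is not None else []
        rows.append({"canonical_name": sp, "uses": MULTI_SEP.join(terms)})
    pd.DataFrame(rows, columns=["canonical_name", "uses"]).to_csv(path, index=False, encoding="utf-8")
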