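"""Three-step consensus interpretation.

The reading order a field ethnobotanist applies to the consensus table:
first screen disease categories by Fic (high Fic = informants agree on
a few taxa), then inspect Nur to see whether the category is a common
local complaint, and finally rank the plants cited within each retained
category by their category-restricted frequency of citation, which
flags the species with the strongest claim to follow-up study.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .indices import CategoryConsensusRow, SpeciesIndexRow
from .survey_model import AilmentMap, ICPC_CATEGORIES, SurveyDataset

__all__ = ["CategoryEntry", "ConsensusReport", "rank_plants_in_category", "interpret_consensus"]


@dataclass(frozen=True)
class CategoryEntry:
    icpc_category: str
    fic: float
    nur: int
    nt: int
    flagged_common_disease: bool
    ranked_plants: tuple[tuple[str, int], ...]  # (canonical_name, category FC)


@dataclass(frozen=True)
class ConsensusReport:
    fic_threshold: float
    nur_threshold: int
    categories: tuple[CategoryEntry, ...]

    def to_dict(self) -> dict:
        return {
            "fic_threshold": self.fic_threshold,
            "nur_threshold": self.nur_threshold,
            "categories": [
                {
                    "icpc_category": c.icpc_category,
                    "fic": c.fic,
                    "nur": c.nur,
                    "nt": c.nt,
                    "flagged_common_disease": c.flagged_common_disease,
                    "ranked_plants": [[name, fc] for name, fc in c.ranked_plants],
                }
                for c in self.categories
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, ensure_ascii=False), encoding="utf-8")

    def to_markdown(self) -> str:
        lines = ["# Consensus report", ""]
        for c in self.categories:
            flag = " (common local disease)" if c.flagged_common_disease else ""
            lines.append(f"## {c.icpc_category}{flag}")
            lines.append(f"Fic = {c.fic:.2f}, Nur = {c.nur}, Nt = {c.nt}")
            for name, fc in c.ranked_plants:
                lines.append(f"- {name} (FC = {fc})")
            lines.append("")
        return "\n".join(lines)


def rank_plants_in_category(
    ds: SurveyDataset, ailment_map: AilmentMap, category: str
) -> list[tuple[str, int]]:
    """Species cited for ``category``, ranked by distinct citing informants.

    The count is category-restricted: only reports whose ailment maps to
    ``category`` contribute, so a species' category FC never exceeds its
    global FC.  Ties are broken by canonical name.
    """
    if category not in ICPC_CATEGORIES:
        raise ValueError(f"unknown ICPC category {category!r}")
    names = {s.species_id: s.canonical_name for s in ds.species}
    citers: dict[str, set[str]] = defaultdict(set)
    for rep in ds.reports:
        if ailment_map[rep.ailment_text] == category:
            citers[rep.species_id].add(rep.informant_id)
    ranked = [(names[sid], len(infs)) for sid, infs in citers.items()]
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return ranked


def interpret_consensus(
    index_rows: Sequence[SpeciesIndexRow],
    consensus_rows: Sequence[CategoryConsensusRow],
    ds: SurveyDataset,
    ailment_map: AilmentMap,
    fic_threshold: float = 0.8,
    nur_threshold: int = 50,
) -> ConsensusReport:
    """Screen categories by Fic, flag common diseases by Nur, rank plants.

    Categories with rounded Fic >= ``fic_threshold`` are retained and
    ordered by Fic descending (ties by Nur descending); each carries its
    FC-ranked plant list restricted to that category's reports.
    """
    if not 0 <= fic_threshold <= 1:
        raise ValueError("fic_threshold must be in [0, 1]")
    if nur_threshold < 0:
        raise ValueError("nur_threshold must be >= 0")
    entries = []
    for row in consensus_rows:
        if row.fic < fic_threshold:
            continue
        entries.append(
            CategoryEntry(
                icpc_category=row.icpc_category,
                fic=row.fic,
                nur=row.nur,
                nt=row.nt,
                flagged_common_disease=row.nur >= nur_threshold,
                ranked_plants=tuple(rank_plants_in_category(ds, ailment_map, row.icpc_category)),
            )
        )
    entries.sort(key=lambda e: (-e.fic, -e.nur, e.icpc_category))
    return ConsensusReport(fic_threshold=fic_threshold, nur_threshold=nur_threshold, categories=tuple(entries))
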