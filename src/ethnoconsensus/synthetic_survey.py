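"""Synthetic survey generator with known ground truth.

Emulates the statistical structure of a small-island medicinal-plant
survey: ~80 fully interviewed informants stratified by gender, age,
education and township; ~83 species in ~48 families with a skewed
family-size law; one-to-many use reports per informant whose species
choice is concentrated within disease categories; and reference floras
covering a configurable fraction of the species pool.

The two behavioural dials are:

* ``knowledge_rate`` — per-gender mean number of distinct species an
  informant cites, drawn zero-truncated Poisson (respondents who would
  draw zero knowledge are emitted as *excluded* interviewees);
* ``concentration`` — per-category symmetric Dirichlet parameter over
  the species pool.  Low concentration puts most probability mass on a
  few taxa, so few taxa absorb the category's reports and the estimated
  Fic is high; high concentration spreads reports over many taxa and
  drives Fic toward 0.  This gives a single dial mapping to consensus.

All randomness flows from one :class:`numpy.random.Generator` seeded by
``SimConfig.seed``; identical configs yield byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .literature_crossref import ReferenceFlora
from .survey_model import (
    AilmentMap,
    ICPC_CATEGORIES,
    Informant,
    SpeciesRecord,
    SurveyDataset,
    UseReport,
    write_ailment_map,
    write_survey,
)

__all__ = ["SimConfig", "GroundTruth", "generate_survey", "make_reference_flora", "simulate_to_dir", "KINMEN_PRESET"]


# Attribute laws mirror a Southern-Fujian island survey: whole plant and
# leaves dominate parts; decoction dominates preparation; oral dominates route.
_PART_LAW = {
    "Wp": 0.36, "Le": 0.31, "Fr": 0.10, "Ro": 0.08,
    "St": 0.06, "Se": 0.05, "Fl": 0.03, "Cx": 0.01,
}
_PREP_LAW = {
    "decoction-fresh": 0.43, "decoction-dried": 0.15, "crush": 0.16,
    "soak": 0.09, "raw": 0.05, "fry": 0.03, "juice": 0.03,
    "burn": 0.02, "cook-with-meat": 0.02, "honey-maceration": 0.02,
}
_ROUTE_LAW = {
    "oral": 0.744, "apply-to-injuries": 0.128, "apply-to-skin": 0.058,
    "fomentation": 0.023, "chew": 0.012, "bath": 0.012,
    "fumigation": 0.012, "fill-teeth": 0.011,
}

_AGE_BANDS = ("20-30", "31-40", "41-50", "51-60", ">60")
_EDU_LEVELS = ("none", "elementary", "junior-high", "senior-high", "university+")
_TOWNSHIPS = ("Jincheng", "Kinhu", "Kinsha", "Jinning", "Lieyu")
_KNOWLEDGE_SOURCES = ("oral-transmission", "books", "media")


def _alpha(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa' ... (letters only, CSV-safe epithets)."""
    out = []
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out.append(chr(ord("a") + r))
    return "".join(reversed(out))


@dataclass
class SimConfig:
    """Generator parameters; defaults are the island-survey conditions."""

    seed: int = 0
    n_informants: int = 80          # fully interviewed (the index denominator N)
    n_excluded: int = 8             # approached but excluded, carry no reports
    gender_split: float = 45 / 80   # fraction female among included
    age_band_weights: Mapping[str, float] = field(
        default_factory=lambda: {"20-30": 7, "31-40": 12, "41-50": 15, "51-60": 12, ">60": 34}
    )
    education_weights: Mapping[str, float] = field(
        default_factory=lambda: {"none": 12, "elementary": 32, "junior-high": 14, "senior-high": 12, "university+": 10}
    )
    township_weights: Mapping[str, float] = field(
        default_factory=lambda: {"Jincheng": 16, "Kinhu": 22, "Kinsha": 19, "Jinning": 13, "Lieyu": 8}
    )
    knowledge_rate: Mapping[str, float] = field(
        default_factory=lambda: {"female": 6.0, "male": 4.0}
    )
    second_source_rate: float = 0.125   # 80 informants naming ~90 sources
    n_species: int = 83
    n_families: int = 48
    family_size_law: str = "skewed"     # or "uniform"
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(
            zip(ICPC_CATEGORIES, (63, 31, 136, 50, 102, 58, 18, 3, 18, 4, 1, 1))
        )
    )
    concentration: Mapping[str, float] = field(
        default_factory=lambda: dict(
            zip(
                ICPC_CATEGORIES,
                (0.03, 0.04, 0.06, 0.08, 0.12, 0.15, 0.30, 0.50, 0.60, 1.0, 1.0, 1.0),
            )
        )
    )
    ailments_per_category: int = 3
    reports_per_citation_mean: float = 1.1
    reference_coverage: Mapping[str, float] = field(
        default_factory=lambda: {
            "catalogue_taiwan": 78 / 83,
            "fujian_materia_medica": 54 / 83,
            "flora_kinmen": 50 / 83,
        }
    )
    use_agreement: float = 39 / 83

    def __post_init__(self) -> None:
        if self.n_informants <= 0 or self.n_species <= 0 or self.n_families <= 0:
            raise ValueError("counts must be positive")
        if self.n_species < self.n_families:
            raise ValueError("n_species must be >= n_families")
        if not 0 <= self.gender_split <= 1:
            raise ValueError("gender_split must be in [0, 1]")
        if self.reports_per_citation_mean < 1:
            raise ValueError("reports_per_citation_mean must be >= 1")
        if any(v <= 0 for v in self.knowledge_rate.values()):
            raise ValueError("knowledge rates must be > 0")
        if any(a <= 0 for a in self.concentration.values()):
            raise ValueError("concentration parameters must be > 0")
        for frac in list(self.reference_coverage.values()) + [self.use_agreement]:
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.family_size_law not in {"uniform", "skewed"}:
            raise ValueError("family_size_law must be 'uniform' or 'skewed'")


#: The study-scale configuration: 80 informants, 83 species, 48 families.
KINMEN_PRESET = SimConfig()


@dataclass
class GroundTruth:
    """Latent generator state for parameter-recovery tests."""

    concentration: dict[str, float]
    knowledge_rate: dict[str, float]
    category_weights: dict[str, float]
    ailment_map: AilmentMap
    species_category_probs: dict[str, np.ndarray]
    reference_membership: dict[str, dict[str, bool]] = field(default_factory=dict)
    use_agreement_flags: dict[str, dict[str, bool]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "concentration": self.concentration,
            "knowledge_rate": self.knowledge_rate,
            "category_weights": self.category_weights,
            "reference_membership": self.reference_membership,
            "use_agreement_flags": self.use_agreement_flags,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True), encoding="utf-8")


def _weighted_choice(rng: np.random.Generator, law: Mapping[str, float], size: int | None = None):
    keys = list(law)
    w = np.array([law[k] for k in keys], dtype=float)
    w /= w.sum()
    idx = rng.choice(len(keys), size=size, p=w)
    if size is None:
        return keys[int(idx)]
    return [keys[int(i)] for i in idx]


def _zt_poisson(rng: np.random.Generator, mu: float) -> int:
    """Zero-truncated Poisson via rejection (mu is the untruncated mean)."""
    while True:
        k = int(rng.poisson(mu))
        if k > 0:
            return k


def _make_species(cfg: SimConfig, rng: np.random.Generator) -> tuple[SpeciesRecord, ...]:
    # Family sizes: every family gets one species; under the skewed law the
    # remainder go preferentially to the first families (a Compositae-like
    # large family emerges), under the uniform law they are spread evenly.
    sizes = np.ones(cfg.n_families, dtype=int)
    extra = cfg.n_species - cfg.n_families
    if extra < 0:
        raise ValueError("n_species must be >= n_families")
    if extra:
        if cfg.family_size_law == "skewed":
            w = 1.0 / np.arange(1, cfg.n_families + 1)
        else:
            w = np.ones(cfg.n_families)
        w = w / w.sum()
        sizes += np.bincount(rng.choice(cfg.n_families, size=extra, p=w), minlength=cfg.n_families)
    species = []
    idx = 0
    for fam_i, size in enumerate(sizes):
        family = f"Family{_alpha(fam_i).capitalize()}"
        for j in range(size):
            genus = f"Genus{_alpha(idx)}"
            epithet = f"sylvestris" if j == 0 else f"communis{_alpha(j)}"
            status = None
            species.append(
                SpeciesRecord(
                    species_id=f"SP{idx + 1:03d}",
                    canonical_name=f"{genus.capitalize()} {epithet}",
                    family=family,
                    local_names=(f"local-{_alpha(idx)}",),
                    voucher_id=f"VCH{idx + 1:03d}",
                    source="wild" if rng.random() < 0.8 else "cultivated/institute",
                    red_list_status=status,
                )
            )
            idx += 1
    return tuple(species)


def generate_survey(cfg: SimConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Draw one complete survey dataset plus its latent ground truth."""
    rng = np.random.default_rng(cfg.seed)
    species = _make_species(cfg, rng)
    n_sp = len(species)
    categories = [c for c in cfg.category_weights if cfg.category_weights[c] > 0]

    # Per-category species-choice law: symmetric Dirichlet over the pool.
    cat_probs: dict[str, np.ndarray] = {
        c: rng.dirichlet(np.full(n_sp, cfg.concentration[c])) for c in categories
    }
    # Ailment vocabulary: a few distinct free-text ailments per category.
    ailment_map_d: dict[str, str] = {}
    cat_ailments: dict[str, list[str]] = {}
    for ci, c in enumerate(categories):
        names = [f"ailment-{ci + 1:02d}-{k + 1}" for k in range(cfg.ailments_per_category)]
        cat_ailments[c] = names
        for nm in names:
            ailment_map_d[nm] = c
    ailment_map = AilmentMap(ailment_map_d)

    # Informants: exact gender stratification, categorical demographics.
    n_female = int(round(cfg.gender_split * cfg.n_informants))
    informants: list[Informant] = []
    reports: list[UseReport] = []
    species_attrs: dict[int, tuple[str, str, str]] = {}

    def _species_attr(si: int) -> tuple[str, str, str]:
        if si not in species_attrs:
            part = _weighted_choice(rng, _PART_LAW)
            if rng.random() < 0.1:  # some species used through two parts
                second = _weighted_choice(rng, _PART_LAW)
                if second != part:
                    part = f"{part};{second}"
            prep = _weighted_choice(rng, _PREP_LAW)
            route = _weighted_choice(rng, _ROUTE_LAW)
            species_attrs[si] = (part, prep, route)
        return species_attrs[si]

    cw = np.array([cfg.category_weights[c] for c in categories], dtype=float)
    cw /= cw.sum()
    for i in range(cfg.n_informants):
        gender = "female" if i < n_female else "male"
        inf = Informant(
            informant_id=f"INF{i + 1:03d}",
            gender=gender,
            age_band=_weighted_choice(rng, cfg.age_band_weights),
            township=_weighted_choice(rng, cfg.township_weights),
            education=_weighted_choice(rng, cfg.education_weights),
            knowledge_sources=tuple(
                dict.fromkeys(
                    ["oral-transmission" if rng.random() < 0.9 else str(_weighted_choice(rng, {"books": 1, "media": 1}))]
                    + (["books"] if rng.random() < cfg.second_source_rate else [])
                )
            ),
            included=True,
        )
        informants.append(inf)
        k = _zt_poisson(rng, cfg.knowledge_rate[gender])
        k = min(k, n_sp)
        chosen: set[int] = set()
        while len(chosen) < k:
            c = categories[int(rng.choice(len(categories), p=cw))]
            si = int(rng.choice(n_sp, p=cat_probs[c]))
            for _ in range(50):
                if si not in chosen:
                    break
                si = int(rng.choice(n_sp, p=cat_probs[c]))
            if si in chosen:  # heavy concentration exhausted: pick any unused
                remaining = [s for s in range(n_sp) if s not in chosen]
                si = int(remaining[int(rng.integers(len(remaining)))])
            chosen.add(si)
            m = 1 + int(rng.poisson(cfg.reports_per_citation_mean - 1))
            m = min(m, len(cat_ailments[c]))
            ailments = rng.choice(cat_ailments[c], size=m, replace=False)
            part, prep, route = _species_attr(si)
            for ailment in ailments:
                reports.append(
                    UseReport(
                        informant_id=inf.informant_id,
                        species_id=species[si].species_id,
                        ailment_text=str(ailment),
                        part=part,
                        preparation=prep,
                        route=route,
                    )
                )
    for j in range(cfg.n_excluded):
        informants.append(
            Informant(
                informant_id=f"EXC{j + 1:03d}",
                gender="male" if j % 2 else "female",
                age_band="20-30",
                township=_weighted_choice(rng, cfg.township_weights),
                education="university+",
                knowledge_sources=("media",),
                included=False,
            )
        )

    # Sparse red-list annotation on a fixed fraction of species.
    annotated = rng.choice(n_sp, size=min(34, n_sp), replace=False)
    statuses = ["EN"] + ["VU"] * 2 + ["NT"] + ["LC"] * 13 + ["DD"] + ["NA"] * 16
    species_list = list(species)
    for si, st in zip(annotated, statuses):
        sp = species_list[si]
        species_list[si] = SpeciesRecord(
            species_id=sp.species_id,
            canonical_name=sp.canonical_name,
            family=sp.family,
            local_names=sp.local_names,
            voucher_id=sp.voucher_id,
            source=sp.source,
            red_list_status=st,
        )

    ds = SurveyDataset(
        informants=tuple(informants), species=tuple(species_list), reports=tuple(reports)
    )
    gt = GroundTruth(
        concentration=dict(cfg.concentration),
        knowledge_rate=dict(cfg.knowledge_rate),
        category_weights={c: float(w) for c, w in zip(categories, cw)},
        ailment_map=ailment_map,
        species_category_probs=cat_probs,
    )
    return ds, gt


def make_reference_flora(
    gt: GroundTruth,
    ds: SurveyDataset,
    coverage: float,
    agreement: float,
    seed: int,
    name: str = "reference",
) -> ReferenceFlora:
    """Build a reference flora covering a chosen fraction of the survey.

    ``round(coverage * n_species)`` survey species are listed; among the
    listed species that the survey actually cites, ``round(agreement *
    n_listed_cited)`` carry a use term matching one of the species'
    surveyed disease categories, the rest an unrelated term.  Membership
    and agreement flags are recorded on the ground truth.
    """
    if not (0 <= coverage <= 1 and 0 <= agreement <= 1):
        raise ValueError("coverage and agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    names = [s.canonical_name for s in ds.species]
    n_inc = int(round(coverage * len(names)))
    order = rng.permutation(len(names))
    included = [names[i] for i in sorted(order[:n_inc])]

    # Surveyed use terms per species (disease categories actually cited).
    surveyed: dict[str, set[str]] = {}
    id_to_name = {s.species_id: s.canonical_name for s in ds.species}
    for rep in ds.reports:
        surveyed.setdefault(id_to_name[rep.species_id], set()).add(
            gt.ailment_map[rep.ailment_text]
        )
    cited_included = [n for n in included if n in surveyed]
    n_agree = int(round(agreement * len(cited_included)))
    agree_idx = set(rng.permutation(len(cited_included))[:n_agree].tolist())
    uses: dict[str, frozenset[str]] = {}
    flags: dict[str, bool] = {}
    for pos, nm in enumerate(cited_included):
        if pos in agree_idx:
            term = sorted(surveyed[nm])[int(rng.integers(len(surveyed[nm])))]
            uses[nm] = frozenset({term})
            flags[nm] = True
        else:
            uses[nm] = frozenset({"unrelated-use"})
            flags[nm] = False
    for nm in included:
        if nm not in uses:
            uses[nm] = frozenset({"unrelated-use"})
    gt.reference_membership[name] = {nm: nm in set(included) for nm in names}
    gt.use_agreement_flags[name] = flags
    return ReferenceFlora(name=name, species=frozenset(included), uses=uses)


def simulate_to_dir(cfg: SimConfig, out_dir: str | Path) -> Path:
    """Write the standard CSV schema plus ``ailment_map.csv`` and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds, gt = generate_survey(cfg)
    write_survey(ds, out_dir)
    write_ailment_map(gt.ailment_map, out_dir / "ailment_map.csv")
    refs_dir = out_dir / "references"
    refs_dir.mkdir(exist_ok=True)
    from .literature_crossref import write_reference_flora

    for i, (ref_name, coverage) in enumerate(sorted(cfg.reference_coverage.items())):
        ref = make_reference_flora(
            gt, ds, coverage, cfg.use_agreement, seed=cfg.seed + 1000 + i, name=ref_name
        )
        write_reference_flora(ref, refs_dir / f"{ref_name}.csv")
    gt.to_json(out_dir / "ground_truth.json")
    return out_dir
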