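"""Domain model for ethnobotanical use-report surveys.

The atomic record is a *use report*: one informant citing one plant
species for one ailment.  Everything downstream — the use value (UV),
frequency of citation (FC), relative frequency of citation (RFC) and
the factor of informant consensus (Fic) — is a count over these
records, so the model is deliberately plain: typed records, CSV
readers/writers for the long-format tables a field team would keep,
validation that turns data problems into located issues, and a
botanical-name canonicalizer used as the matching key everywhere.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PART_VOCAB",
    "PREPARATION_VOCAB",
    "ROUTE_VOCAB",
    "ICPC_CATEGORIES",
    "RED_LIST_VOCAB",
    "Informant",
    "SpeciesRecord",
    "UseReport",
    "AilmentMap",
    "SurveyDataset",
    "AnalysisConfig",
    "ValidationIssue",
    "SurveyValidationError",
    "round_half_up",
    "canonicalize_name",
    "load_survey",
    "write_survey",
    "load_ailment_map",
    "validate",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Plant-part codes: leaves, stems, roots, fruits, whole plant, seeds,
#: flowers, calyx.
PART_VOCAB = frozenset({"Le", "St", "Ro", "Fr", "Wp", "Se", "Fl", "Cx"})

PREPARATION_VOCAB = frozenset(
    {
        "decoction-fresh",
        "decoction-dried",
        "crush",
        "soak",
        "raw",
        "fry",
        "juice",
        "burn",
        "cook-with-meat",
        "honey-maceration",
    }
)

ROUTE_VOCAB = frozenset(
    {
        "oral",
        "apply-to-injuries",
        "apply-to-skin",
        "fomentation",
        "chew",
        "bath",
        "fumigation",
        "fill-teeth",
    }
)

#: ICPC ailment categories used to group free-text ailments for the
#: consensus analysis.
ICPC_CATEGORIES = (
    "Musculoskeletal diseases",
    "Eye diseases",
    "Respiratory diseases",
    "Diseases related to blood, blood-forming organs, lymph, spleen",
    "General and unspecified diseases",
    "Digestive diseases",
    "Urological diseases",
    "Female genital system and breast diseases",
    "Endocrine, metabolic, and nutritional diseases",
    "Psychological diseases",
    "Cardiovascular diseases",
    "Male genital system diseases",
)

RED_LIST_VOCAB = frozenset({"EN", "VU", "NT", "LC", "DD", "NA"})

GENDER_VOCAB = frozenset({"male", "female"})

#: Inner separator for multi-valued CSV cells (parts, local names, ...).
MULTI_SEP = ";"


# ---------------------------------------------------------------------------
# Rounding
# ---------------------------------------------------------------------------

def round_half_up(x: float | Fraction | int, digits: int = 2) -> float:
    """Round ``x`` half-up (commercial rounding) to ``digits`` decimals.

    Survey indices are ratios of small integers, so ties at the rounding
    digit (e.g. 74/80 = 0.925) are common; banker's rounding would send
    half of them the wrong way relative to the published convention.
    Fractions are converted through exact decimal division so that a tie
    is recognised as a tie.
    """
    if digits < 0:
        raise ValueError("digits must be >= 0")
    quantum = Decimal(1).scaleb(-digits)
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(str(x))
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Informant:
    """One survey respondent.

    ``included`` marks respondents who completed the interview and
    therefore enter the informant denominator N; excluded respondents
    (e.g. those reporting no medicinal-plant experience) are retained
    for demographic bookkeeping only and must carry no use reports.
    """

    informant_id: str
    gender: str
    age_band: str
    township: str
    education: str
    knowledge_sources: tuple[str, ...] = ()
    included: bool = True


@dataclass(frozen=True)
class SpeciesRecord:
    """One voucher-anchored plant species.

    ``canonical_name`` is the authority-free binomial used as the
    matching key in every cross-reference; ``local_names`` may contain
    CJK or diacritics and are never used for matching.
    """

    species_id: str
    canonical_name: str
    family: str
    local_names: tuple[str, ...] = ()
    voucher_id: str | None = None
    source: str = "wild"
    red_list_status: str | None = None


@dataclass(frozen=True)
class UseReport:
    """One informant citing one species for one ailment.

    This is the unit of Ui (per-species use reports) and of Nur
    (per-category use reports).  ``part``, ``preparation`` and ``route``
    may hold several ``;``-separated vocabulary tokens; tabulations
    count each distinct value once per species.
    """

    informant_id: str
    species_id: str
    ailment_text: str
    part: str = ""
    preparation: str = ""
    route: str = ""

    def parts(self) -> tuple[str, ...]:
        return _split_multi(self.part)

    def preparations(self) -> tuple[str, ...]:
        return _split_multi(self.preparation)

    def routes(self) -> tuple[str, ...]:
        return _split_multi(self.route)


class AilmentMap:
    """Total mapping from free-text ailments to ICPC categories.

    The map must cover every ailment that occurs in the dataset; an
    unmapped ailment is a hard error, never a silent drop.
    """

    def __init__(self, mapping: Mapping[str, str]):
        unknown = {c for c in mapping.values() if c not in ICPC_CATEGORIES}
        if unknown:
            raise ValueError(f"unknown ICPC categories in ailment map: {sorted(unknown)}")
        self._map = dict(mapping)

    def __getitem__(self, ailment_text: str) -> str:
        try:
            return self._map[ailment_text]
        except KeyError:
            raise KeyError(f"ailment not mapped to an ICPC category: {ailment_text!r}") from None

    def __contains__(self, ailment_text: str) -> bool:
        return ailment_text in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def category_of(self, ailment_text: str) -> str:
        return self[ailment_text]


@dataclass
class SurveyDataset:
    """A validated survey: informants, species and use reports.

    ``n_informants`` is the denominator N of all indices: the number of
    *included* informants, not the number of people approached.
    """

    informants: tuple[Informant, ...]
    species: tuple[SpeciesRecord, ...]
    reports: tuple[UseReport, ...]

    @property
    def n_informants(self) -> int:
        return sum(1 for i in self.informants if i.included)

    def informant_by_id(self) -> dict[str, Informant]:
        return {i.informant_id: i for i in self.informants}

    def species_by_id(self) -> dict[str, SpeciesRecord]:
        return {s.species_id: s for s in self.species}


@dataclass
class AnalysisConfig:
    """Tunable knobs shared across pipeline stages."""

    rounding_digits: int = 2
    fic_degenerate_value: float = 0.0
    min_support: int = 2
    min_confidence: float = 0.5
    fic_threshold: float = 0.8
    nur_threshold: int = 50
    seed: int = 0
    ailment_map_path: str | None = None

    def __post_init__(self) -> None:
        if self.rounding_digits < 0:
            raise ValueError("rounding_digits must be >= 0")
        if self.min_support < 0 or self.min_confidence < 0:
            raise ValueError("thresholds must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Name canonicalization
# ---------------------------------------------------------------------------

_MARKUP_RE = re.compile(r"[*_]")
_RANK_TOKENS = {"var.", "subsp.", "ssp.", "f.", "forma", "cv."}
_EPITHET_RE = re.compile(r"^[a-z][a-z\-]*$")


def canonicalize_name(raw: str) -> str:
    """Reduce a decorated scientific name to its authority-free binomial.

    Strips italics markup and author citations, collapses whitespace,
    capitalizes the genus and lower-cases the epithet; infraspecific
    ranks (``var.``, ``subsp.``) and their epithets are preserved.  The
    result is idempotent, so canonical names can be re-canonicalized
    freely at module boundaries.

    >>> canonicalize_name("*Justicia procumbens* L.")
    'Justicia procumbens'
    >>> canonicalize_name("Raphanus raphanistrum subsp. sativus (L.) Domin.")
    'Raphanus raphanistrum subsp. sativus'
    """
    text = unicodedata.normalize("NFC", _MARKUP_RE.sub(" ", raw)).strip()
    if not text:
        raise ValueError("empty species name")
    tokens = text.split()
    genus = tokens[0].capitalize()
    out = [genus]
    i = 1
    # The species epithet is the first all-lowercase token after the genus;
    # anything else there (an authority like "(L.)") means a bare genus name.
    if i < len(tokens) and _EPITHET_RE.match(tokens[i].lower()) and not _is_authority(tokens[i]):
        out.append(tokens[i].lower())
        i += 1
        # Scan the remainder for infraspecific rank markers; authority
        # strings ("(L.) Domin.", "Hayata") are dropped.
        while i < len(tokens):
            tok = tokens[i].lower()
            if tok in _RANK_TOKENS and i + 1 < len(tokens):
                rank = "subsp." if tok == "ssp." else tok
                out.extend([rank, tokens[i + 1].lower().rstrip(".")])
                i += 2
            else:
                i += 1
    return " ".join(out)


def _is_authority(token: str) -> bool:
    return token.startswith("(") or token.rstrip(".").istitle()


def _split_multi(cell: str) -> tuple[str, ...]:
    if not cell:
        return ()
    return tuple(v.strip() for v in str(cell).split(MULTI_SEP) if v.strip())


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    """A located data problem; ``kind`` is a stable machine-readable tag."""

    kind: str
    message: str
    table: str | None = None
    row: int | None = None

    def __str__(self) -> str:
        loc = f" [{self.table} row {self.row}]" if self.table else ""
        return f"{self.kind}: {self.message}{loc}"


class SurveyValidationError(ValueError):
    """Raised when a dataset fails validation on load."""

    def __init__(self, issues: Sequence[ValidationIssue]):
        self.issues = list(issues)
        lines = "\n".join(f"  - {i}" for i in self.issues)
        super().__init__(f"survey validation failed with {len(self.issues)} issue(s):\n{lines}")


def validate(ds: SurveyDataset, ailment_map: AilmentMap | None = None) -> list[ValidationIssue]:
    """Check referential and vocabulary integrity; returns issues, raises nothing."""
    issues: list[ValidationIssue] = []
    seen_inf: set[str] = set()
    for i, inf in enumerate(ds.informants):
        if inf.informant_id in seen_inf:
            issues.append(ValidationIssue("duplicate-id", f"duplicate informant_id {inf.informant_id!r}", "informants", i))
        seen_inf.add(inf.informant_id)
        if inf.gender not in GENDER_VOCAB:
            issues.append(ValidationIssue("vocabulary", f"gender {inf.gender!r} not in {sorted(GENDER_VOCAB)}", "informants", i))
    seen_sp: set[str] = set()
    for i, sp in enumerate(ds.species):
        if sp.species_id in seen_sp:
            issues.append(ValidationIssue("duplicate-id", f"duplicate species_id {sp.species_id!r}", "species", i))
        seen_sp.add(sp.species_id)
        if not sp.canonical_name.strip():
            issues.append(ValidationIssue("empty-name", f"species {sp.species_id!r} has empty canonical_name", "species", i))
        if sp.red_list_status is not None and sp.red_list_status not in RED_LIST_VOCAB:
            issues.append(ValidationIssue("vocabulary", f"red_list_status {sp.red_list_status!r} not in {sorted(RED_LIST_VOCAB)}", "species", i))
    informants = ds.informant_by_id()
    for i, rep in enumerate(ds.reports):
        if rep.informant_id not in informants:
            issues.append(ValidationIssue("dangling-key", f"report cites unknown informant_id {rep.informant_id!r}", "use_reports", i))
        elif not informants[rep.informant_id].included:
            issues.append(ValidationIssue("excluded-informant", f"report from excluded informant {rep.informant_id!r}", "use_reports", i))
        if rep.species_id not in seen_sp:
            issues.append(ValidationIssue("dangling-key", f"report cites unknown species_id {rep.species_id!r}", "use_reports", i))
        for value, vocab, label in (
            (rep.parts(), PART_VOCAB, "part"),
            (rep.preparations(), PREPARATION_VOCAB, "preparation"),
            (rep.routes(), ROUTE_VOCAB, "route"),
        ):
            for v in value:
                if v not in vocab:
                    issues.append(ValidationIssue("vocabulary", f"{label} token {v!r} outside vocabulary", "use_reports", i))
        if ailment_map is not None and rep.ailment_text not in ailment_map:
            issues.append(ValidationIssue("unmapped-ailment", f"ailment {rep.ailment_text!r} not in ailment map", "use_reports", i))
    return issues


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

INFORMANT_COLUMNS = ["informant_id", "gender", "age_band", "township", "education", "knowledge_sources", "included"]
SPECIES_COLUMNS = ["species_id", "canonical_name", "family", "local_names", "voucher_id", "source", "red_list_status"]
REPORT_COLUMNS = ["informant_id", "species_id", "ailment_text", "part", "preparation", "route"]


def _read_csv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing survey file: {path}")
    df = pd.read_csv(path, dtype=str, encoding="utf-8", keep_default_na=False)
    missing = set(columns) - set(df.columns)
    if missing:
        raise SurveyValidationError(
            [ValidationIssue("schema", f"{path.name} missing columns {sorted(missing)}", path.stem)]
        )
    return df


def load_survey(
    directory: str | Path,
    config: AnalysisConfig | None = None,
    ailment_map: AilmentMap | None = None,
) -> SurveyDataset:
    """Load ``informants.csv``, ``species.csv`` and ``use_reports.csv``.

    Species names are canonicalized on the way in.  Any validation issue
    (dangling foreign key, vocabulary violation, unmapped ailment)
    raises :class:`SurveyValidationError` listing every offending row.
    """
    directory = Path(directory)
    inf_df = _read_csv(directory / "informants.csv", INFORMANT_COLUMNS)
    sp_df = _read_csv(directory / "species.csv", SPECIES_COLUMNS)
    rep_df = _read_csv(directory / "use_reports.csv", REPORT_COLUMNS)

    informants = tuple(
        Informant(
            informant_id=r.informant_id,
            gender=r.gender,
            age_band=r.age_band,
            township=r.township,
            education=r.education,
            knowledge_sources=_split_multi(r.knowledge_sources),
            included=str(r.included).strip().lower() in {"true", "1", "yes"},
        )
        for r in inf_df.itertuples()
    )
    species = tuple(
        SpeciesRecord(
            species_id=r.species_id,
            canonical_name=canonicalize_name(r.canonical_name),
            family=r.family,
            local_names=_split_multi(r.local_names),
            voucher_id=r.voucher_id or None,
            source=r.source or "wild",
            red_list_status=r.red_list_status or None,
        )
        for r in sp_df.itertuples()
    )
    reports = tuple(
        UseReport(
            informant_id=r.informant_id,
            species_id=r.species_id,
            ailment_text=r.ailment_text,
            part=r.part,
            preparation=r.preparation,
            route=r.route,
        )
        for r in rep_df.itertuples()
    )
    ds = SurveyDataset(informants=informants, species=species, reports=reports)
    issues = validate(ds, ailment_map=ailment_map)
    if issues:
        raise SurveyValidationError(issues)
    return ds


def write_survey(ds: SurveyDataset, directory: str | Path) -> None:
    """Write the three standard CSV tables (UTF-8, ``;`` inner separator)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "informant_id": i.informant_id,
                "gender": i.gender,
                "age_band": i.age_band,
                "township": i.township,
                "education": i.education,
                "knowledge_sources": MULTI_SEP.join(i.knowledge_sources),
                "included": str(i.included).lower(),
            }
            for i in ds.informants
        ],
        columns=INFORMANT_COLUMNS,
    ).to_csv(directory / "informants.csv", index=False, encoding="utf-8")
    pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "canonical_name": s.canonical_name,
                "family": s.family,
                "local_names": MULTI_SEP.join(s.local_names),
                "voucher_id": s.voucher_id or "",
                "source": s.source,
                "red_list_status": s.red_list_status or "",
            }
            for s in ds.species
        ],
        columns=SPECIES_COLUMNS,
    ).to_csv(directory / "species.csv", index=False, encoding="utf-8")
    pd.DataFrame(
        [
            {
                "informant_id": r.informant_id,
                "species_id": r.species_id,
                "ailment_text": r.ailment_text,
                "part": r.part,
                "preparation": r.preparation,
                "route": r.route,
            }
            for r in ds.reports
        ],
        columns=REPORT_COLUMNS,
    ).to_csv(directory / "use_reports.csv", index=False, encoding="utf-8")


def load_ailment_map(path: str | Path) -> AilmentMap:
    """Read ``ailment_map.csv`` (columns ``ailment_text,icpc_category``)."""
    df = _read_csv(Path(path), ["ailment_text", "icpc_category"])
    return AilmentMap(dict(zip(df["ailment_text"], df["icpc_category"])))


def write_ailment_map(amap: AilmentMap, path: str | Path) -> None:
    pd.DataFrame(sorted(amap.items()), columns=["ailment_text", "icpc_category"]).to_csv(
        path, index=False, encoding="utf-8"
    )
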