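"""End-to-end pipeline: validate → indices → consensus → crossref → network.

One call, :func:`run_all`, executes every analysis stage on a survey
directory and writes the standard outputs (indices.csv, fic.csv,
consensus_report.json, crossref.csv, novelty.csv, network.graphml,
summary.md) plus a run manifest with input digests, so a run can be
audited and reproduced.  There is no hidden state: running the stages
individually on the same inputs yields the same outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc_network import build_baskets, export_network, mine_rules, to_network
from .consensus_ranking import interpret_consensus
from .indices import compute_fic, compute_species_indices, demographic_summary, tabulate_attribute
from .literature_crossref import annotation_counts, detect_novelty, load_reference_flora, overlap, shared_use
from .survey_model import AnalysisConfig, load_ailment_map, load_survey

__all__ = ["run_all", "PipelineError"]

logger = logging.getLogger("ethnoconsensus")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    input_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    refs_dir: str | Path | None = None,
) -> Path:
    """Run every stage on ``input_dir`` and write results to ``out_dir``.

    ``input_dir`` must hold the standard CSV schema (informants.csv,
    species.csv, use_reports.csv, ailment_map.csv); ``refs_dir`` holds
    reference-flora CSVs for the cross-reference stage (defaults to
    ``input_dir/references`` when present, and the stage is skipped when
    no references exist).  Any stage error aborts the run with the stage
    name; already-written outputs are listed as partial in the manifest.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or AnalysisConfig()
    t0 = time.time()
    outputs: list[str] = []
    timings: dict[str, float] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.start = time.time()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.time() - self_inner.start, 4)
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.3fs", name, timings[name])
                return False

        return _Ctx()

    with _stage("load"):
        ailment_map = load_ailment_map(input_dir / "ailment_map.csv")
        ds = load_survey(input_dir, config, ailment_map=ailment_map)

    with _stage("indices"):
        index_rows = compute_species_indices(ds, config)
        pd.DataFrame(
            [
                {
                    "species_id": r.species_id,
                    "canonical_name": r.canonical_name,
                    "family": r.family,
                    "sum_ui": r.sum_ui,
                    "uv": r.uv,
                    "fc": r.fc,
                    "rfc": r.rfc,
                }
                for r in index_rows
            ]
        ).to_csv(out_dir / "indices.csv", index=False, encoding="utf-8")
        outputs.append("indices.csv")
        fic_rows = compute_fic(ds, ailment_map, config)
        pd.DataFrame(
            [
                {"icpc_category": r.icpc_category, "nur": r.nur, "nt": r.nt, "fic": r.fic}
                for r in fic_rows
            ]
        ).to_csv(out_dir / "fic.csv", index=False, encoding="utf-8")
        outputs.append("fic.csv")
        for attr in ("part", "preparation", "route", "family"):
            table = tabulate_attribute(ds, attr, config)
            pd.DataFrame(table.rows, columns=[attr, "count", "pct"]).to_csv(
                out_dir / f"freq_{attr}.csv", index=False, encoding="utf-8"
            )
            outputs.append(f"freq_{attr}.csv")

    with _stage("consensus"):
        report = interpret_consensus(
            index_rows, fic_rows, ds, ailment_map,
            fic_threshold=config.fic_threshold, nur_threshold=config.nur_threshold,
        )
        report.to_json(out_dir / "consensus_report.json")
        (out_dir / "consensus_report.md").write_text(report.to_markdown(), encoding="utf-8")
        outputs += ["consensus_report.json", "consensus_report.md"]

    # An explicitly requested references directory must exist; the implicit
    # default (input_dir/references) makes the crossref stage optional.
    if refs_dir is not None:
        refs_dir = Path(refs_dir)
        if not refs_dir.exists():
            raise PipelineError("crossref", FileNotFoundError(f"references directory not found: {refs_dir}"))
    else:
        refs_dir = input_dir / "references"
    refs = []
    if refs_dir.exists():
        with _stage("crossref"):
            refs = [load_reference_flora(p) for p in sorted(refs_dir.glob("*.csv"))]
            survey_names = [s.canonical_name for s in ds.species]
            crossref_rows = []
            use_map = dict(ailment_map.items())
            for ref in refs:
                result = overlap(survey_names, ref, config)
                crossref_rows.append(
                    {
                        "reference": result.reference,
                        "n_survey": result.n_survey,
                        "n_matched": result.n_matched,
                        "pct": result.pct,
                    }
                )
            with_uses = [r for r in refs if r.uses is not None]
            if with_uses:
                n_shared, pct_shared = shared_use(ds, with_uses, use_map, config)
                crossref_rows.append(
                    {"reference": "shared-use (all refs)", "n_survey": len(set(survey_names)),
                     "n_matched": n_shared, "pct": pct_shared}
                )
            pd.DataFrame(crossref_rows).to_csv(out_dir / "crossref.csv", index=False, encoding="utf-8")
            outputs.append("crossref.csv")
            novelty = detect_novelty(ds, refs, use_map)
            rows = [{"kind": "novel-species", "species": s, "use": ""} for s in sorted(novelty.novel_species)]
            rows += [{"kind": "novel-use", "species": s, "use": u} for s, u in novelty.novel_uses]
            pd.DataFrame(rows, columns=["kind", "species", "use"]).to_csv(
                out_dir / "novelty.csv", index=False, encoding="utf-8"
            )
            outputs.append("novelty.csv")
            red_list = annotation_counts(ds, "red_list_status")
            pd.DataFrame(red_list.rows, columns=["status", "count", "pct"]).to_csv(
                out_dir / "red_list.csv", index=False, encoding="utf-8"
            )
            outputs.append("red_list.csv")

    with _stage("network"):
        baskets = build_baskets(ds)
        rules = mine_rules(baskets, config.min_support, config.min_confidence)
        net = to_network(rules, index_rows)
        export_network(net, out_dir / "network.graphml", "graphml")
        export_network(net, out_dir / "network_edges.csv", "edge-csv")
        outputs += ["network.graphml", "network_edges.csv"]

    with _stage("summary"):
        demo = demographic_summary(ds, config)
        lines = [
            "# Survey analysis summary",
            "",
            f"Informants (N): {ds.n_informants}; species: {len(ds.species)}; use reports: {len(ds.reports)}",
            "",
            "## Species indices (top 10 by UV)",
            "",
            "| Species | Family | ΣUi | UV | FC | RFC |",
            "|---|---|---|---|---|---|",
        ]
        for r in index_rows[:10]:
            lines.append(f"| {r.canonical_name} | {r.family} | {r.sum_ui} | {r.uv:.2f} | {r.fc} | {r.rfc:.2f} |")
        lines += ["", "## Consensus by ICPC category", "", "| Category | Nur | Nt | Fic |", "|---|---|---|---|"]
        for r in fic_rows:
            lines.append(f"| {r.icpc_category} | {r.nur} | {r.nt} | {r.fic:.2f} |")
        if refs:
            lines += ["", "## Literature cross-reference", ""]
            for row in crossref_rows:
                lines.append(f"- {row['reference']}: {row['n_matched']}/{row['n_survey']} ({row['pct']:.2f}%)")
        ratio = demo.female_male_ratio
        if ratio is not None:
            lines += ["", f"Female/male mean distinct species cited: {ratio:.2f}"]
        lines += ["", f"Co-use rules: {len(rules)}; network edges: {net.number_of_edges()}"]
        (out_dir / "summary.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
        outputs.append("summary.md")

    manifest = {
        "tool": "ethnoconsensus",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": {p.name: _digest(p) for p in sorted(input_dir.glob("*.csv"))},
        "references": {p.name: _digest(p) for p in sorted(refs_dir.glob("*.csv"))} if refs_dir.exists() else {},
        "outputs": outputs,
        "timings_s": timings,
        "elapsed_s": round(time.time() - t0, 4),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return out_dir
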