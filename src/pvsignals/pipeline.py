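"""End-to-end orchestration: ingest → dedup → tables → statistics → profiling.

:func:`run_pipeline` executes the whole analysis for one source directory and
writes a reproducible output bundle: the signal table (PT level), SOC tables,
ranked top-N lists, demographic/annual/SOC/onset summaries, optional tumor vs
non-tumor stratified tables, and a run manifest echoing the configuration and
per-stage row counts.  Identical configuration and inputs yield byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from . import __version__
from .contingency import build_tables, tables_to_frame
from .profiling import (IndicationLexicon, annual_distribution, demographic_summary,
                        soc_distribution, stratified_signals, time_to_onset)
from .report_io import (DedupPolicy, IngestStats, deduplicate, filter_suspect,
                        read_faers_quarter, read_jader)
from .signal_stats import (BcpnnPriors, SignalCriteria, rank_signals, score_tables,
                           signal_table)
from .vocab import DrugLexicon, MeddraDictionary

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """The pipeline configuration references missing inputs or bad options."""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    input_dir: str
    source: str = "faers"                 # faers | jader
    focal_drug: str = "obinutuzumab"
    lexicon_path: str | None = None       # None -> bundled synthetic lexicon
    dictionary_path: str | None = None    # None -> bundled synthetic dictionary
    suspect_roles: tuple[str, ...] = ("primary_suspect",)
    margins: str = "pairs"
    continuity_correction: bool = False
    yates: bool = True
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    priors: BcpnnPriors = field(default_factory=BcpnnPriors)
    rank_by: str = "ror"
    top_n: int = 30
    stratify_indications: bool = False
    out_dir: str = "pvsignals_out"
    seed: int = 0

    def validate(self) -> None:
        if self.source not in ("faers", "jader"):
            raise PipelineConfigError(f"unknown source {self.source!r}")
        if not Path(self.input_dir).is_dir():
            raise PipelineConfigError(f"input directory not found: {self.input_dir}")
        for label, path in (("lexicon", self.lexicon_path),
                            ("dictionary", self.dictionary_path)):
            if path is not None and not Path(path).exists():
                raise PipelineConfigError(f"{label} file not found: {path}")


@dataclass
class PipelineResult:
    manifest: dict
    out_dir: Path


def _json_default(obj):
    import numpy as np

    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {obj!r}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config`` and write the bundle.

    Raises :class:`PipelineConfigError` before any compute when referenced
    paths are missing; stage failures propagate with the stage named.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lexicon = (DrugLexicon.from_file(config.lexicon_path)
               if config.lexicon_path else DrugLexicon.default())
    dictionary = (MeddraDictionary.from_file(config.dictionary_path)
                  if config.dictionary_path else MeddraDictionary.default())
    canonical_drug, _ = lexicon.normalize(config.focal_drug)

    counters: dict[str, int] = {}
    stage = "ingest"
    try:
        stats = IngestStats()
        reader = read_faers_quarter if config.source == "faers" else read_jader
        raw_reports = reader(config.input_dir, lexicon=lexicon, stats=stats)
        counters["reports_read"] = len(raw_reports)
        counters["rows_skipped"] = stats.orphan_rows + stats.malformed_rows

        stage = "deduplicate"
        reports = deduplicate(raw_reports, DedupPolicy())
        counters["reports_deduplicated"] = len(reports)

        stage = "suspect_filter"
        focal = filter_suspect(reports, canonical_drug, roles=config.suspect_roles)
        counters["focal_reports"] = len(focal)

        stage = "contingency"
        pt_tables = build_tables(reports, canonical_drug,
                                 suspect_roles=config.suspect_roles,
                                 margins=config.margins)
        soc_tables = build_tables(reports, canonical_drug, level="SOC",
                                  dictionary=dictionary,
                                  suspect_roles=config.suspect_roles,
                                  margins=config.margins)
        counters["pt_pairs"] = len(pt_tables)
        counters["soc_pairs"] = len(soc_tables)

        stage = "statistics"
        records = score_tables(pt_tables, priors=config.priors,
                               criteria=config.criteria,
                               continuity_correction=config.continuity_correction,
                               yates=config.yates)
        soc_records = score_tables(soc_tables, priors=config.priors,
                                   criteria=config.criteria,
                                   continuity_correction=config.continuity_correction,
                                   yates=config.yates)
        counters["flagged_pt_pairs"] = sum(r.flagged for r in records)

        stage = "ranking"
        indications = sorted({ind for r in focal for ind in r.indications})
        ranked = rank_signals(records, by=config.rank_by, top_n=config.top_n,
                              exclude_indications=indications)
        counters["ranked_signals"] = len(ranked)

        stage = "profiling"
        demo = demographic_summary(reports)
        annual = annual_distribution(reports)
        socs = soc_distribution(focal, dictionary)
        onset = time_to_onset(focal)

        stage = "write"
        signal_table(records).to_csv(out_dir / "signals_pt.csv", index=False)
        signal_table(soc_records).to_csv(out_dir / "signals_soc.csv", index=False)
        signal_table(ranked).to_csv(out_dir / "signals_ranked.csv", index=False)
        tables_to_frame(pt_tables).to_csv(out_dir / "contingency_pt.csv", index=False)
        demo.table.to_csv(out_dir / "demographics.csv", index=False)
        (out_dir / "annual_distribution.json").write_text(
            json.dumps(annual, indent=2, sort_keys=True, default=str), encoding="utf-8")
        socs.to_csv(out_dir / "soc_distribution.csv", index=False)
        (out_dir / "time_to_onset.json").write_text(
            json.dumps(asdict(onset), indent=2, sort_keys=True), encoding="utf-8")

        if config.stratify_indications:
            stage = "stratify"
            lexicon_ind = IndicationLexicon()
            for stratum in ("tumor", "non_tumor"):
                result = stratified_signals(reports, canonical_drug, stratum,
                                            lexicon=lexicon_ind,
                                            suspect_roles=config.suspect_roles,
                                            priors=config.priors,
                                            criteria=config.criteria)
                signal_table(result.top_by_count).to_csv(
                    out_dir / f"strat_{stratum}_by_count.csv", index=False)
                signal_table(result.top_by_ror).to_csv(
                    out_dir / f"strat_{stratum}_by_ror.csv", index=False)
                counters[f"{stratum}_scored_pairs"] = len(result.records)
    except PipelineConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (counters so far: {counters})") from exc

    manifest = {
        "pvsignals_version": __version__,
        "config": {**asdict(config),
                   "criteria": asdict(config.criteria),
                   "priors": asdict(config.priors)},
        "counters": counters,
        "male_female_ratio": demo.male_female_ratio,
        "onset_median_days": onset.median_days,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default),
        encoding="utf-8")
    return PipelineResult(manifest=manifest, out_dir=out_dir)
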