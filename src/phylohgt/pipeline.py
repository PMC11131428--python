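"""End-to-end orchestration: screen -> root -> classify -> enrich -> recency.

Operates on a dataset directory using the per-stage file formats (hits TSV,
Newick gene trees, taxonomy TSV, gene/term annotation TSV, presence/absence
TSV) and writes per-stage tables plus a run report into an output directory.
Identical inputs and config produce bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import classify as _classify
from . import enrichment as _enrichment
from . import recency as _recency
from .screen import ScreenConfig, ScreenResult, screen as screen_hits, write_screen_report
from .rooting import mad_root
from .taxa import TaxonMap, load_taxon_map
from .trees import GeneTree

log = logging.getLogger("phylohgt")


@dataclass
class PipelineConfig:
    data_dir: str = "."
    out_dir: str = "results"
    min_pident: float = 35.0
    min_cov: float = 0.80
    contam_pident: float = 76.0
    support_threshold: float = 80.0
    majority_fraction: float = 0.5
    min_bacteria_genomes: int = 2
    max_intruders: int = 0
    ancient_plant_fraction: float = 0.9
    min_term_size: int = 5
    max_recent_rank: str = "family"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key: value config file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            min_pident=self.min_pident,
            min_cov=self.min_cov,
            contam_pident=self.contam_pident,
        )

    def classify_config(self) -> _classify.ClassifyConfig:
        return _classify.ClassifyConfig(
            support_threshold=self.support_threshold,
            majority_fraction=self.majority_fraction,
            min_bacteria_genomes=self.min_bacteria_genomes,
            max_intruders=self.max_intruders,
            ancient_plant_fraction=self.ancient_plant_fraction,
        )


def run_screen(cfg: PipelineConfig) -> ScreenResult:
    data = Path(cfg.data_dir)
    ann = data / "organelle_annotations.tsv"
    result = screen_hits(
        data / "hits.tsv",
        ann if ann.exists() else None,
        cfg.screen_config(),
    )
    write_screen_report(result, Path(cfg.out_dir))
    log.info(
        "screen: %d hits kept, %d plant genes, %d contamination flags",
        len(result.kept_hits), len(result.plant_genes), len(result.contamination_flags),
    )
    return result


def run_root(cfg: PipelineConfig) -> Path:
    """MAD-root every unrooted tree in data_dir/trees into out_dir/rooted."""
    out = Path(cfg.out_dir) / "rooted"
    out.mkdir(parents=True, exist_ok=True)
    n = 0
    for path in sorted(Path(cfg.data_dir).glob("trees/*.nwk")):
        gt = GeneTree.from_file(path)
        rooted = gt if gt.rooted else mad_root(gt).rooted_tree
        rooted.write(out / path.name)
        n += 1
    log.info("root: %d trees rooted", n)
    return out


def run_classify(cfg: PipelineConfig, tree_dir: Optional[Path] = None) -> list[_classify.HGTCall]:
    taxon_map = load_taxon_map(Path(cfg.data_dir) / "taxonomy.tsv")
    tree_dir = tree_dir or Path(cfg.out_dir) / "rooted"
    calls = _classify.classify_directory(tree_dir, taxon_map, cfg.classify_config())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _classify.calls_to_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    _classify.summarize_calls(calls).to_csv(out / "calls_summary.tsv", sep="\t", index=False)
    log.info("classify: %d trees called", len(calls))
    return calls


def run_enrich(cfg: PipelineConfig) -> list[_enrichment.EnrichmentResult]:
    data = Path(cfg.data_dir)
    universe = _enrichment.load_universe(data / "go_annotations.tsv")
    bg = data / "background.txt"
    if bg.exists():
        universe = _enrichment.AnnotationUniverse(
            background_genes={
                l.strip() for l in bg.read_text().splitlines() if l.strip()
            },
            term_to_genes=universe.term_to_genes,
        )
    study = {
        l.strip()
        for l in (data / "study_set.txt").read_text().splitlines()
        if l.strip()
    }
    results = _enrichment.enrich(study, universe, cfg.min_term_size)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _enrichment.results_to_frame(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    log.info("enrich: %d terms tested against N=%d background", len(results), universe.size)
    return results


def run_recency(cfg: PipelineConfig) -> pd.DataFrame:
    data = Path(cfg.data_dir)
    taxonomy = load_taxon_map(data / "presence_taxonomy.tsv")
    matrix = _recency.read_presence_matrix(data / "presence.tsv", taxonomy)
    scores = _recency.score_all(matrix, cfg.max_recent_rank)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out / "recency.tsv", sep="\t", index=False)
    log.info("recency: %d genes scored", len(scores))
    return scores


def run_all(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    screen_result = run_screen(cfg)
    tree_dir = run_root(cfg)
    calls = run_classify(cfg, tree_dir)
    enrich_results = run_enrich(cfg)
    recency_scores = run_recency(cfg)
    summary = {
        "screen_kept_hits": len(screen_result.kept_hits),
        "screen_plant_genes": len(screen_result.plant_genes),
        "screen_contamination_flags": len(screen_result.contamination_flags),
        "n_trees": len(calls),
        "pct_acquired_by_plants": _classify.pct_acquired_by_plants(calls),
        "n_enriched_terms_q05": sum(1 for r in enrich_results if r.q_value < 0.05),
        "n_recent_genes": int(recency_scores["recent_flag"].sum()) if len(recency_scores) else 0,
    }
    for cat in _classify.Category:
        summary[f"n_{cat.value.lower()}"] = sum(1 for c in calls if c.category is cat)
    write_report(summary, cfg, out / "report.tsv", out / "report.txt")
    return summary


def write_report(summary: dict, cfg: PipelineConfig, tsv_path: Path, txt_path: Path) -> None:
    rows = [("config:" + k, v) for k, v in sorted(vars(cfg).items())]
    rows += sorted(summary.items())
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(tsv_path, sep="\t", index=False)
    lines = ["phylohgt run report", "===================", ""]
    lines += [f"{k}: {v}" for k, v in sorted(summary.items())]
    lines += ["", "thresholds:"]
    lines += [f"  {k} = {v}" for k, v in sorted(vars(cfg).items())]
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
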