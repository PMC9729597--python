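"""End-to-end workflow: simulate/load -> prioritize -> segregate -> enrich -> SKAT.

Two independent analytical arms share the prioritized RPD variant set:
within-family segregation (sb-RPD / ss-RPD tiers plus gene-set
overrepresentation of the segregating genes) and a cross-pedigree
kinship-adjusted case/control SKAT. Stage outputs are flat TSVs carrying
the config hash and seed in a comment header; a JSON manifest records
per-stage row counts for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import GeneSet
from .enrichment import (
    DEFAULT_UNIVERSE_SIZE,
    specificity_scan,
)
from .io import AnnotationKeys, read_annotated_vcf, read_gene_list, read_pedigree
from .prioritize import MAF_BROAD, MAF_STRINGENT, filter_rpd
from .segregation import (
    find_shared_broad,
    find_shared_stringent,
    gene_summary,
    segregation_table,
    select_multisample_families,
)
from .simulate import SimulatedData, SimulationConfig, simulate
from .skat import run_association

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_full_pipeline"]


@dataclass
class RunConfig:
    """Everything a full run needs; defaults are the analysis defaults."""

    vcf: str | None = None
    ped: str | None = None
    gene_sets: dict[str, str] = field(default_factory=dict)  # name -> path
    simulate: bool = True  # no input files -> run on a synthetic cohort
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    maf_broad: float = MAF_BROAD
    maf_stringent: float = MAF_STRINGENT
    min_shared: int = 3
    consensus_rule: str = "strict"
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    skat_B: int = 10_000
    seed: int = 17
    outdir: str = "pedseg_out"

    def content_hash(self) -> str:
        payload = _jsonable(self)
        payload.pop("outdir", None)  # output location does not change results
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def validate_config(cfg: RunConfig) -> list[str]:
    """Static checks; empty list means runnable. Entries name the key."""
    problems = []
    if not cfg.simulate:
        for key in ("vcf", "ped"):
            path = getattr(cfg, key)
            if path is None:
                problems.append(f"{key}: required when simulate is off")
            elif not Path(path).exists():
                problems.append(f"{key}: file not found: {path}")
    for name, path in cfg.gene_sets.items():
        if not Path(path).exists():
            problems.append(f"gene_sets[{name}]: file not found: {path}")
    if not 0 < cfg.maf_broad <= 0.01:
        problems.append(
            f"maf_broad: {cfg.maf_broad} outside the rare-variant regime (0, 0.01]"
        )
    if cfg.maf_stringent > cfg.maf_broad:
        problems.append("maf_stringent: must not exceed maf_broad")
    if cfg.min_shared < 1:
        problems.append("min_shared: must be >= 1")
    if cfg.consensus_rule not in ("strict", "lenient"):
        problems.append(f"consensus_rule: unknown rule {cfg.consensus_rule!r}")
    return problems


def _write_tsv(frame: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pedseg {__version__} config={cfg_hash} seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns a dict with the in-memory stage results (rpd_calls, broad,
    stringent, enrichment, skat, manifest, paths).
    """
    problems = validate_config(cfg)
    hard = [p for p in problems if "outside" not in p]
    if hard:
        raise ValueError("config invalid: " + "; ".join(hard))
    for p in problems:
        logger.warning("config: %s", p)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.content_hash()
    manifest = RunManifest(
        version=__version__, config_hash=cfg_hash, seed=cfg.seed, started=time.time()
    )
    stage = "load"
    try:
        if cfg.simulate:
            sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
            data: SimulatedData = simulate(sim_cfg)
            cohort, variants = data.cohort, data.variants
            common = data.common_genotypes
            universe = sim_cfg.n_genes
            gene_sets = [
                GeneSet(
                    name="CNS",
                    genes=frozenset(sim_cfg.cns_genes),
                    universe_size=universe,
                )
            ]
        else:
            cohort = read_pedigree(cfg.ped)
            variants = read_annotated_vcf(cfg.vcf, cohort, AnnotationKeys())
            common = None
            universe = cfg.universe_size
            gene_sets = [
                read_gene_list(path, name, universe)
                for name, path in cfg.gene_sets.items()
            ]
        manifest.stage_counts["samples"] = len(cohort)
        manifest.stage_counts["variants_loaded"] = len(variants)
        logger.info("loaded %d variants, %d samples", len(variants), len(cohort))

        stage = "prioritize"
        rpd = filter_rpd(
            variants,
            maf_broad=cfg.maf_broad,
            maf_stringent=cfg.maf_stringent,
            consensus_rule=cfg.consensus_rule,
        )
        manifest.stage_counts["rpd_variants"] = len(rpd)
        logger.info("RPD retained: %d", len(rpd))
        rpd_frame = pd.DataFrame(
            {
                "vid": [c.variant.vid for c in rpd],
                "gene": [c.variant.gene for c in rpd],
                "consequence": [c.variant.consequence.value for c in rpd],
                "is_ptv": [c.is_ptv for c in rpd],
                "deleterious_votes": [c.deleterious_votes for c in rpd],
                "rarity_stringent": [c.passes_rarity_stringent for c in rpd],
            }
        )
        _write_tsv(rpd_frame, outdir / "rpd_variants.tsv", cfg_hash, cfg.seed)

        stage = "segregate"
        broad = find_shared_broad(rpd, cohort, min_shared=cfg.min_shared)
        stringent = find_shared_stringent(broad, maf_stringent=cfg.maf_stringent)
        manifest.stage_counts["sb_rpd"] = len(broad)
        manifest.stage_counts["ss_rpd"] = len(stringent)
        logger.info(
            "multi-sample families: %d, sb-RPD: %d, ss-RPD: %d",
            len(select_multisample_families(cohort, cfg.min_shared)),
            len(broad),
            len(stringent),
        )
        _write_tsv(
            segregation_table(broad + stringent),
            outdir / "segregation.tsv",
            cfg_hash,
            cfg.seed,
        )
        _write_tsv(gene_summary(broad), outdir / "gene_summary.tsv", cfg_hash, cfg.seed)

        stage = "enrich"
        seg_genes = sorted({r.variant.gene for r in broad})
        manifest.stage_counts["sb_genes"] = len(seg_genes)
        enr_rows = []
        enrichment = []
        if seg_genes and gene_sets:
            enrichment = specificity_scan(seg_genes, gene_sets, universe_size=universe)
            for e in enrichment:
                enr_rows.append(
                    {
                        "gene_set": e.gene_set_name,
                        "a": e.a,
                        "b": e.b,
                        "c": e.c,
                        "d": e.d,
                        "odds_ratio": e.odds_ratio,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                        "p": e.p_two_sided,
                        "p_corrected": e.p_corrected,
                    }
                )
        _write_tsv(pd.DataFrame(enr_rows), outdir / "enrichment.tsv", cfg_hash, cfg.seed)

        stage = "skat"
        skat_results = []
        if common is not None and gene_sets:
            units = {gs.name: sorted(gs.genes) for gs in gene_sets}
            skat_results = run_association(
                cohort,
                rpd,
                units,
                common_genotypes=common,
                B=cfg.skat_B,
                seed=cfg.seed,
            )
        skat_frame = pd.DataFrame(
            {
                "unit": [r.unit for r in skat_results],
                "variant_count": [r.variant_count for r in skat_results],
                "case_variant_count": [r.case_variant_count for r in skat_results],
                "uc_variant_count": [r.control_variant_count for r in skat_results],
                "p": [r.p_reported for r in skat_results],
                "p_bonferroni": [r.p_bonferroni for r in skat_results],
            }
        )
        _write_tsv(skat_frame, outdir / "skat.tsv", cfg_hash, cfg.seed)
        manifest.stage_counts["skat_units"] = len(skat_results)
    except Exception:
        manifest.finished = time.time()
        manifest.write(outdir / "manifest.json")
        logger.error("pipeline failed at stage %r", stage)
        raise

    manifest.finished = time.time()
    manifest.write(outdir / "manifest.json")
    return {
        "cohort": cohort,
        "rpd_calls": rpd,
        "broad": broad,
        "stringent": stringent,
        "enrichment": enrichment,
        "skat": skat_results,
        "manifest": manifest,
        "outdir": outdir,
    }
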