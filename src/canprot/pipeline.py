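"""End-to-end pipeline orchestration.

Stages run in a fixed order — simulate (optional) -> quantify -> map ->
gsea -> blot -> report — each writing its outputs before the next starts.
A manifest (JSON) lists every output file with a SHA-256 checksum, so a
rerun with the same configuration and seed is verifiably byte-identical.
With ``resume=True`` a stage whose outputs already exist is skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import blot as blot_mod
from . import gsea as gsea_mod
from . import io as cio
from . import quantify as quant_mod
from . import simulate as sim_mod
from .errors import ConfigError, StageError
from .orthomap import MappingStage, build_rnk

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "map", "gsea", "blot", "report")


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for a full pipeline run.

    Thresholds default to the analysis conventions of the emulated study:
    cohort significance alpha 0.05, 2-fold rule bounds 0.5/2, minimum gene-
    set size 10, set-level significance p < .01 and FDR q < 0.1.
    """

    out_dir: str = "canprot_out"
    peptide_table: str | None = None  # None -> simulate
    map_stage1: str | None = None
    map_stage1_fallback: str | None = None
    map_stage2: str | None = None
    map_stage2_fallback: str | None = None
    map_stage3: str | None = None
    map_stage3_fallback: str | None = None
    gmt: str | None = None
    blot_table: str | None = None
    alpha: float = 0.05
    fc_lower: float = 0.5
    fc_upper: float = 2.0
    min_set_size: int = 10
    gsea_p_thresh: float = 0.01
    gsea_q_thresh: float = 0.1
    n_perm: int = 1000
    weight: float = 1.0
    blot_band: float = 0.05
    seed: int = 0
    bcell_dogs: list[str] = field(default_factory=list)
    sim: sim_mod.SimConfig = field(default_factory=sim_mod.SimConfig)

    def validate(self) -> None:
        for name in ("alpha", "fc_lower", "fc_upper", "gsea_p_thresh",
                     "gsea_q_thresh", "weight"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fc_lower >= self.fc_upper:
            raise ConfigError("fc_lower must be strictly below fc_upper")
        if self.min_set_size < 1 or self.n_perm < 1:
            raise ConfigError("min_set_size and n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        cfg = cls(**raw)
        sim_known = {f.name for f in dataclasses.fields(sim_mod.SimConfig)}
        bad = set(sim_raw) - sim_known
        if bad:
            raise ConfigError(f"unknown sim fields: {sorted(bad)}")
        cfg.sim = sim_mod.SimConfig(**sim_raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_outputs(out: Path) -> dict[str, list[Path]]:
    return {
        "simulate": [out / "peptides.tsv", out / "ground_truth.tsv",
                     out / "map_stage1.tsv", out / "map_stage1_fallback.tsv",
                     out / "map_stage2.tsv", out / "map_stage2_fallback.tsv",
                     out / "map_stage3.tsv", out / "map_stage3_fallback.tsv",
                     out / "gene_sets.gmt", out / "blot.tsv"],
        "quantify": [out / "quant_all_dogs.tsv", out / "quant_per_dog.tsv",
                     out / "per_dog_summary.tsv", out / "venn.tsv"],
        "map": [out / "ranked.rnk"],
        "gsea": [out / "gsea_results.tsv", out / "gsea_significant.tsv",
                 out / "gsea_nonredundant.tsv"],
        "blot": [out / "blot_concordance.tsv"],
        "report": [out / "manifest.json"],
    }


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute all stages; returns the output directory.

    Raises :class:`~canprot.errors.StageError` naming the failing stage;
    outputs of earlier stages are preserved on failure.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expected = _stage_outputs(out)

    def skip(stage: str) -> bool:
        if resume and all(p.exists() for p in expected[stage]):
            logger.info("stage %s: outputs exist, skipped (--resume)", stage)
            return True
        return False

    # ---- simulate -------------------------------------------------------
    if config.peptide_table is None:
        if not skip("simulate"):
            try:
                sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
                table, truth = sim_mod.simulate_cohort(sim_cfg)
                stages_raw, gmt, truth = sim_mod.make_fixture_maps(sim_cfg, truth)
                blot_df = sim_mod.make_fixture_blot(sim_cfg, truth)
                cio.write_peptide_table(table, out / "peptides.tsv")
                truth_rows = [
                    (a, v, a in truth.mappable, truth.gene_of.get(a, ""))
                    for a, v in sorted(truth.true_log2fc.items())
                ]
                with open(out / "ground_truth.tsv", "w") as fh:
                    fh.write("protein_accession\ttrue_log2fc\tmappable\tgene_id\n")
                    for a, v, m, g in truth_rows:
                        fh.write(f"{a}\t{v:g}\t{int(m)}\t{g}\n")
                for s, stage in enumerate(stages_raw, start=1):
                    cio.write_mapping_table(stage["primary"], out / f"map_stage{s}.tsv")
                    cio.write_mapping_table(
                        stage["fallback"], out / f"map_stage{s}_fallback.tsv"
                    )
                cio.write_gmt(gmt, out / "gene_sets.gmt")
                blot_df.to_csv(out / "blot.tsv", sep="\t", index=False)
            except Exception as exc:
                raise StageError("simulate", str(exc)) from exc
        config = dataclasses.replace(
            config,
            peptide_table=str(out / "peptides.tsv"),
            map_stage1=str(out / "map_stage1.tsv"),
            map_stage1_fallback=str(out / "map_stage1_fallback.tsv"),
            map_stage2=str(out / "map_stage2.tsv"),
            map_stage2_fallback=str(out / "map_stage2_fallback.tsv"),
            map_stage3=str(out / "map_stage3.tsv"),
            map_stage3_fallback=str(out / "map_stage3_fallback.tsv"),
            gmt=str(out / "gene_sets.gmt"),
            blot_table=str(out / "blot.tsv"),
        )

    for name in ("peptide_table", "map_stage1", "map_stage2", "map_stage3", "gmt"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise StageError("input", f"required input '{name}' missing: {p}")

    # ---- quantify -------------------------------------------------------
    if not skip("quantify"):
        try:
            peptides = cio.read_peptide_table(config.peptide_table)
            quant = quant_mod.protein_quant_table(peptides)
            cio.write_results_table(quant, out / "quant_all_dogs.tsv")
            per_dog = quant_mod.per_dog_quant(peptides)
            cio.write_results_table(per_dog, out / "quant_per_dog.tsv")
            cio.write_results_table(
                quant_mod.per_dog_summary(per_dog), out / "per_dog_summary.tsv"
            )
            venn = quant_mod.venn_partition(peptides)
            with open(out / "venn.tsv", "w") as fh:
                fh.write("partition\tn\taccessions\n")
                for part in ("both", "d0_only", "d7_only"):
                    accs = sorted(getattr(venn, part))
                    fh.write(f"{part}\t{len(accs)}\t{','.join(accs)}\n")
            logger.info(
                "quantify: %d proteins, venn %s", len(quant), venn.sizes()
            )
        except Exception as exc:
            raise StageError("quantify", str(exc)) from exc

    # ---- map ------------------------------------------------------------
    if not skip("map"):
        try:
            quant = cio.read_results_table(out / "quant_all_dogs.tsv")
            stages = [
                MappingStage.from_files(
                    f"stage{s}", f"stage{s + 1}",
                    getattr(config, f"map_stage{s}"),
                    getattr(config, f"map_stage{s}_fallback"),
                )
                for s in (1, 2, 3)
            ]
            rnk, stats = build_rnk(quant[quant["fc"].notna()], stages)
            cio.write_rnk(rnk, out / "ranked.rnk")
            logger.info("map: %s", stats)
        except Exception as exc:
            raise StageError("map", str(exc)) from exc

    # ---- gsea -----------------------------------------------------------
    if not skip("gsea"):
        try:
            rnk = cio.read_rnk(out / "ranked.rnk")
            gmt = cio.read_gmt(config.gmt)
            results = gsea_mod.prerank(
                rnk, gmt, weight=config.weight, n_perm=config.n_perm,
                min_size=config.min_set_size, seed=config.seed,
            )
            sig = gsea_mod.significant_sets(
                results, config.gsea_p_thresh, config.gsea_q_thresh
            )
            nonred = gsea_mod.collapse_redundant(sig)
            for df, fname in (
                (results, "gsea_results.tsv"),
                (sig, "gsea_significant.tsv"),
                (nonred, "gsea_nonredundant.tsv"),
            ):
                flat = df.copy()
                flat["leading_edge"] = flat["leading_edge"].map(",".join)
                cio.write_results_table(flat, out / fname)
            logger.info(
                "gsea: %d sets used; %s; %d significant, %d nonredundant",
                len(results), gsea_mod.summarize_directions(results),
                len(sig), len(nonred),
            )
        except Exception as exc:
            raise StageError("gsea", str(exc)) from exc

    # ---- blot -----------------------------------------------------------
    if not skip("blot"):
        try:
            if config.blot_table and Path(config.blot_table).exists():
                records = cio.read_results_table(config.blot_table)
                blots = blot_mod.blot_table(records)
                per_dog = cio.read_results_table(out / "quant_per_dog.tsv")
                report = blot_mod.concordance_report(
                    blots, per_dog, band=config.blot_band
                )
                cio.write_results_table(report, out / "blot_concordance.tsv")
            else:
                (out / "blot_concordance.tsv").write_text(
                    "dog_id\ttarget_protein\tner\tfc\tcall\n"
                )
        except Exception as exc:
            raise StageError("blot", str(exc)) from exc

    # ---- report ---------------------------------------------------------
    try:
        files = sorted(
            p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {p.name: _sha256(p) for p in files}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise StageError("report", str(exc)) from exc
    return out
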