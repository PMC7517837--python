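"""Synthetic paired-cohort peptide data with known ground truth.

The generator emulates a small paired-design label-free proteomics study:
``n_dogs`` subjects each contribute exactly one pooled sample before (D0)
and one after (D7) supplementation. Each protein has a log-normal baseline
abundance and 1-10 peptides with their own ionization efficiencies; a small
fraction of proteins carries a true timepoint effect of ±``effect_log2fc``
log2 units (sign random per protein). Detection dropout acts at the peptide
level through a logistic function of ln abundance, so low-abundance
peptides go missing more often — a protein counts as detected in a sample
when at least one of its peptides is present.

The companion fixture builders emit the three-stage ortholog mapping tables
(canine accession -> canine protein id -> human protein id -> human gene
id) with partial coverage, a GMT gene-set collection whose flagged
"enriched" sets are biased toward true-effect genes, and a band-volume
table for the immunoblot stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

_LN2 = math.log(2.0)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 7 dogs, 915 proteins with
    1-10 peptides each, ~5% true effects of ±2 log2 units, and ortholog-map
    coverage of 514/915 proteins. Noise magnitudes (peptide CV 0.2, per-dog
    log2 offset sd 0.25) and the detection-dropout logistic are realistic
    stand-ins and deliberately configuration-exposed.
    """

    n_dogs: int = 7
    n_proteins: int = 915
    peptides_min: int = 1
    peptides_max: int = 10
    frac_true_effect: float = 0.05
    effect_log2fc: float = 2.0
    peptide_cv: float = 0.2
    dog_effect_sd: float = 0.25
    baseline_log_mean: float = 13.8
    baseline_log_sd: float = 1.5
    peptide_eff_log_sd: float = 0.7
    dropout_midpoint: float | None = 9.5
    dropout_slope: float = 1.2
    map_coverage: float = 514 / 915
    n_gene_sets: int = 50
    n_enriched_sets: int = 3
    set_size_min: int = 10
    set_size_max: int = 155
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_dogs": self.n_dogs,
            "n_proteins": self.n_proteins,
            "peptides_min": self.peptides_min,
            "peptides_max": self.peptides_max,
            "n_gene_sets": self.n_gene_sets,
            "set_size_min": self.set_size_min,
            "set_size_max": self.set_size_max,
        }
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.peptides_min > self.peptides_max:
            raise ConfigError("peptides_min must not exceed peptides_max")
        if self.set_size_min > self.set_size_max:
            raise ConfigError("set_size_min must not exceed set_size_max")
        for name in ("frac_true_effect", "map_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("peptide_cv", "dog_effect_sd", "baseline_log_sd",
                     "peptide_eff_log_sd", "dropout_slope"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be nonnegative, got {v!r}")
        if self.n_enriched_sets < 0 or self.n_enriched_sets > self.n_gene_sets:
            raise ConfigError("n_enriched_sets must lie in [0, n_gene_sets]")


@dataclass
class GroundTruth:
    """What the generator injected, keyed by accession / set name."""

    true_log2fc: dict[str, float]
    mappable: set[str]
    gene_of: dict[str, str] = field(default_factory=dict)
    enriched_sets: dict[str, bool] = field(default_factory=dict)

    @property
    def effect_accessions(self) -> set[str]:
        return {a for a, v in self.true_log2fc.items() if v != 0.0}


def _protein_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), 0])


def _dog_rng(config: SimConfig, dog_index: int) -> np.random.Generator:
    # Per-dog sub-stream so a dog's data are invariant to n_dogs.
    return np.random.default_rng([int(config.seed), 1, int(dog_index)])


def _protein_params(config: SimConfig):
    rng = _protein_rng(config)
    n = config.n_proteins
    accessions = [f"CACC{i:05d}" for i in range(n)]
    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    n_peps = rng.integers(config.peptides_min, config.peptides_max + 1, size=n)
    pep_effs = [
        rng.normal(0.0, config.peptide_eff_log_sd, size=k) for k in n_peps
    ]
    n_effect = round(config.frac_true_effect * n)
    effect_idx = rng.choice(n, size=n_effect, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_effect)
    true_log2fc = np.zeros(n)
    true_log2fc[effect_idx] = signs * config.effect_log2fc
    n_map = round(config.map_coverage * n)
    map_idx = set(rng.choice(n, size=n_map, replace=False).tolist())
    return accessions, baselines, n_peps, pep_effs, true_log2fc, map_idx


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the long-format peptide table and its ground truth.

    One sample per dog per timepoint; an undetected peptide measurement is
    an absent row. Identical (config, seed) reproduces the table exactly.
    """
    config.validate()
    accessions, baselines, n_peps, pep_effs, true_log2fc, map_idx = _protein_params(
        config
    )
    sigma = (
        math.sqrt(math.log1p(config.peptide_cv**2)) if config.peptide_cv > 0 else 0.0
    )

    records: list[tuple] = []
    for d in range(config.n_dogs):
        rng = _dog_rng(config, d)
        dog_id = f"dog{d + 1}"
        offset_ln = _LN2 * rng.normal(0.0, config.dog_effect_sd) if config.dog_effect_sd > 0 else 0.0
        for tp in ("D0", "D7"):
            sample_id = f"{dog_id}_{tp}"
            for i, acc in enumerate(accessions):
                shift = _LN2 * true_log2fc[i] if tp == "D7" else 0.0
                for k in range(n_peps[i]):
                    noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                    log_ab = baselines[i] + pep_effs[i][k] + offset_ln + shift + noise
                    if config.dropout_midpoint is not None:
                        z = config.dropout_slope * (log_ab - config.dropout_midpoint)
                        p_det = 1.0 / (1.0 + math.exp(-z))
                        if rng.uniform() >= p_det:
                            continue
                    records.append(
                        (dog_id, tp, sample_id, acc, f"{acc}_pep{k}", math.exp(log_ab))
                    )
    table = pd.DataFrame(
        records,
        columns=[
            "dog_id",
            "timepoint",
            "sample_id",
            "protein_accession",
            "peptide_id",
            "abundance",
        ],
    )
    truth = GroundTruth(
        true_log2fc={a: float(v) for a, v in zip(accessions, true_log2fc)},
        mappable={accessions[i] for i in map_idx},
    )
    return table, truth


def _set_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    # Skewed toward small sets: log-scale with a squared uniform exponent,
    # putting the median near the low tens for the default 10-155 range.
    u = rng.uniform()
    return int(round(lo * (hi / lo) ** (u**2)))


def make_fixture_maps(
    config: SimConfig, truth: GroundTruth
) -> tuple[list[dict], dict[str, tuple[str, list[str]]], GroundTruth]:
    """Build the three mapping stages and a GMT collection for the cohort.

    Returns ``(stages, gmt, truth)`` where ``stages`` is a list of three
    dicts with keys ``source_namespace``, ``target_namespace``, ``primary``
    and ``fallback`` (lists of (source, target, confidence) rows). Exactly
    the ``truth.mappable`` accessions survive the full chain; roughly a
    fifth of surviving hops sit in the fallback table rather than the
    primary one. Flagged enriched sets draw about half their members from
    same-direction true-effect genes.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 2])
    accessions = sorted(truth.true_log2fc)
    namespaces = [
        ("canine_uniprot", "canine_ensembl_protein"),
        ("canine_ensembl_protein", "human_ensembl_protein"),
        ("human_ensembl_protein", "human_entrez_gene"),
    ]
    stages = [
        {
            "source_namespace": s,
            "target_namespace": t,
            "primary": [],
            "fallback": [],
        }
        for s, t in namespaces
    ]
    gene_of: dict[str, str] = {}
    for i, acc in enumerate(accessions):
        hops = [acc, f"ENSCAFP{i:07d}", f"ENSP{i:07d}", f"GENE{i:05d}"]
        mappable = acc in truth.mappable
        # Unmappable accessions break at one stage (round-robin); earlier
        # hops still appear so partial chains exist in the tables.
        break_stage = None if mappable else i % 3
        for s in range(3):
            if break_stage is not None and s == break_stage:
                continue
            row = (hops[s], hops[s + 1], None)
            table = "fallback" if rng.uniform() < 0.2 else "primary"
            stages[s][table].append(row)
        if mappable:
            gene_of[acc] = hops[3]
    truth.gene_of = gene_of

    universe = sorted(gene_of.values())
    effect_up = sorted(
        gene_of[a] for a in truth.effect_accessions & truth.mappable
        if truth.true_log2fc[a] > 0
    )
    effect_down = sorted(
        gene_of[a] for a in truth.effect_accessions & truth.mappable
        if truth.true_log2fc[a] < 0
    )
    gmt: dict[str, tuple[str, list[str]]] = {}
    enriched: dict[str, bool] = {}
    for j in range(config.n_gene_sets):
        name = f"SET_{j:03d}"
        size = min(_set_size(rng, config.set_size_min, config.set_size_max),
                   len(universe))
        is_enriched = j < config.n_enriched_sets
        if is_enriched:
            pool = effect_up if j % 2 == 0 else effect_down
            if not pool:
                pool = effect_down if j % 2 == 0 else effect_up
            # An "enriched" set must actually be enriched: size it so about
            # half its members come from the same-direction effect pool.
            size = min(
                max(config.set_size_min, 2 * len(pool)),
                config.set_size_max,
                len(universe),
            )
            n_eff = min(len(pool), max(1, math.ceil(0.5 * size)))
            eff_members = list(rng.choice(pool, size=n_eff, replace=False)) if pool else []
            rest_pool = [g for g in universe if g not in set(eff_members)]
            n_rest = max(0, size - len(eff_members))
            rest = list(rng.choice(rest_pool, size=min(n_rest, len(rest_pool)),
                                   replace=False))
            members = sorted(eff_members + rest)
        else:
            members = sorted(rng.choice(universe, size=size, replace=False))
        gmt[name] = (f"synthetic gene set {j}", members)
        enriched[name] = bool(is_enriched)
    truth.enriched_sets = enriched
    return stages, gmt, truth


def make_fixture_blot(
    config: SimConfig,
    truth: GroundTruth,
    targets: list[str] | None = None,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Synthetic immunoblot band-volume table for a couple of target proteins.

    Per dog, the normalized expression ratio implied by the band volumes
    equals the protein's true fold change perturbed by log-normal noise
    (sd ``noise_sd`` in ln units), emulating densitometry error against a
    constant actin loading control.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 3])
    if targets is None:
        effects = sorted(truth.effect_accessions)
        targets = effects[:2] if len(effects) >= 2 else sorted(truth.true_log2fc)[:2]
    rows = []
    for acc in targets:
        fc = 2.0 ** truth.true_log2fc.get(acc, 0.0)
        for d in range(config.n_dogs):
            actin_d0 = rng.uniform(800, 1200)
            actin_d7 = rng.uniform(800, 1200)
            base = rng.uniform(200, 2000)
            ner = fc * math.exp(rng.normal(0.0, noise_sd))
            rows.append(
                {
                    "dog_id": f"dog{d + 1}",
                    "target_protein": acc,
                    "band_volume_d0": base,
                    "band_volume_d7": base * ner * actin_d7 / actin_d0,
                    "actin_volume_d0": actin_d0,
                    "actin_volume_d7": actin_d7,
                }
            )
    return pd.DataFrame(rows)


def null_config(**overrides) -> SimConfig:
    """A convenience no-effect configuration for type-I-error studies."""
    cfg = SimConfig(frac_true_effect=0.0)
    return replace(cfg, **overrides)
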