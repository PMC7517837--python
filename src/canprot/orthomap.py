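"""Three-stage ortholog identifier mapping and ranked-list construction.

Canine protein accessions reach human gene identifiers through an ordered
chain of mapping stages (canine accession -> canine Ensembl protein ->
human Ensembl protein -> human Entrez gene). Each stage has a primary
table and an optional fallback table consulted only on a primary miss,
mirroring the common practice of patching BioMart gaps with Bioconductor
annotation packages. One-to-many mappings resolve deterministically:
highest confidence first (absent confidence counts as 0), then
lexicographically smallest target.

``build_rnk`` turns per-protein fold changes into a preranked gene list:
score = log2(FC); unmapped proteins are dropped (counted); duplicate human
genes collapse to the score of largest magnitude, ties going to the
lexicographically smaller source accession; output is sorted by score
descending with ties broken by gene id ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import read_mapping_table

logger = logging.getLogger(__name__)


def _index(rows) -> dict[str, list[tuple[str, float | None]]]:
    out: dict[str, list[tuple[str, float | None]]] = {}
    for src, tgt, conf in rows:
        out.setdefault(src, []).append((tgt, conf))
    return out


@dataclass
class MappingStage:
    """One hop of the chain: primary table first, fallback on a miss."""

    source_namespace: str
    target_namespace: str
    primary: dict[str, list[tuple[str, float | None]]] = field(default_factory=dict)
    fallback: dict[str, list[tuple[str, float | None]]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, source_namespace, target_namespace, primary_rows,
                  fallback_rows=()):
        return cls(
            source_namespace,
            target_namespace,
            _index(primary_rows),
            _index(fallback_rows),
        )

    @classmethod
    def from_files(cls, source_namespace, target_namespace, primary_path,
                   fallback_path=None):
        primary = read_mapping_table(primary_path)
        fallback = read_mapping_table(fallback_path) if fallback_path else []
        return cls.from_rows(source_namespace, target_namespace, primary, fallback)

    def lookup(self, identifier: str) -> tuple[str, str] | None:
        """Resolve one identifier; returns (target, table_used) or None."""
        for table_name in ("primary", "fallback"):
            candidates = getattr(self, table_name).get(identifier)
            if candidates:
                best = min(
                    candidates,
                    key=lambda c: (-(c[1] if c[1] is not None else 0.0), c[0]),
                )
                return best[0], table_name
        return None


def chain_map(
    accession: str, stages: list[MappingStage]
) -> tuple[str | None, list[str]]:
    """Map an accession through all stages in order.

    Returns ``(human_gene_id, provenance)`` where provenance records which
    table resolved each hop; ``(None, provenance)`` if any hop fails after
    the fallback. Pure function of (accession, tables).
    """
    current = accession
    provenance: list[str] = []
    for stage in stages:
        hit = stage.lookup(current)
        if hit is None:
            provenance.append(f"{stage.source_namespace}->{stage.target_namespace}:unmapped")
            return None, provenance
        current, table = hit
        provenance.append(f"{stage.source_namespace}->{stage.target_namespace}:{table}")
    return current, provenance


def build_rnk(
    quant: pd.DataFrame, stages: list[MappingStage]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build a ranked gene list from per-protein fold changes.

    ``quant`` needs columns ``protein_accession`` and ``fc`` (positive;
    rows with absent fc are ignored). Returns the ranked DataFrame with
    columns ``gene_id``, ``score`` and a stats dict satisfying
    ``n_ranked + n_unmapped + n_collapsed == n_input``.
    """
    rows = quant[quant["fc"].notna()] if "fc" in quant else quant
    n_input = len(rows)
    mapped: dict[str, tuple[float, str]] = {}
    n_unmapped = 0
    n_collapsed = 0
    for acc, fc in sorted(zip(rows["protein_accession"], rows["fc"])):
        gene, _prov = chain_map(acc, stages)
        if gene is None:
            n_unmapped += 1
            continue
        score = float(np.log2(fc))
        if gene in mapped:
            prev_score, prev_acc = mapped[gene]
            # Keep the strongest signal; tie -> lexicographically smaller
            # source accession (sorted iteration makes that the incumbent).
            if abs(score) > abs(prev_score):
                mapped[gene] = (score, acc)
            n_collapsed += 1
        else:
            mapped[gene] = (score, acc)
    if not mapped:
        raise InsufficientDataError(
            "no protein mapped to a human gene; check mapping-table coverage"
        )
    df = pd.DataFrame(
        {"gene_id": list(mapped), "score": [v[0] for v in mapped.values()]}
    ).sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    stats = {
        "n_input": n_input,
        "n_ranked": len(df),
        "n_unmapped": n_unmapped,
        "n_collapsed": n_collapsed,
    }
    logger.info(
        "build_rnk: %(n_input)d proteins in, %(n_ranked)d ranked, "
        "%(n_unmapped)d unmapped dropped, %(n_collapsed)d duplicates collapsed",
        stats,
    )
    return df, stats
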