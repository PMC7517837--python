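"""Immunoblot densitometry normalization and concordance with LC-MS/MS.

Band volumes are normalized to the actin loading control; the normalized
expression ratio NER D7/D0 is the normalized expression after
supplementation divided by the one before. Concordance with the mass-
spectrometry fold change is called qualitatively on direction, with a
small flat band around 1 (default ±5%) inside which a ratio counts as
unchanged and the call is ambiguous.
"""

from __future__ import annotations

import pandas as pd

from .errors import DomainError

BLOT_COLUMNS = [
    "dog_id",
    "target_protein",
    "band_volume_d0",
    "band_volume_d7",
    "actin_volume_d0",
    "actin_volume_d7",
]


def normalized_expression(band_volume: float, actin_volume: float) -> float:
    """Band volume over the matching actin band volume."""
    if band_volume <= 0 or actin_volume <= 0:
        raise DomainError("band and actin volumes must be positive")
    return band_volume / actin_volume


def ner(norm_d7: float, norm_d0: float) -> float:
    """Normalized expression ratio D7/D0."""
    if norm_d7 <= 0 or norm_d0 <= 0:
        raise DomainError("normalized expressions must be positive")
    return norm_d7 / norm_d0


def _direction(x: float, band: float) -> str:
    # multiplicative band: keeps the call invariant under x -> 1/x
    if x > 1.0 + band:
        return "up"
    if x < 1.0 / (1.0 + band):
        return "down"
    return "flat"


def concordance(ner_value: float, fc: float, band: float = 0.05) -> str:
    """Directional agreement between blot NER and LC-MS/MS fold change.

    ``concordant`` when both point the same non-flat way, ``discordant``
    when they point opposite ways, ``ambiguous`` when either falls inside
    the flat band.
    """
    if ner_value <= 0 or fc <= 0:
        raise DomainError("ner and fc must be positive")
    a, b = _direction(ner_value, band), _direction(fc, band)
    if "flat" in (a, b):
        return "ambiguous"
    return "concordant" if a == b else "discordant"


def blot_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add the NER D7/D0 column to a band-volume table."""
    missing = [c for c in BLOT_COLUMNS if c not in records.columns]
    if missing:
        raise DomainError(f"blot table missing columns {missing}")
    out = records.copy()
    out["ner"] = [
        ner(
            normalized_expression(r.band_volume_d7, r.actin_volume_d7),
            normalized_expression(r.band_volume_d0, r.actin_volume_d0),
        )
        for r in records.itertuples()
    ]
    return out


def concordance_report(
    blots: pd.DataFrame, per_dog_fc: pd.DataFrame, band: float = 0.05
) -> pd.DataFrame:
    """Join blot NERs with per-dog LC-MS/MS fold changes and call concordance.

    ``per_dog_fc`` needs columns ``dog_id``, ``protein_accession``, ``fc``.
    Dogs without a mass-spectrometry fold change for the target get an
    absent call.
    """
    fc_lookup = {
        (r.dog_id, r.protein_accession): r.fc for r in per_dog_fc.itertuples()
    }
    rows = []
    for r in blots.itertuples():
        fc = fc_lookup.get((r.dog_id, r.target_protein))
        rows.append(
            {
                "dog_id": r.dog_id,
                "target_protein": r.target_protein,
                "ner": r.ner,
                "fc": fc,
                "call": concordance(r.ner, fc, band) if fc is not None else None,
            }
        )
    return pd.DataFrame(rows)
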