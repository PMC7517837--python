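"""Peptide-ratio quantification of paired (pre/post) label-free proteomes.

The fold change of a protein between day 7 (post) and day 0 (pre) is built
bottom-up:

1. For each peptide group, form *all* cross-ratios ``a_i / b_j`` between the
   D7 replicate abundances ``a_i`` and the D0 replicate abundances ``b_j``.
2. The peptide-group ratio is the geometric median of those cross-ratios.
   For scalars the geometric median reduces to ``exp(median(log x))`` — the
   ordinary median in log space (geometric mean of the two central values
   when the count is even).
3. The protein ratio (FC D7/D0) is the geometric median of its
   peptide-group ratios.

Significance of a protein's shift is a two-sided one-sample t-test of the
log2 peptide-group ratios against zero. Detection-based filtering keeps
proteins seen in a strict majority of samples at *both* timepoints
(``both``), or seen at exactly one timepoint (``d0_only``/``d7_only``).
Per-dog comparisons use each dog's single D7/D0 sample pair and are
classified by the 2-fold rule (FC < 0.5 down, FC > 2 up) with no p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError

COMPARISON_ALL = "all_dogs"
COMPARISON_BCELL = "bcell_subset"


# ---------------------------------------------------------------------------
# scalar primitives
# ---------------------------------------------------------------------------

def ratio_combinations(numerator_abundances, denominator_abundances) -> np.ndarray:
    """All cross-ratios ``a_i / b_j``, numerator-major order.

    Raises
    ------
    InsufficientDataError
        If either sequence is empty.
    """
    num = np.asarray(list(numerator_abundances), dtype=float)
    den = np.asarray(list(denominator_abundances), dtype=float)
    if num.size == 0 or den.size == 0:
        raise InsufficientDataError("ratio_combinations requires nonempty sequences")
    return (num[:, None] / den[None, :]).ravel()


def geometric_median(values) -> float:
    """Geometric median of positive scalars: ``exp(median(log x))``.

    For an even number of values the log-space median is the arithmetic mean
    of the two central log values, i.e. the geometric mean of the two
    central values.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise InsufficientDataError("geometric_median requires a nonempty sequence")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DomainError("geometric_median requires strictly positive finite values")
    return float(np.exp(np.median(np.log(x))))


def peptide_group_ratio(d7_abundances, d0_abundances) -> float | None:
    """Geometric median of all D7-over-D0 cross-ratios for one peptide group.

    Returns ``None`` (absent) when either timepoint has no detected
    abundance — absence is a value here, not an error.
    """
    d7 = list(d7_abundances)
    d0 = list(d0_abundances)
    if not d7 or not d0:
        return None
    return geometric_median(ratio_combinations(d7, d0))


def protein_ratio(peptide_group_ratios) -> float:
    """Protein fold change: geometric median of present peptide-group ratios."""
    present = [r for r in peptide_group_ratios if r is not None]
    if not present:
        raise InsufficientDataError("protein_ratio requires >=1 present peptide-group ratio")
    return geometric_median(present)


def protein_significance(log2_ratios) -> float | None:
    """Two-sided one-sample t-test p-value of log2 peptide-group ratios vs 0.

    Returns ``None`` with fewer than two finite ratios. Zero-variance
    degenerate samples use the sign convention: p=1 when the common value is
    0 (zero t-statistic), p=0 otherwise.
    """
    x = np.asarray([v for v in log2_ratios if v is not None], dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return None
    if np.ptp(x) == 0.0:
        return 1.0 if x[0] == 0.0 else 0.0
    t, p = stats.ttest_1samp(x, 0.0)
    return float(p)


def detection_filter(
    n_detected_d0: int, n_detected_d7: int, n_samples_d0: int, n_samples_d7: int
) -> str:
    """Classify a protein's detection pattern across the cohort.

    ``both`` needs detection in strictly more than half the samples at each
    timepoint (for 7 samples that is >=4); ``d0_only``/``d7_only`` need >=1
    detection at one timepoint and none at the other; anything else is
    ``excluded``.
    """
    if n_detected_d0 > n_samples_d0 / 2 and n_detected_d7 > n_samples_d7 / 2:
        return "both"
    if n_detected_d0 >= 1 and n_detected_d7 == 0:
        return "d0_only"
    if n_detected_d7 >= 1 and n_detected_d0 == 0:
        return "d7_only"
    return "excluded"


def classify_fold_change(fc: float) -> str:
    """2-fold rule: ``down`` if fc < 0.5, ``up`` if fc > 2, else ``unchanged``.

    Boundaries are exclusive: fc of exactly 0.5 or 2 is ``unchanged``.
    """
    if not np.isfinite(fc) or fc <= 0:
        raise DomainError(f"fold change must be a positive finite real, got {fc!r}")
    if fc < 0.5:
        return "down"
    if fc > 2.0:
        return "up"
    return "unchanged"


def format_percentage(count: int, total: int) -> str:
    """Percentage to 1 decimal, half-away-from-zero, without a trailing '.0'.

    266 of 299 renders as '89'; 210 of 211 as '99.5'.
    """
    if total <= 0:
        raise DomainError("format_percentage requires a positive total")
    pct = Decimal(100 * count) / Decimal(total)
    q = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    s = str(q)
    return s[:-2] if s.endswith(".0") else s


# ---------------------------------------------------------------------------
# cohort-level tables
# ---------------------------------------------------------------------------

@dataclass
class DetectionPartition:
    """Cohort-level detection classes (pairwise-disjoint accession sets)."""

    both: set[str]
    d0_only: set[str]
    d7_only: set[str]

    def sizes(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "d0_only": len(self.d0_only),
            "d7_only": len(self.d7_only),
        }


def _sample_universe(peptides: pd.DataFrame) -> pd.DataFrame:
    """Distinct (dog_id, timepoint, sample_id) present anywhere in the table."""
    return peptides[["dog_id", "timepoint", "sample_id"]].drop_duplicates()


def _detection_counts(peptides: pd.DataFrame) -> pd.DataFrame:
    """Per-protein count of samples (per timepoint) with >=1 peptide present."""
    det = (
        peptides[["protein_accession", "timepoint", "sample_id"]]
        .drop_duplicates()
        .groupby(["protein_accession", "timepoint"])
        .size()
        .unstack(fill_value=0)
    )
    for tp in ("D0", "D7"):
        if tp not in det.columns:
            det[tp] = 0
    return det[["D0", "D7"]]


def protein_quant_table(
    peptides: pd.DataFrame, dogs=None, comparison: str = COMPARISON_ALL
) -> pd.DataFrame:
    """Per-protein fold change, p-value and detection class for a dog subset.

    Peptide-group ratios pool all D7 replicates over all D0 replicates of
    the subset; the replicates are the dogs (one sample per dog per
    timepoint). A p-value is reported only when >=2 peptide-group ratios are
    available and the protein's measurements span >=2 dogs.
    """
    sub = peptides if dogs is None else peptides[peptides["dog_id"].isin(set(dogs))]
    if sub.empty:
        raise InsufficientDataError("no peptide measurements for the requested dogs")
    universe = _sample_universe(sub)
    n_samples = universe.groupby("timepoint")["sample_id"].nunique()
    n_d0 = int(n_samples.get("D0", 0))
    n_d7 = int(n_samples.get("D7", 0))
    det = _detection_counts(sub)

    rows = []
    for acc, grp in sub.groupby("protein_accession", sort=True):
        ratios = []
        for _pep, pg in grp.groupby("peptide_id", sort=True):
            d7 = pg.loc[pg["timepoint"] == "D7", "abundance"].to_numpy()
            d0 = pg.loc[pg["timepoint"] == "D0", "abundance"].to_numpy()
            r = peptide_group_ratio(d7, d0)
            if r is not None:
                ratios.append(r)
        n_det_d0 = int(det.at[acc, "D0"]) if acc in det.index else 0
        n_det_d7 = int(det.at[acc, "D7"]) if acc in det.index else 0
        dclass = detection_filter(n_det_d0, n_det_d7, n_d0, n_d7)
        if ratios:
            fc = protein_ratio(ratios)
            log2_fc = float(np.log2(fc))
            p = (
                protein_significance(np.log2(ratios))
                if grp["dog_id"].nunique() >= 2
                else None
            )
            direction = classify_fold_change(fc)
        else:
            fc = log2_fc = p = None
            direction = None
        rows.append(
            {
                "protein_accession": acc,
                "comparison": comparison,
                "fc": fc,
                "log2_fc": log2_fc,
                "p_value": p,
                "n_peptide_groups": len(ratios),
                "detection_class": dclass,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def cohort_differential_table(
    peptides: pd.DataFrame,
    dogs=None,
    alpha: float = 0.05,
    comparison: str = COMPARISON_ALL,
) -> tuple[pd.DataFrame, dict]:
    """Significantly shifted proteins for a >=2-dog subset, plus a summary.

    Keeps proteins with detection class ``both`` and p < alpha, splits them
    into downregulated (fc < 1) and upregulated (fc > 1), sorts by
    (p ascending, accession), and reports per-direction median and range of
    the fold change.
    """
    sub = peptides if dogs is None else peptides[peptides["dog_id"].isin(set(dogs))]
    if sub.empty or sub["dog_id"].nunique() < 2:
        raise InsufficientDataError(
            "cohort comparison requires >=2 dogs; use the per-dog analysis instead"
        )
    quant = protein_quant_table(sub, comparison=comparison)
    mask = (
        (quant["detection_class"] == "both")
        & quant["p_value"].notna()
        & (quant["p_value"] < alpha)
    )
    table = quant[mask].sort_values(
        ["p_value", "protein_accession"], kind="mergesort"
    ).reset_index(drop=True)

    summary: dict = {"n_significant": len(table), "n_tested": int(
        ((quant["detection_class"] == "both") & quant["p_value"].notna()).sum()
    )}
    for label, sel in (("down", table["fc"] < 1), ("up", table["fc"] > 1)):
        fcs = table.loc[sel, "fc"]
        summary[f"n_{label}"] = int(sel.sum())
        if len(fcs):
            summary[f"median_fc_{label}"] = float(fcs.median())
            summary[f"range_fc_{label}"] = (float(fcs.min()), float(fcs.max()))
        else:
            summary[f"median_fc_{label}"] = None
            summary[f"range_fc_{label}"] = None
    return table, summary


def per_dog_quant(peptides: pd.DataFrame) -> pd.DataFrame:
    """Per-dog, per-protein fold change from each dog's single D0/D7 pair.

    Each dog contributes exactly one D7/D0 ratio per peptide group; no
    p-value is computed for single-dog comparisons.
    """
    rows = []
    for dog, dgrp in peptides.groupby("dog_id", sort=True):
        for acc, grp in dgrp.groupby("protein_accession", sort=True):
            ratios = []
            for _pep, pg in grp.groupby("peptide_id", sort=True):
                d7 = pg.loc[pg["timepoint"] == "D7", "abundance"].to_numpy()
                d0 = pg.loc[pg["timepoint"] == "D0", "abundance"].to_numpy()
                r = peptide_group_ratio(d7, d0)
                if r is not None:
                    ratios.append(r)
            if not ratios:
                continue
            fc = protein_ratio(ratios)
            rows.append(
                {
                    "dog_id": dog,
                    "protein_accession": acc,
                    "comparison": f"single_dog:{dog}",
                    "fc": fc,
                    "log2_fc": float(np.log2(fc)),
                    "p_value": None,
                    "n_peptide_groups": len(ratios),
                    "direction": classify_fold_change(fc),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "dog_id",
            "protein_accession",
            "comparison",
            "fc",
            "log2_fc",
            "p_value",
            "n_peptide_groups",
            "direction",
        ],
    )


def per_dog_summary(per_dog: pd.DataFrame) -> pd.DataFrame:
    """Per-dog counts of >=2-fold shifted proteins with formatted percentages.

    ``retained`` counts proteins whose direction is not ``unchanged``;
    percentages are of the retained count, absent when nothing is retained.
    """
    rows = []
    for dog, grp in per_dog.groupby("dog_id", sort=True):
        n_down = int((grp["direction"] == "down").sum())
        n_up = int((grp["direction"] == "up").sum())
        retained = n_down + n_up
        rows.append(
            {
                "dog_id": dog,
                "n_retained": retained,
                "n_down": n_down,
                "n_up": n_up,
                "pct_down": format_percentage(n_down, retained) if retained else None,
                "pct_up": format_percentage(n_up, retained) if retained else None,
            }
        )
    return pd.DataFrame(rows)


def venn_partition(peptides: pd.DataFrame) -> DetectionPartition:
    """Partition detected proteins by cohort-level timepoint presence.

    ``d7_only``: detected in >=1 dog at D7 and no dog at D0; ``d0_only``
    symmetric; ``both``: detected at both timepoints somewhere in the
    cohort. The three sets are disjoint and cover every detected protein.
    """
    det = _detection_counts(peptides)
    d0 = det["D0"] > 0
    d7 = det["D7"] > 0
    return DetectionPartition(
        both=set(det.index[d0 & d7]),
        d0_only=set(det.index[d0 & ~d7]),
        d7_only=set(det.index[d7 & ~d0]),
    )
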