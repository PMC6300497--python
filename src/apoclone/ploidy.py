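"""Flow-cytometry peak ratios to relative DNA content and cytotype calls.

Propidium-iodide flow cytometry measures relative nuclear DNA content: the
ratio of a sample's G1 peak mean to that of a co-chopped internal standard of
known genome size gives the sample's 2C value in picograms.  Dividing twice
the 2C value by a diploid reference 2C yields a continuous ploidy estimate;
samples near an integer are called as that cytotype (2x/3x/4x, chromosome
number 2n = ploidy * x), others are flagged ambiguous rather than silently
assigned.

Inputs are peak summaries (means and CV%), not raw FCS histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FcmRecord",
    "relative_2c",
    "infer_ploidy",
    "classify_records",
    "cytotype_table",
    "read_fcm_csv",
    "SORBUS_BASE_X",
]

#: base chromosome number for Sorbus and other Maloideae
SORBUS_BASE_X = 17


@dataclass
class FcmRecord:
    """One sample's flow-cytometry peak summary and derived ploidy call."""

    sample_id: str
    sample_peak: float
    standard_peak: float
    standard_2c: float = 1.0  # pg; e.g. Oryza sativa 'IR36' = 1 pg
    cv_percent: float = 0.0
    taxon: str = ""
    relative_2c: float | None = None
    inferred_ploidy: int | None = None
    inferred_2n: int | None = None
    ambiguous: bool = False


def relative_2c(sample_peak: float, standard_peak: float,
                standard_2c: float = 1.0) -> float:
    """Relative 2C DNA content in pg: (sample/standard peak) * standard 2C."""
    if sample_peak <= 0 or standard_peak <= 0:
        raise ValueError("peak means must be positive")
    if standard_2c <= 0:
        raise ValueError("standard 2C must be positive")
    return (sample_peak / standard_peak) * standard_2c


def infer_ploidy(
    rel_2c: float,
    diploid_ref_2c: float,
    base_x: int = SORBUS_BASE_X,
    *,
    tolerance: float = 0.25,
) -> tuple[int, int] | None:
    """Cytotype call from relative 2C against a diploid reference.

    The continuous estimate is ``p* = 2 * rel_2c / diploid_ref_2c``; the call
    is the nearest integer when within ``tolerance``, else ``None``
    (ambiguous).  Genome downsizing in polyploids makes p* fall short of the
    integer (e.g. a tetraploid at 1.88x the diploid 2C gives p* = 3.77), so
    the default tolerance is generous but still rejects midpoints.
    Returns ``(ploidy, 2n)`` with 2n = ploidy * base_x.
    """
    if diploid_ref_2c <= 0:
        raise ValueError("diploid reference 2C must be positive")
    if base_x < 1:
        raise ValueError("base chromosome number must be >= 1")
    p_star = 2.0 * rel_2c / diploid_ref_2c
    p = int(round(p_star))
    if p < 1 or abs(p_star - p) > tolerance:
        return None
    return p, p * base_x


def classify_records(
    records: list[FcmRecord],
    diploid_ref_2c: float,
    base_x: int = SORBUS_BASE_X,
    *,
    tolerance: float = 0.25,
) -> list[FcmRecord]:
    """Fill in relative_2c and the ploidy call for each record, in place."""
    for r in records:
        r.relative_2c = relative_2c(r.sample_peak, r.standard_peak, r.standard_2c)
        call = infer_ploidy(r.relative_2c, diploid_ref_2c, base_x, tolerance=tolerance)
        if call is None:
            r.ambiguous = True
            r.inferred_ploidy = r.inferred_2n = None
        else:
            r.ambiguous = False
            r.inferred_ploidy, r.inferred_2n = call
    return records


def cytotype_table(records: list[FcmRecord]) -> pd.DataFrame:
    """Per-cytotype summary: N, 2C min–max, mean ± SD, mean CV%.

    Ambiguous records are listed as their own ``ploidy = "ambiguous"`` row
    and excluded from the numeric summaries.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    called = [r for r in records if not r.ambiguous and r.relative_2c is not None]
    for p in sorted({r.inferred_ploidy for r in called}):
        grp = [r for r in called if r.inferred_ploidy == p]
        vals = np.array([r.relative_2c for r in grp])
        rows.append(
            {
                "ploidy": f"{p}x",
                "2n": grp[0].inferred_2n,
                "N": len(grp),
                "min_2c": vals.min(),
                "max_2c": vals.max(),
                "mean_2c": vals.mean(),
                "sd_2c": vals.std(ddof=1) if len(grp) > 1 else 0.0,
                "mean_cv": float(np.mean([r.cv_percent for r in grp])),
            }
        )
    amb = [r for r in records if r.ambiguous]
    if amb:
        vals = np.array([r.relative_2c for r in amb])
        rows.append(
            {
                "ploidy": "ambiguous",
                "2n": None,
                "N": len(amb),
                "min_2c": vals.min(),
                "max_2c": vals.max(),
                "mean_2c": vals.mean(),
                "sd_2c": vals.std(ddof=1) if len(amb) > 1 else 0.0,
                "mean_cv": float(np.mean([r.cv_percent for r in amb])),
            }
        )
    return pd.DataFrame(rows)


def read_fcm_csv(path) -> list[FcmRecord]:
    """Read peak summaries: sample_id,sample_peak,standard_peak,standard_2c,cv_percent[,taxon]."""
    df = pd.read_csv(path)
    recs = []
    for _, row in df.iterrows():
        recs.append(
            FcmRecord(
                sample_id=str(row["sample_id"]),
                sample_peak=float(row["sample_peak"]),
                standard_peak=float(row["standard_peak"]),
                standard_2c=float(row.get("standard_2c", 1.0)),
                cv_percent=float(row.get("cv_percent", 0.0)),
                taxon=str(row["taxon"]) if "taxon" in df.columns else "",
            )
        )
    return recs


def write_fcm_csv(records: list[FcmRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "taxon": r.taxon,
                "sample_peak": r.sample_peak,
                "standard_peak": r.standard_peak,
                "standard_2c": r.standard_2c,
                "cv_percent": r.cv_percent,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
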