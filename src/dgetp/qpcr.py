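"""Efficiency-corrected relative qPCR quantification and cross-method
correlation.

Relative transcript ratios are computed by the efficiency-corrected
delta-delta-Ct method: for a target gene with amplification efficiency E
(fold amplification per cycle; 2 = perfect doubling) and cycle-threshold
shift dCt = Ct_control - Ct_treated, the raw fold change is E**dCt, which
is then normalized by the geometric mean of the same quantity over one or
more reference genes (typically ribosomal protein genes) measured in the
same condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class QpcrMeasurement:
    gene_id: str
    condition: str
    ct_treated: float
    ct_control: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(
                f"amplification efficiency must be in (1, 2.2], got {self.efficiency}"
            )
        if self.ct_treated <= 0 or self.ct_control <= 0:
            raise ValueError("Ct values must be > 0")

    @property
    def delta_ct(self) -> float:
        return self.ct_control - self.ct_treated

    @property
    def raw_fold(self) -> float:
        return self.efficiency ** self.delta_ct


def efficiency_corrected_ratio(
    target: QpcrMeasurement, references: Sequence[QpcrMeasurement]
) -> float:
    """Fold change of the target normalized to reference genes.

    ratio = E_t**dCt_t / geomean_r(E_r**dCt_r); references must share the
    target's condition.
    """
    refs = [r for r in references if r.condition == target.condition]
    if not refs:
        raise ValueError(
            f"no reference measurement for condition {target.condition!r}"
        )
    log_norm = math.fsum(math.log(r.raw_fold) for r in refs) / len(refs)
    return target.raw_fold / math.exp(log_norm)


def ratio_table(
    measurements: Iterable[QpcrMeasurement], reference_genes: set[str]
) -> pd.DataFrame:
    """Normalized ratios for all non-reference (gene, condition) pairs."""
    ms = list(measurements)
    refs = [m for m in ms if m.gene_id in reference_genes]
    rows = [
        {
            "gene": m.gene_id,
            "condition": m.condition,
            "ratio": efficiency_corrected_ratio(m, refs),
        }
        for m in ms
        if m.gene_id not in reference_genes
    ]
    return pd.DataFrame(rows)


def cross_method_correlation(log_ratios_a, log_ratios_b) -> tuple[float, float]:
    """Pearson r between paired log10 ratios and its two-sided p-value.

    Used to validate tag-derived transcription ratios against qPCR, and
    equally applicable to any paired numeric summaries (e.g. response
    counts vs exposure molarity).
    """
    a = pd.Series(log_ratios_a, dtype=float)
    b = pd.Series(log_ratios_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("inputs must be paired")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if not (a.notna().all() and b.notna().all()):
        raise ValueError("inputs must be finite")
    if a.nunique() == 1 or b.nunique() == 1:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(a.to_numpy(), b.to_numpy())
    return float(r), float(p)


def read_qpcr_tsv(path: str | Path) -> tuple[list[QpcrMeasurement], set[str]]:
    """Read measurements from TSV with columns:
    gene, condition, ct_treated, ct_control, efficiency, is_reference."""
    df = pd.read_csv(path, sep="\t")
    measurements = [
        QpcrMeasurement(
            gene_id=row["gene"], condition=row["condition"],
            ct_treated=float(row["ct_treated"]), ct_control=float(row["ct_control"]),
            efficiency=float(row["efficiency"]),
        )
        for _, row in df.iterrows()
    ]
    refs = set(df.loc[df["is_reference"].astype(bool), "gene"])
    return measurements, refs
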