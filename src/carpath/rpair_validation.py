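"""ROC validation of the CAR as a classifier of main biotransformation pairs.

Reactant-product pair databases historically label the principal
substrate->product alignment of a reaction "main" and ancillary
alignments (cofactor turnover, leaving groups, transferred moieties)
with secondary types.  If atom conservation drives that distinction, a
simple cutoff on the CAR should recover the main pairs.  This module
sweeps 100 CAR cutoffs, records sensitivity/specificity at each, and
summarizes discrimination by the area under the ROC curve and the
Youden-optimal cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LabeledPair:
    substrate_id: str
    product_id: str
    car: float
    is_main: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.car <= 1.0:
            raise ValueError(f"CAR {self.car} outside [0, 1]")


class RocRow(NamedTuple):
    cutoff: float
    true_positives: int
    false_positives: int
    sensitivity: float
    specificity: float
    youden: float


@dataclass(frozen=True)
class RocTable:
    rows: tuple[RocRow, ...]
    auc: float
    optimal_cutoff: float
    youden_max: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=RocRow._fields)


def predict_main(car: float, cutoff: float) -> bool:
    """A pair is predicted 'main' when its CAR reaches the cutoff."""
    return car >= cutoff


def roc_analysis(pairs: Iterable[LabeledPair], n_cutoffs: int = 100) -> RocTable:
    """ROC of the CAR score against binary main-pair labels.

    For each cutoff ``c_i = i / n_cutoffs`` (i = 1..n_cutoffs) a pair is
    predicted positive when ``car >= c_i``; sensitivity, specificity and
    the Youden index (sensitivity + specificity - 1) are tabulated.  The
    AUC is the trapezoidal area under the (FPR, TPR) points augmented
    with (0,0) and (1,1); the optimal cutoff maximizes the Youden index
    (smallest cutoff on ties).

    Raises ``ValueError`` when only one class is present (AUC undefined).
    """
    pairs = list(pairs)
    cars = np.array([p.car for p in pairs], dtype=float)
    labels = np.array([p.is_main for p in pairs], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC analysis needs at least one positive and one negative label"
        )

    rows: list[RocRow] = []
    fprs, tprs = [0.0], [0.0]
    for i in range(1, n_cutoffs + 1):
        c = i / n_cutoffs
        pred = cars >= c
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        sens = tp / n_pos
        spec = (n_neg - fp) / n_neg
        rows.append(RocRow(c, tp, fp, sens, spec, sens + spec - 1.0))
        fprs.append(fp / n_neg)
        tprs.append(sens)
    fprs.append(1.0)
    tprs.append(1.0)

    order = np.lexsort((tprs, fprs))
    auc = float(np.trapezoid(np.array(tprs)[order], np.array(fprs)[order]))

    youden_max = max(r.youden for r in rows)
    optimal_cutoff = min(r.cutoff for r in rows if r.youden == youden_max)
    return RocTable(
        rows=tuple(rows),
        auc=auc,
        optimal_cutoff=optimal_cutoff,
        youden_max=youden_max,
    )
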