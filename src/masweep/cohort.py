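"""Cohort-level reporting statistics on per-subject diastolic parameters.

Utilities for relating sweep-volume indices to reference tissue-Doppler
measurements (Spearman rank correlation), classifying diastolic dysfunction
(ROC with the accuracy-optimal cutoff), and quantifying reproducibility
between repeated analyses (Bland-Altman bias/limits of agreement and the
intraclass correlation coefficient).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("masweep")


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its p-value.

    Constant input leaves the rank correlation undefined; (nan, nan) is
    returned with a warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input: Spearman correlation undefined")
        return math.nan, math.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RocResult:
    """ROC summary at the accuracy-optimal threshold."""

    auc: float
    cutoff: float            # threshold in the original score scale
    rule: str                # e.g. "score <= cutoff is positive"
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


def roc_analysis(scores, labels, direction: str = "higher_is_positive") -> RocResult:
    """ROC analysis with the cutoff that maximizes classification accuracy.

    ``direction`` states which tail of the score marks the positive
    (dysfunction) class. AUC is the trapezoidal area over all thresholds;
    among cutoffs tying on accuracy the one with higher specificity wins.
    """
    from sklearn.metrics import roc_auc_score

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if direction not in ("higher_is_positive", "lower_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "higher_is_positive" else -1.0
    d = sign * s                       # positive class has high d

    auc = float(roc_auc_score(y, d))

    # candidate thresholds: midpoints between adjacent unique scores, plus
    # sentinels classifying everyone one way
    u = np.unique(d)
    cands = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    best = None
    for thr in cands:
        pred = d > thr
        tp = int((pred & y).sum())
        tn = int((~pred & ~y).sum())
        acc = (tp + tn) / len(y)
        spec = tn / n_neg
        key = (acc, spec)
        if best is None or key > best[0]:
            best = (key, thr, tp, tn)
    _, thr, tp, tn = best
    fp = n_neg - tn
    fn = n_pos - tp
    cmp_word = ">" if sign > 0 else "<"
    return RocResult(
        auc=auc,
        cutoff=float(sign * thr),
        rule=f"score {cmp_word} {sign * thr:.4g} is positive",
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        ppv=tp / (tp + fp) if tp + fp else math.nan,
        npv=tn / (tn + fn) if tn + fn else math.nan,
        accuracy=(tp + tn) / len(y),
    )


def bland_altman(x1, x2) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement between paired measurements.

    bias = mean(x1 - x2); limits = bias +/- 1.96 * SD of the differences.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) != len(x2) or len(x1) < 2:
        raise ValueError("need at least two paired measurements")
    diff = x1 - x2
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def icc(x1, x2, model: str = "ICC2") -> tuple[float, float, float]:
    """Intraclass correlation for two raters/readings with F-based 95% CI.

    Default is the two-way, absolute-agreement, single-measure form (the
    mixed- and random-effects variants share this computation); ``model``
    accepts the standard short codes (ICC1/ICC2/ICC3).
    """
    import pingouin as pg

    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) != len(x2) or len(x1) < 5:
        raise ValueError("need at least five paired measurements")
    if np.ptp(np.concatenate([x1, x2])) == 0:
        logger.warning("zero between-subject variance: ICC undefined")
        return math.nan, math.nan, math.nan
    n = len(x1)
    df = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["r1", "r2"], n),
        "score": np.concatenate([x1, x2]),
    })
    table = pg.intraclass_corr(data=df, targets="subject", raters="rater",
                               ratings="score")
    aliases = {  # short codes vs McGraw-Wong labels, across pingouin versions
        "ICC1": ("ICC1", "ICC(1,1)"), "ICC2": ("ICC2", "ICC(A,1)"),
        "ICC3": ("ICC3", "ICC(C,1)"),
    }.get(model, (model,))
    rows = table[table["Type"].isin(aliases)]
    if rows.empty:
        raise ValueError(f"unknown ICC model {model!r}")
    row = rows.iloc[0]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    ci_low, ci_high = row[ci_col]
    return float(row["ICC"]), float(ci_low), float(ci_high)


# septal e' < 8 cm/s, lateral e' < 10 cm/s, or LA volume index >= 34 mL/m2
E_PRIME_SEPTAL_CUTOFF = 8.0
E_PRIME_LATERAL_CUTOFF = 10.0
LAVI_CUTOFF = 34.0


def assign_dysfunction_label(
    e_prime_septal: float,
    e_prime_lateral: float,
    la_volume_index: float | None = None,
) -> str:
    """Reference-standard labeling of diastolic dysfunction from TTE values.

    A subject is labeled ``dysfunction`` when the septal early-diastolic
    annular velocity is below 8 cm/s, the lateral below 10 cm/s, or the left
    atrial volume index is 34 mL/m^2 or more; otherwise ``normal``.
    """
    if e_prime_septal <= 0 or e_prime_lateral <= 0:
        raise ValueError("annular velocities must be positive")
    dys = (e_prime_septal < E_PRIME_SEPTAL_CUTOFF
           or e_prime_lateral < E_PRIME_LATERAL_CUTOFF
           or (la_volume_index is not None and la_volume_index >= LAVI_CUTOFF))
    return "dysfunction" if dys else "normal"


def cohort_report(
    table: pd.DataFrame,
    score_col: str,
    label_col: str = "group_label",
    reference_cols: dict[str, str] | None = None,
    direction: str = "lower_is_positive",
) -> dict:
    """Summary metrics for a per-subject results table.

    ROC of ``score_col`` against the dysfunction labels, plus Spearman
    correlations against any reference columns supplied as
    ``{name: column}``.
    """
    labels = (table[label_col] == "dysfunction").to_numpy()
    roc = roc_analysis(table[score_col].to_numpy(), labels, direction)
    out = {
        "score": score_col,
        "n": int(len(table)),
        "roc": {k: getattr(roc, k) for k in
                ("auc", "cutoff", "rule", "sensitivity", "specificity",
                 "ppv", "npv", "accuracy")},
        "correlations": {},
    }
    for name, col in (reference_cols or {}).items():
        rho, p = spearman_corr(table[score_col], table[col])
        out["correlations"][name] = {"rho": rho, "p": p}
    return out
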