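"""Inter-rater agreement and method-comparison statistics.

Concordance between pathologist scores and a reference (or between two
pathologists) over the ordered TPS categories is summarized by accuracy and
weighted kappa, with the conventional qualitative reliability bands
(poor / slight / fair / moderate / substantial / almost perfect).
Comparisons of quantification error between imaging conditions use one-sided
Student's t-tests on absolute errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are the rater's calls, columns the reference."""

    counts: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.categories)
        if c.shape != (k, k):
            raise ValueError("counts must be K x K for K categories")
        if k < 2:
            raise ValueError("need at least 2 categories")
        if (c < 0).any():
            raise ValueError("negative counts")
        if c.sum() == 0:
            raise ValueError("no cases")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class AgreementResult:
    accuracy: float
    kappa: float
    weight_scheme: str
    band: str


def confusion_matrix(
    rater: Sequence[str], reference: Sequence[str], categories: Sequence[str]
) -> ConfusionMatrix:
    """Cross-tabulate rater vs reference labels over ordered categories."""
    if len(rater) != len(reference):
        raise ValueError("length mismatch between rater and reference")
    if len(rater) == 0:
        raise ValueError("no cases")
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=int)
    for a, b in zip(rater, reference):
        if a not in index or b not in index:
            raise ValueError(f"unknown label: {a if a not in index else b!r}")
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(counts=counts, categories=tuple(categories))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of cases on the diagonal: trace / total."""
    return float(np.trace(cm.counts) / cm.total)


def kappa_weights(k: int, scheme: str = "linear") -> np.ndarray:
    """Agreement weights ``w_ij`` for K ordered categories."""
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    d = np.abs(i - j) / (k - 1)
    if scheme == "linear":
        return 1.0 - d
    if scheme == "quadratic":
        return 1.0 - d**2
    if scheme == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(cm: ConfusionMatrix, scheme: str = "linear") -> float:
    """Chance-corrected weighted agreement.

    ``kappa = (P_o - P_e) / (1 - P_e)`` with observed weighted agreement
    ``P_o = sum w_ij n_ij / n`` and expected ``P_e = sum w_ij r_i c_j / n^2``
    from the marginals.
    """
    n = cm.total
    w = kappa_weights(len(cm.categories), scheme)
    p_o = float((w * cm.counts).sum() / n)
    r = cm.counts.sum(axis=1)
    c = cm.counts.sum(axis=0)
    p_e = float((w * np.outer(r, c)).sum() / n**2)
    if p_e == 1.0:
        raise ValueError("undefined kappa: degenerate marginals")
    return (p_o - p_e) / (1.0 - p_e)


#: Reliability bands applied to kappa rounded to two decimals.
RELIABILITY_BANDS = (
    (-1.00, "poor"),
    (0.00, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def reliability_band(kappa: float) -> str:
    """Qualitative interpretation of a kappa value.

    Bands: poor (<0), slight (0.01-0.20), fair (0.21-0.40), moderate
    (0.41-0.60), substantial (0.61-0.80), almost perfect (0.81-1.00),
    applied after rounding to two decimals; a rounded value of exactly 0.00
    maps to "slight".
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must be in [-1, 1]")
    k2 = round(kappa, 2)
    label = RELIABILITY_BANDS[0][1]
    for lo, name in RELIABILITY_BANDS:
        if k2 >= lo:
            label = name
    return label


def agreement_summary(cm: ConfusionMatrix, scheme: str = "linear") -> AgreementResult:
    k = weighted_kappa(cm, scheme)
    return AgreementResult(
        accuracy=accuracy(cm), kappa=k, weight_scheme=scheme, band=reliability_band(k)
    )


def one_sided_t(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    paired: bool = True,
) -> tuple[float, float, float]:
    """One-sided Student's t-test that errors_a exceed errors_b.

    Paired (default): ``t = mean(d) / (sd(d)/sqrt(n))`` on ``d = a - b``
    with ``df = n - 1``; unpaired uses the Welch statistic and
    Welch–Satterthwaite df.  Returns ``(t, df, p)`` with the upper-tail
    p-value.  Standard deviations use the n-1 denominator.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        d = a - b
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0:
            if d.mean() == 0:
                raise ValueError("undefined statistic: zero variance, zero mean")
            logger.warning("degenerate variance in paired t-test; p set by sign")
            return (np.inf * np.sign(d.mean()), n - 1, 0.0 if d.mean() > 0 else 1.0)
        t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        if va == 0 and vb == 0:
            if a.mean() == b.mean():
                raise ValueError("undefined statistic: zero variance, zero mean")
            return (np.inf * np.sign(a.mean() - b.mean()), na + nb - 2,
                    0.0 if a.mean() > b.mean() else 1.0)
        se = np.sqrt(va / na + vb / nb)
        t = (a.mean() - b.mean()) / se
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    p = float(stats.t.sf(t, df))
    return (float(t), float(df), p)


def median_absolute_error(
    proportions: Sequence[float], references: Sequence[float]
) -> float:
    """Median of ``|p_i - r_i|`` (mean of the two central values when even)."""
    p = np.asarray(proportions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape:
        raise ValueError("length mismatch")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.median(np.abs(p - r)))
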