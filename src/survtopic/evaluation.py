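"""Model evaluation: concordance index and D-calibration.

Concordance measures discrimination: over all comparable patient pairs
(pairs whose death ordering is known despite censoring), the fraction whose
predicted risk ordering matches the observed ordering.

D-calibration measures distributional calibration of individual survival
curves: if the curves are correct, each patient's predicted survival
probability evaluated at their own death time is uniform on [0, 1]. The
departure from uniformity over G probability bins is tested with a
Hosmer-Lemeshow chi-square statistic on G - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .io_preprocess import SurvivalLabels
from .survival_models import SurvivalCurve

__all__ = ["comparable_pairs", "concordance", "DCalibrationReport", "d_calibration"]


def comparable_pairs(labels: SurvivalLabels) -> list[tuple[int, int]]:
    """Ordered pairs (i, j) where patient i is known to die before j's
    last observed time: i uncensored and y_i < y_j."""
    time, event = labels.time, labels.event
    n = len(time)
    pairs = []
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if j != i and time[i] < time[j]:
                pairs.append((i, j))
    return pairs


def concordance(risks, labels: SurvivalLabels, tie_credit: float = 0.0) -> float:
    """Concordance index of risk scores against right-censored labels.

    A pair scores 1 when the earlier death has the strictly higher risk.
    Risk ties score ``tie_credit`` (0 by default, the strict indicator; 0.5
    matches the convention of most survival packages).
    """
    risks = np.asarray(risks, dtype=float)
    time = labels.time
    event = labels.event.astype(bool)
    # comparable: i uncensored with y_i < y_j
    lt = time[:, None] < time[None, :]
    comp = event[:, None] & lt
    np.fill_diagonal(comp, False)
    n_pairs = int(comp.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    gt = risks[:, None] > risks[None, :]
    eq = risks[:, None] == risks[None, :]
    score = float(np.sum(comp & gt)) + tie_credit * float(np.sum(comp & eq))
    return score / n_pairs


@dataclass
class DCalibrationReport:
    """Per-bin observed/expected death counts and the HL test outcome."""

    n_bins: int
    bin_edges: np.ndarray
    observed: np.ndarray  # E_g: deaths whose predicted P(D >= d_i) fell in bin g
    expected: np.ndarray  # P_g = N / G under perfect calibration
    proportions: np.ndarray  # pi_g = 1 / G
    statistic: float
    dof: int
    pvalue: float

    @property
    def passed(self) -> bool:
        return self.pvalue > 0.05


def d_calibration(
    curves: list[SurvivalCurve], labels: SurvivalLabels, n_bins: int = 20
) -> DCalibrationReport:
    """Hosmer-Lemeshow test of survival-curve calibration (uncensored only).

    For each uncensored patient the predicted probability P(D >= d_i) is
    read off their curve (linear interpolation between grid points, held
    flat beyond the last one) and assigned to one of G equal-width
    probability bins [0, 1/G), ..., [(G-1)/G, 1]. Under perfect calibration
    each bin holds N/G deaths; the statistic

        HL = sum_g (E_g - N/G)^2 / (N * pi_g * (1 - pi_g)),  pi_g = 1/G

    is referred to a chi-square distribution with G - 2 degrees of freedom.
    (The classical grouped form with each bin treated as a binomial over all
    N deaths; see the methods note for why this reading of the group terms
    is used.)
    """
    if n_bins < 3:
        raise ValueError("need at least 3 bins (df = G - 2 >= 1)")
    event = labels.event.astype(bool)
    if not event.any():
        raise ValueError("no uncensored patients")
    if len(curves) != len(labels.time):
        raise ValueError("one curve per patient required")
    probs = np.array(
        [curves[i].probability(labels.time[i]) for i in np.where(event)[0]]
    )
    N = len(probs)
    G = n_bins
    idx = np.minimum((probs * G).astype(int), G - 1)
    observed = np.bincount(idx, minlength=G).astype(float)
    expected = np.full(G, N / G)
    pi = np.full(G, 1.0 / G)
    hl = float(np.sum((observed - expected) ** 2 / (N * pi * (1.0 - pi))))
    dof = G - 2
    pval = float(chi2.sf(hl, dof))
    return DCalibrationReport(
        n_bins=G,
        bin_edges=np.linspace(0.0, 1.0, G + 1),
        observed=observed,
        expected=expected,
        proportions=pi,
        statistic=hl,
        dof=dof,
        pvalue=pval,
    )
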