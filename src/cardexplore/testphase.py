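"""Validation of the observer model through the end-of-round test phase.

If the Bayesian observer captures what is learnable from a round, then test
accuracy should fall toward chance as the observer's end-of-round entropy for
a table rises, and confidence should track the posterior's concentration.
These analyses run on simulated test records and check the expected
qualitative signatures: monotone decline of binned accuracy with entropy, a
negative logistic slope of accuracy on entropy, and a chance-level floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = ["ValidationSummary", "validate_observer", "unsolvable_flag",
           "deck_observation_counts"]


@dataclass
class ValidationSummary:
    """Binned accuracy/confidence vs end-of-round entropy plus a logistic slope."""

    bins: pd.DataFrame        # per bin: edges, mean entropy, accuracy, se, n,
                              # mean confidence for correct / error trials
    slope: float              # logistic slope of accuracy on entropy
    slope_se: float
    intercept: float
    n_records: int

    def is_monotone_decreasing(self, se_tol: float = 0.0) -> bool:
        """Bin-mean accuracy non-increasing in entropy.

        ``se_tol`` allows each increase up to that many binomial standard
        errors (0 demands strict non-increase of the point estimates).
        """
        acc = self.bins["accuracy"].to_numpy()
        se = self.bins["accuracy_se"].to_numpy()
        slack = se_tol * np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
        return bool(np.all(np.diff(acc) <= slack + 1e-12))


def validate_observer(test_records: pd.DataFrame, n_bins: int = 10,
                      drop_practice: bool = True) -> ValidationSummary:
    """Relate test accuracy and confidence to end-of-round entropy.

    Bins use equal-count (quantile) edges, which keeps per-bin standard errors
    stable at small simulated n; empty or degenerate bins are dropped with a
    log entry.  The logistic fit ``correct ~ entropy`` is a standard
    unpenalized fit.
    """
    df = test_records
    if drop_practice and "is_practice" in df:
        df = df[~df["is_practice"].astype(bool)]
    if len(df) == 0:
        raise ValueError("no test records to validate on")
    h = df["end_of_round_entropy"].to_numpy(dtype=float)
    correct = df["correct"].to_numpy(dtype=float)
    conf = df["confidence"].to_numpy(dtype=float)

    edges = np.unique(np.quantile(h, np.linspace(0.0, 1.0, n_bins + 1)))
    if len(edges) == 1:  # constant entropy: single degenerate bin
        edges = np.array([edges[0] - 1e-12, edges[0]])
    if len(edges) - 1 < n_bins:
        log.info("entropy ties reduced the bin count from %d to %d",
                 n_bins, len(edges) - 1)
    idx = np.clip(np.searchsorted(edges, h, side="right") - 1, 0, len(edges) - 2)

    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            log.info("dropping empty entropy bin %d", b)
            continue
        acc = float(correct[m].mean())
        rows.append({
            "bin": b, "lo": float(edges[b]), "hi": float(edges[b + 1]),
            "mean_entropy": float(h[m].mean()), "n": n,
            "accuracy": acc, "accuracy_se": float(np.sqrt(acc * (1 - acc) / n)),
            "confidence_correct": float(conf[m & (correct == 1)].mean())
            if (m & (correct == 1)).any() else np.nan,
            "confidence_error": float(conf[m & (correct == 0)].mean())
            if (m & (correct == 0)).any() else np.nan,
        })
    bins = pd.DataFrame(rows)

    if np.ptp(h) == 0.0:
        log.info("entropy is constant; accuracy~entropy slope undefined")
        slope = slope_se = intercept = float("nan")
    else:
        X = sm.add_constant(h)
        res = sm.GLM(correct, X, family=sm.families.Binomial()).fit()
        slope, slope_se = float(res.params[1]), float(res.bse[1])
        intercept = float(res.params[0])
    return ValidationSummary(
        bins=bins, slope=slope, slope_se=slope_se,
        intercept=intercept, n_records=len(df),
    )


def unsolvable_flag(n_deck1: int, n_deck2: int) -> bool:
    """A table's test question is unsolvable when either deck was never sampled."""
    if n_deck1 < 0 or n_deck2 < 0:
        raise ValueError("observation counts cannot be negative")
    return n_deck1 == 0 or n_deck2 == 0


def deck_observation_counts(trials: pd.DataFrame, participant_id: int,
                            round_id: int, table_id: int) -> tuple[int, int]:
    """Per-deck card counts for one table in one participant-round of a trial table."""
    m = ((trials["participant_id"] == participant_id)
         & (trials["round_id"] == round_id)
         & (trials["chosen_table"] == table_id))
    sub = trials[m]
    return int((sub["chosen_deck"] == 1).sum()), int((sub["chosen_deck"] == 2).sum())
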