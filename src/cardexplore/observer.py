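"""Bayesian observer for the two-deck card task.

The observer tracks, for each deck on a table, a conjugate Beta posterior over
the proportion of orange cards, starting from a flat Beta(1, 1) prior.  The
quantity of interest on each table is the sign of the difference in proportions
between its two decks, ``theta = sgn(pi1 - pi2)``.  From the pair of Beta
posteriors the observer derives

* ``P(theta = 1) = P(pi1 > pi2)`` by integrating the density of deck 1 against
  the CDF of deck 2,
* the entropy of the binary posterior over theta (in nats), the task's
  uncertainty measure,
* the expected information gain (EIG) of the next card: the expected reduction
  in that entropy under the posterior-predictive distribution of the card's
  colour, and
* the exposure count: the total number of cards observed on the table.

All quantities are deterministic functions of the four Beta pseudo-counts, so
they are memoised on integer counts (the only case arising in simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from scipy import integrate, special, stats

__all__ = [
    "ORANGE",
    "BLUE",
    "LN2",
    "MAX_TABLE_ENTROPY",
    "MAX_OVERALL_UNCERTAINTY",
    "DECK_POLICIES",
    "DV_KINDS",
    "DeckBelief",
    "TableBelief",
    "update",
    "prob_theta_positive",
    "entropy_theta",
    "expected_information_gain",
    "deck_information_gains",
    "exposure",
    "delta_dv",
    "overall_uncertainty",
]

ORANGE = 1
BLUE = 0

LN2 = math.log(2.0)
#: entropy of a table the observer knows nothing about (flat priors on both decks)
MAX_TABLE_ENTROPY = LN2
#: two fresh tables presented together
MAX_OVERALL_UNCERTAINTY = 2.0 * LN2

DECK_POLICIES = ("max_over_decks", "mean_over_decks", "least_sampled_deck")
DV_KINDS = ("eig", "uncertainty", "exposure")


@dataclass(frozen=True)
class DeckBelief:
    """Beta posterior over one deck's orange-card proportion.

    ``alpha`` counts 1 (the flat prior) plus orange cards seen; ``beta``
    counts 1 plus blue cards seen.
    """

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1:
            raise ValueError(
                f"pseudo-counts must be >= 1 (flat prior), got "
                f"alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def n_observed(self) -> float:
        """Number of cards observed on this deck."""
        return self.alpha + self.beta - 2.0

    @property
    def mean(self) -> float:
        """Posterior-predictive probability that the next card is orange."""
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class TableBelief:
    """Pair of deck beliefs for one table."""

    deck1: DeckBelief = DeckBelief()
    deck2: DeckBelief = DeckBelief()

    @classmethod
    def fresh(cls) -> "TableBelief":
        return cls(DeckBelief(), DeckBelief())

    @classmethod
    def from_counts(cls, a1, b1, a2, b2) -> "TableBelief":
        return cls(DeckBelief(a1, b1), DeckBelief(a2, b2))

    def counts(self) -> tuple[float, float, float, float]:
        return (self.deck1.alpha, self.deck1.beta, self.deck2.alpha, self.deck2.beta)

    def with_card(self, deck: int, color: int) -> "TableBelief":
        if deck not in (1, 2):
            raise ValueError(f"deck must be 1 or 2, got {deck}")
        if deck == 1:
            return TableBelief(update(self.deck1, color), self.deck2)
        return TableBelief(self.deck1, update(self.deck2, color))


def update(belief: DeckBelief, color: int) -> DeckBelief:
    """Conjugate update: orange increments alpha, blue increments beta."""
    if color == ORANGE:
        return DeckBelief(belief.alpha + 1, belief.beta)
    if color == BLUE:
        return DeckBelief(belief.alpha, belief.beta + 1)
    raise ValueError(f"color must be {BLUE} (blue) or {ORANGE} (orange), got {color!r}")


def _is_int(x: float) -> bool:
    return float(x).is_integer()


@lru_cache(maxsize=None)
def _p_greater_int(a1: int, b1: int, a2: int, b2: int) -> float:
    # Exact P(X > Y) for X~Beta(a1,b1), Y~Beta(a2,b2) with integer parameters:
    # sum_{i=0}^{a1-1} B(a2+i, b1+b2) / ((b1+i) B(1+i, b1) B(a2, b2)).
    # Sum over the smaller first parameter via P(X>Y) = 1 - P(Y>X).
    if a2 < a1:
        return 1.0 - _p_greater_int(a2, b2, a1, b1)
    lbeta = special.betaln
    c = lbeta(a2, b2)
    total = 0.0
    for i in range(a1):
        total += math.exp(lbeta(a2 + i, b1 + b2) - math.log(b1 + i) - lbeta(1 + i, b1) - c)
    return min(max(total, 0.0), 1.0)


def _p_greater_quad(a1: float, b1: float, a2: float, b2: float) -> float:
    # adaptive Gauss-Kronrod on [0,1]; integrand f_{pi1}(z) F_{pi2}(z)
    pdf1 = stats.beta(a1, b1).pdf
    cdf2 = stats.beta(a2, b2).cdf
    val, _ = integrate.quad(lambda z: pdf1(z) * cdf2(z), 0.0, 1.0, epsabs=1e-8, limit=200)
    return min(max(val, 0.0), 1.0)


def prob_theta_positive(tb: TableBelief) -> float:
    """P(theta = 1 | x) = P(pi1 > pi2) under the current posteriors.

    Uses the exact finite sum when all pseudo-counts are integers, adaptive
    quadrature (absolute tolerance 1e-8) otherwise.
    """
    a1, b1, a2, b2 = tb.counts()
    if all(_is_int(v) for v in (a1, b1, a2, b2)):
        return _p_greater_int(int(a1), int(b1), int(a2), int(b2))
    return _p_greater_quad(a1, b1, a2, b2)


def _binary_entropy(p: float, base: float = math.e) -> float:
    # 0 * log 0 := 0
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * math.log(q)
    return h / math.log(base)


def entropy_theta(tb: TableBelief, base: float = math.e) -> float:
    """Entropy of the posterior over theta; nats by default, bits for base=2."""
    return _binary_entropy(prob_theta_positive(tb), base=base)


@lru_cache(maxsize=None)
def _stats_int(a1: int, b1: int, a2: int, b2: int) -> tuple[float, float, float, float]:
    """(P(theta=1), H, EIG_deck1, EIG_deck2) for integer counts."""
    p = _p_greater_int(a1, b1, a2, b2)
    h = _binary_entropy(p)
    p1 = a1 / (a1 + b1)
    p2 = a2 / (a2 + b2)
    eig1 = h - (
        p1 * _binary_entropy(_p_greater_int(a1 + 1, b1, a2, b2))
        + (1.0 - p1) * _binary_entropy(_p_greater_int(a1, b1 + 1, a2, b2))
    )
    eig2 = h - (
        p2 * _binary_entropy(_p_greater_int(a1, b1, a2 + 1, b2))
        + (1.0 - p2) * _binary_entropy(_p_greater_int(a1, b1, a2, b2 + 1))
    )
    # EIG is non-negative by Jensen (P is a martingale under the predictive,
    # entropy is concave); clip float roundoff
    return p, h, max(eig1, 0.0), max(eig2, 0.0)


def deck_information_gains(tb: TableBelief) -> tuple[float, float]:
    """EIG (nats) of the next card for each deck separately."""
    a1, b1, a2, b2 = tb.counts()
    if all(_is_int(v) for v in (a1, b1, a2, b2)):
        _, _, e1, e2 = _stats_int(int(a1), int(b1), int(a2), int(b2))
        return e1, e2
    h = entropy_theta(tb)
    gains = []
    for deck, belief in ((1, tb.deck1), (2, tb.deck2)):
        p_orange = belief.mean
        h_orange = entropy_theta(tb.with_card(deck, ORANGE))
        h_blue = entropy_theta(tb.with_card(deck, BLUE))
        gains.append(max(h - (p_orange * h_orange + (1.0 - p_orange) * h_blue), 0.0))
    return gains[0], gains[1]


def expected_information_gain(tb: TableBelief, deck_policy: str = "max_over_decks") -> float:
    """Table-level EIG: per-deck EIGs aggregated by ``deck_policy``.

    The table-level quantity requires a convention for which deck the next
    card would come from.  ``max_over_decks`` (default) assumes the agent
    samples the deck it expects to learn most from; ``mean_over_decks``
    averages; ``least_sampled_deck`` takes the EIG of the deck with fewer
    observations (ties broken by the larger EIG).
    """
    e1, e2 = deck_information_gains(tb)
    if deck_policy == "max_over_decks":
        return max(e1, e2)
    if deck_policy == "mean_over_decks":
        return 0.5 * (e1 + e2)
    if deck_policy == "least_sampled_deck":
        n1, n2 = tb.deck1.n_observed, tb.deck2.n_observed
        if n1 < n2:
            return e1
        if n2 < n1:
            return e2
        return max(e1, e2)
    raise ValueError(f"unknown deck_policy {deck_policy!r}; expected one of {DECK_POLICIES}")


def exposure(tb: TableBelief) -> float:
    """Total number of cards observed on the table (n_x)."""
    return tb.deck1.n_observed + tb.deck2.n_observed


def delta_dv(left: TableBelief, right: TableBelief, kind: str,
             deck_policy: str = "max_over_decks") -> float:
    """Right-minus-left difference in the decision variable ``kind``."""
    if kind == "eig":
        return expected_information_gain(right, deck_policy) - expected_information_gain(
            left, deck_policy
        )
    if kind == "uncertainty":
        return entropy_theta(right) - entropy_theta(left)
    if kind == "exposure":
        return exposure(right) - exposure(left)
    raise ValueError(f"unknown decision-variable kind {kind!r}; expected one of {DV_KINDS}")


def overall_uncertainty(left: TableBelief, right: TableBelief) -> float:
    """Sum of the two presented tables' entropies (nats); decision difficulty."""
    return entropy_theta(left) + entropy_theta(right)
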