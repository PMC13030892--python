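"""Task environment: round structure, true proportions, pair presentation, card draws.

The task is a room of four tables, each with two decks of cards whose hidden
sides are one of two colours (a fresh colour pair every round).  The learner's
goal on each table is the sign of the difference in orange-card proportions
between its decks.  Exploration-phase length is a shifted geometric draw, so
the test phase is equally likely to follow any trial after the shift.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TaskConfig",
    "RoundConfig",
    "PresentedPair",
    "DEFAULT_SCHEDULE",
    "SMALL_SCHEDULE",
    "sample_round_length",
    "sample_practice_length",
    "sample_true_proportions",
    "present_pair",
    "draw_card",
    "make_round",
]

#: four sessions: one practice round each, then 3 / 5 / 5 / 5 experimental rounds
DEFAULT_SCHEDULE: tuple[tuple[int, int], ...] = ((1, 3), (1, 5), (1, 5), (1, 5))
#: compact schedule for quick simulations: 6 experimental rounds over two sessions
SMALL_SCHEDULE: tuple[tuple[int, int], ...] = ((1, 3), (1, 3))

#: practice rounds use a short fixed-range length instead of the geometric draw
PRACTICE_LENGTH_RANGE = (12, 19)


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the card task."""

    n_tables: int = 4
    n_decks_per_table: int = 2
    geometric_rate: float = 1.0 / 44.0
    geometric_shift: int = 10
    session_schedule: tuple[tuple[int, int], ...] = DEFAULT_SCHEDULE
    reward_per_correct: float = 0.25
    proportion_grid: tuple[float, ...] = tuple(k / 10.0 for k in range(1, 10))

    def __post_init__(self) -> None:
        if not (0.0 < self.geometric_rate < 1.0):
            raise ValueError(f"geometric_rate must be in (0,1), got {self.geometric_rate}")
        if self.geometric_shift < 0:
            raise ValueError(f"geometric_shift must be >= 0, got {self.geometric_shift}")
        if self.n_tables < 2:
            raise ValueError(f"need at least 2 tables, got {self.n_tables}")
        if not self.proportion_grid:
            raise ValueError("proportion_grid must be nonempty")
        if any(not (0.0 < p < 1.0) for p in self.proportion_grid):
            raise ValueError("all proportions must lie strictly in (0,1)")
        if len(set(self.proportion_grid)) < 2:
            raise ValueError(
                "proportion_grid needs at least two distinct values so that the "
                "two decks of a table can differ"
            )
        object.__setattr__(self, "session_schedule",
                           tuple(tuple(s) for s in self.session_schedule))
        object.__setattr__(self, "proportion_grid", tuple(self.proportion_grid))

    @property
    def n_experimental_rounds(self) -> int:
        return sum(e for _, e in self.session_schedule)

    @property
    def n_practice_rounds(self) -> int:
        return sum(p for p, _ in self.session_schedule)

    @property
    def mean_round_length(self) -> float:
        return self.geometric_shift + 1.0 / self.geometric_rate

    def to_dict(self) -> dict:
        d = asdict(self)
        d["session_schedule"] = [list(s) for s in self.session_schedule]
        d["proportion_grid"] = list(self.proportion_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "session_schedule" in d:
            d["session_schedule"] = tuple(tuple(s) for s in d["session_schedule"])
        if "proportion_grid" in d:
            d["proportion_grid"] = tuple(d["proportion_grid"])
        return cls(**d)


@dataclass(frozen=True)
class RoundConfig:
    """Ground truth for one round."""

    round_id: int
    color_pair: tuple[str, str]
    true_proportions: tuple[tuple[float, float], ...]  # per table (pi1, pi2)
    exploration_length: int
    is_practice: bool = False

    def __post_init__(self) -> None:
        for t, (p1, p2) in enumerate(self.true_proportions):
            if p1 == p2:
                raise ValueError(f"table {t}: pi1 == pi2 leaves theta undefined")
        if self.exploration_length < 1:
            raise ValueError("exploration_length must be >= 1")

    @property
    def theta_true(self) -> tuple[int, ...]:
        """sgn(pi1 - pi2) per table."""
        return tuple(1 if p1 > p2 else -1 for p1, p2 in self.true_proportions)

    @property
    def n_tables(self) -> int:
        return len(self.true_proportions)


@dataclass(frozen=True)
class PresentedPair:
    left_table_id: int
    right_table_id: int

    def __post_init__(self) -> None:
        if self.left_table_id == self.right_table_id:
            raise ValueError("a trial must present two distinct tables")


def sample_round_length(rng: np.random.Generator,
                        rate: float = 1.0 / 44.0,
                        shift: int = 10) -> int:
    """Shifted-geometric exploration length: shift + G, G ~ Geometric(rate) on {1,2,...}.

    The minimum length is ``shift + 1`` and the test phase is equally likely to
    follow any trial after the first ``shift`` (constant hazard ``rate``).
    """
    if not (0.0 < rate < 1.0):
        raise ValueError(f"rate must be in (0,1), got {rate}")
    if shift < 0:
        raise ValueError(f"shift must be >= 0, got {shift}")
    return int(shift + rng.geometric(rate))


def sample_practice_length(rng: np.random.Generator) -> int:
    lo, hi = PRACTICE_LENGTH_RANGE
    return int(rng.integers(lo, hi + 1))


def sample_true_proportions(rng: np.random.Generator,
                            config: TaskConfig) -> tuple[tuple[float, float], ...]:
    """Per-table deck proportions drawn from the grid, resampled on within-table ties."""
    grid = np.asarray(config.proportion_grid)
    out = []
    for _ in range(config.n_tables):
        p1 = float(grid[rng.integers(len(grid))])
        p2 = float(grid[rng.integers(len(grid))])
        while p2 == p1:
            p2 = float(grid[rng.integers(len(grid))])
        out.append((p1, p2))
    return tuple(out)


def present_pair(rng: np.random.Generator, n_tables: int) -> PresentedPair:
    """Uniform unordered pair of distinct tables, sides assigned uniformly."""
    if n_tables < 2:
        raise ValueError(f"need at least 2 tables, got {n_tables}")
    a, b = rng.choice(n_tables, size=2, replace=False)
    return PresentedPair(int(a), int(b))


def draw_card(rng: np.random.Generator, pi: float) -> int:
    """Bernoulli(pi) card colour; orange coded 1, blue 0."""
    if not (0.0 < pi < 1.0):
        raise ValueError(f"pi must be strictly inside (0,1), got {pi}")
    return int(rng.random() < pi)


# fixed palette so colour-pair labels cycle without repeating within a session
_COLOR_NAMES = (
    "orange/blue", "red/green", "purple/yellow", "pink/teal", "brown/cyan",
    "magenta/lime", "navy/gold", "maroon/turquoise", "olive/violet",
    "coral/indigo", "salmon/mint",
)


def make_round(rng: np.random.Generator, config: TaskConfig, round_id: int,
               is_practice: bool = False) -> RoundConfig:
    """Draw a complete round: colour pair, truth per table, exploration length."""
    pair = _COLOR_NAMES[round_id % len(_COLOR_NAMES)].split("/")
    length = (sample_practice_length(rng) if is_practice
              else sample_round_length(rng, config.geometric_rate, config.geometric_shift))
    return RoundConfig(
        round_id=round_id,
        color_pair=(pair[0], pair[1]),
        true_proportions=sample_true_proportions(rng, config),
        exploration_length=length,
        is_practice=is_practice,
    )
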