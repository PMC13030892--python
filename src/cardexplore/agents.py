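"""Strategy-driven agent simulation of the card task.

Agents play the exploration phase with the Bayesian observer's beliefs and
choose between the two presented tables through a logistic choice rule applied
to one of the candidate decision variables (Delta-EIG, Delta-uncertainty or
Delta-exposure, all right-minus-left), plus a side intercept, a repeat-option
bias, an optional overall-uncertainty threshold above which the decision
variable's slope changes (the approach/avoid mechanism), and a lapse mixture.

The generator is the study-conditions mirror of the fitted models: data
simulated from :func:`choice_probability` with known parameters should be
recovered by the inference modules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd

from . import observer as obs
from .task import TaskConfig, RoundConfig, make_round, SMALL_SCHEDULE

__all__ = [
    "STRATEGIES",
    "DEFAULT_SCALING",
    "AgentParams",
    "SimTrial",
    "TestRecord",
    "DatasetSpec",
    "SimDataset",
    "choice_probability",
    "simulate_round",
    "simulate_test_phase",
    "simulate_dataset",
    "homogeneous_population",
    "jittered_population",
    "threshold_population",
    "TRIAL_COLUMNS",
]

STRATEGIES = ("eig", "uncertainty", "exposure", "random")

#: Calibration constants used to z-score the raw decision variables inside the
#: generator: standard deviations of the right-minus-left differences measured
#: once from a large random-exploration simulation at the default task
#: configuration (means are 0 by left/right symmetry).  They are stored in each
#: dataset's metadata so that generation and fitting share the same scale.
DEFAULT_SCALING: dict[str, float] = {
    "eig": 0.0149,
    "uncertainty": 0.2918,
    "exposure": 4.778,
}


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated participant.

    ``beta_dv`` is the slope on the z-scored decision variable of ``strategy``;
    ``tau`` (nats) and ``beta_int`` (slope change per nat above ``tau``) switch
    on the approach/avoid threshold mechanism when both are set.
    ``threshold_form`` selects the hinge (slope varies linearly in U - tau,
    default) or step (constant slope change) variant.
    """

    strategy: str = "uncertainty"
    beta_dv: float = 1.0
    beta_side: float = 0.0
    beta_rep: float = 0.0
    tau: float | None = None
    beta_int: float | None = None
    lapse: float = 0.0
    deck_policy: str = "max_over_decks"
    threshold_form: str = "hinge"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if not (0.0 <= self.lapse <= 1.0):
            raise ValueError(f"lapse must be in [0,1], got {self.lapse}")
        if self.tau is not None and not (0.0 < self.tau <= obs.MAX_OVERALL_UNCERTAINTY):
            raise ValueError(f"tau must be in (0, 2 ln 2], got {self.tau}")
        if self.deck_policy not in obs.DECK_POLICIES:
            raise ValueError(f"unknown deck_policy {self.deck_policy!r}")
        if self.threshold_form not in ("hinge", "step"):
            raise ValueError(f"threshold_form must be 'hinge' or 'step', got {self.threshold_form!r}")
        if self.strategy == "random" and self.beta_dv != 0.0:
            object.__setattr__(self, "beta_dv", 0.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(slots=True)
class SimTrial:
    """One exploration trial; decision variables are the pre-choice values.

    ``delta_eig`` and ``delta_uncertainty`` are right-minus-left (nats).
    ``delta_exposure`` is the observation-count difference in the
    least-exposure orientation (left minus right), so that for every strategy
    a positive value points to the option its heuristic prescribes.
    """

    participant_id: int
    session: int
    round_id: int
    trial_index: int
    left_table: int
    right_table: int
    delta_eig: float
    delta_uncertainty: float
    delta_exposure: float
    overall_uncertainty: float
    repeat_side: int  # +1 right is the repeat option, -1 left, 0 none
    choice_side: int  # 1 = right, 0 = left
    chosen_table: int
    chosen_deck: int  # 1 or 2
    observed_color: int  # 1 = orange, 0 = blue
    is_practice: bool


@dataclass(slots=True)
class TestRecord:
    """One test-phase question (one table at the end of a round)."""

    participant_id: int
    session: int
    round_id: int
    table_id: int
    end_of_round_entropy: float
    p_max: float
    correct: bool
    confidence: int
    unsolvable: bool
    is_practice: bool


TRIAL_COLUMNS = list(SimTrial.__dataclass_fields__)
TEST_COLUMNS = list(TestRecord.__dataclass_fields__)


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def effective_slope(agent: AgentParams, overall_uncertainty: float) -> float:
    """Slope s(U) on the z-scored decision variable, given overall uncertainty U."""
    s = agent.beta_dv
    if agent.tau is not None and agent.beta_int is not None and overall_uncertainty > agent.tau:
        if agent.threshold_form == "hinge":
            s = s + agent.beta_int * (overall_uncertainty - agent.tau)
        else:
            s = s + agent.beta_int
    return s


def choice_probability(agent: AgentParams, delta_dv_scaled: float,
                       overall_uncertainty: float, repeat_side: int) -> float:
    """P(choose right) for one trial.

    logit = beta_side + beta_rep * r + s(U) * delta, mixed with a lapse:
    P = (1 - lapse) * logistic(logit) + lapse * 0.5.
    """
    logit = (agent.beta_side
             + agent.beta_rep * repeat_side
             + effective_slope(agent, overall_uncertainty) * delta_dv_scaled)
    return (1.0 - agent.lapse) * _logistic(logit) + 0.5 * agent.lapse


def _ordered_pairs(n_tables: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n_tables) for j in range(n_tables) if i != j]


def simulate_round(agent: AgentParams, round_config: RoundConfig,
                   beliefs: list[obs.TableBelief], rng: np.random.Generator,
                   scaling: dict[str, float] | None = None,
                   participant_id: int = 0, session: int = 0) -> tuple[list[SimTrial], list[obs.TableBelief]]:
    """Simulate one exploration round; returns the trials and final beliefs.

    Beliefs are the Bayesian observer's: every observed card performs the
    conjugate update on the chosen deck, and all decision variables are
    computed from the belief state *before* the choice.
    """
    if len(beliefs) != round_config.n_tables:
        raise ValueError(
            f"got {len(beliefs)} table beliefs for a round with "
            f"{round_config.n_tables} tables"
        )
    scaling = scaling or DEFAULT_SCALING
    n_tables = round_config.n_tables
    counts = [tuple(int(c) for c in tb.counts()) for tb in beliefs]
    pairs = _ordered_pairs(n_tables)
    L = round_config.exploration_length

    pair_idx = rng.integers(0, len(pairs), size=L)
    u_choice = rng.random(L)
    u_card = rng.random(L)
    u_tie = rng.random(L)

    strategy = agent.strategy
    policy = agent.deck_policy
    s_eig = scaling["eig"]
    s_unc = scaling["uncertainty"]
    s_exp = scaling["exposure"]
    last_chosen = [-1] * n_tables
    stats = obs._stats_int
    trials: list[SimTrial] = []

    for t in range(L):
        lt, rt = pairs[pair_idx[t]]
        cl, cr = counts[lt], counts[rt]
        _, h_l, e1_l, e2_l = stats(*cl)
        _, h_r, e1_r, e2_r = stats(*cr)
        exp_l = cl[0] + cl[1] + cl[2] + cl[3] - 4
        exp_r = cr[0] + cr[1] + cr[2] + cr[3] - 4

        if policy == "mean_over_decks":
            eig_l, eig_r = 0.5 * (e1_l + e2_l), 0.5 * (e1_r + e2_r)
        elif policy == "least_sampled_deck":
            n1l, n2l = cl[0] + cl[1] - 2, cl[2] + cl[3] - 2
            n1r, n2r = cr[0] + cr[1] - 2, cr[2] + cr[3] - 2
            eig_l = e1_l if n1l < n2l else e2_l if n2l < n1l else max(e1_l, e2_l)
            eig_r = e1_r if n1r < n2r else e2_r if n2r < n1r else max(e1_r, e2_r)
        else:
            eig_l, eig_r = max(e1_l, e2_l), max(e1_r, e2_r)

        d_eig = eig_r - eig_l
        d_unc = h_r - h_l
        # least-exposure orientation: positive when the right table has been
        # sampled less, so the exposure heuristic predicts a positive slope,
        # consistent with the other two strategies
        d_exp = float(exp_l - exp_r)
        u_tot = h_l + h_r

        if last_chosen[lt] == last_chosen[rt]:
            r = 0  # neither table chosen yet this round
        elif last_chosen[rt] > last_chosen[lt]:
            r = 1
        else:
            r = -1

        if strategy == "eig":
            dv = d_eig / s_eig
        elif strategy == "uncertainty":
            dv = d_unc / s_unc
        elif strategy == "exposure":
            dv = d_exp / s_exp
        else:
            dv = 0.0

        p_right = choice_probability(agent, dv, u_tot, r)
        go_right = u_choice[t] < p_right
        chosen = rt if go_right else lt
        cc = counts[chosen]

        # deck to flip on the chosen table
        if policy == "least_sampled_deck":
            n1, n2 = cc[0] + cc[1] - 2, cc[2] + cc[3] - 2
            if n1 < n2:
                deck = 1
            elif n2 < n1:
                deck = 2
            else:
                deck = 1 if u_tie[t] < 0.5 else 2
        else:
            e1, e2 = (e1_r, e2_r) if go_right else (e1_l, e2_l)
            if e1 > e2:
                deck = 1
            elif e2 > e1:
                deck = 2
            else:
                deck = 1 if u_tie[t] < 0.5 else 2

        pi = round_config.true_proportions[chosen][deck - 1]
        color = 1 if u_card[t] < pi else 0
        a1, b1, a2, b2 = cc
        if deck == 1:
            counts[chosen] = (a1 + color, b1 + (1 - color), a2, b2)
        else:
            counts[chosen] = (a1, b1, a2 + color, b2 + (1 - color))
        last_chosen[chosen] = t

        trials.append(SimTrial(
            participant_id, session, round_config.round_id, t,
            lt, rt, d_eig, d_unc, d_exp, u_tot, r,
            int(go_right), chosen, deck, color, round_config.is_practice,
        ))

    final = [obs.TableBelief.from_counts(*c) for c in counts]
    return trials, final


DEFAULT_CONFIDENCE_EDGES = (0.6, 0.7, 0.8, 0.9)  # equal-width bins of p_max on [0.5, 1]


def _confidence_bin(p_max: float) -> int:
    conf = 1
    for edge in DEFAULT_CONFIDENCE_EDGES:
        if p_max >= edge:
            conf += 1
    return conf


def simulate_test_phase(beliefs: list[obs.TableBelief], round_config: RoundConfig,
                        rng: np.random.Generator,
                        confidence_map: Callable[[float], int] | None = None,
                        participant_id: int = 0, session: int = 0) -> list[TestRecord]:
    """Simulate the end-of-round test: one deck choice per table.

    The simulated participant answers with the observer's MAP value of theta
    with probability equal to the posterior maximum (probability matching), so
    accuracy is at chance when the posterior is flat and approaches 1 as the
    posterior concentrates on the truth.  Confidence is a monotone bin of the
    posterior maximum into 1..5.
    """
    confidence_map = confidence_map or _confidence_bin
    records = []
    for table_id, tb in enumerate(beliefs):
        p = obs.prob_theta_positive(tb)
        h = obs._binary_entropy(p)
        p_max = max(p, 1.0 - p)
        map_theta = 1 if p > 0.5 else -1 if p < 0.5 else (1 if rng.random() < 0.5 else -1)
        answer = map_theta if rng.random() < p_max else -map_theta
        unsolvable = tb.deck1.n_observed == 0 or tb.deck2.n_observed == 0
        records.append(TestRecord(
            participant_id, session, round_config.round_id, table_id,
            h, p_max, answer == round_config.theta_true[table_id],
            int(confidence_map(p_max)), bool(unsolvable), round_config.is_practice,
        ))
    return records


Population = Union[AgentParams, Callable[[np.random.Generator, int], AgentParams]]


def homogeneous_population(params: AgentParams) -> Population:
    """All participants share the same generative parameters."""
    return params


def jittered_population(base: AgentParams, sd: dict[str, float]) -> Population:
    """Independent Gaussian jitter on the named numeric fields of ``base``."""

    def draw(rng: np.random.Generator, i: int) -> AgentParams:
        changes = {k: getattr(base, k) + rng.normal(0.0, s) for k, s in sd.items()}
        if "lapse" in changes:
            changes["lapse"] = float(np.clip(changes["lapse"], 0.0, 1.0))
        if "tau" in changes:
            changes["tau"] = float(np.clip(changes["tau"], 1e-6, obs.MAX_OVERALL_UNCERTAINTY))
        return replace(base, **changes)

    return draw


def threshold_population(beta_low_mean: float = 1.0, beta_low_sd: float = 0.3,
                         beta_int_mean: float = -5.0, beta_int_sd: float = 2.0,
                         rho: float = 0.0, tau_mean: float = 1.0, tau_sd: float = 0.0,
                         base: AgentParams | None = None) -> Population:
    """Uncertainty-strategy population with a threshold mechanism.

    Draws (beta_dv, |beta_int|) from a bivariate normal with correlation
    ``rho`` — positive rho plants the approach/avoid coupling in which stronger
    uncertainty-approachers also avoid more above threshold.  beta_int is
    truncated to be <= 0 (avoidance) and beta_dv to be >= 0.
    """
    base = base or AgentParams(strategy="uncertainty")
    mag_mean = abs(beta_int_mean)
    cov = np.array([
        [beta_low_sd ** 2, rho * beta_low_sd * beta_int_sd],
        [rho * beta_low_sd * beta_int_sd, beta_int_sd ** 2],
    ])

    def draw(rng: np.random.Generator, i: int) -> AgentParams:
        lo, mag = rng.multivariate_normal([beta_low_mean, mag_mean], cov)
        tau = tau_mean if tau_sd == 0 else rng.normal(tau_mean, tau_sd)
        tau = float(np.clip(tau, 0.3, obs.MAX_OVERALL_UNCERTAINTY))
        return replace(base, strategy="uncertainty",
                       beta_dv=max(lo, 0.0), beta_int=-max(mag, 0.0), tau=tau)

    return draw


@dataclass
class DatasetSpec:
    """What to simulate: task structure, population, scale, scaling constants."""

    task: TaskConfig = field(default_factory=lambda: TaskConfig(session_schedule=SMALL_SCHEDULE))
    n_participants: int = 30
    population: Population = field(default_factory=AgentParams)
    scaling: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCALING))
    name: str = "sim"

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        missing = set(obs.DV_KINDS) - set(self.scaling)
        if missing:
            raise ValueError(f"scaling constants missing for {sorted(missing)}")


@dataclass
class SimDataset:
    """Tidy simulated dataset: exploration trials, test records, ground truth."""

    trials: pd.DataFrame
    tests: pd.DataFrame
    agents: pd.DataFrame  # one row per participant: the true generative parameters
    scaling: dict[str, float]
    meta: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.tests.to_csv(outdir / "tests.csv", index=False)
        self.agents.to_csv(outdir / "agents.csv", index=False)
        with open(outdir / "meta.json", "w") as fh:
            json.dump({"scaling": self.scaling, **self.meta}, fh, indent=2)

    @classmethod
    def read(cls, outdir: str | Path) -> "SimDataset":
        outdir = Path(outdir)
        with open(outdir / "meta.json") as fh:
            meta = json.load(fh)
        scaling = meta.pop("scaling")
        return cls(
            trials=pd.read_csv(outdir / "trials.csv"),
            tests=pd.read_csv(outdir / "tests.csv"),
            agents=pd.read_csv(outdir / "agents.csv"),
            scaling=scaling,
            meta=meta,
        )


def simulate_dataset(spec: DatasetSpec, rng: np.random.Generator) -> SimDataset:
    """Simulate a complete dataset: all participants, sessions, rounds and tests."""
    all_trials: list[SimTrial] = []
    all_tests: list[TestRecord] = []
    agent_rows = []
    population = spec.population

    for p in range(spec.n_participants):
        agent = population if isinstance(population, AgentParams) else population(rng, p)
        agent_rows.append({"participant_id": p, **agent.to_dict()})
        round_id = 0
        for session, (n_practice, n_exp) in enumerate(spec.task.session_schedule):
            for k in range(n_practice + n_exp):
                is_practice = k < n_practice
                rc = make_round(rng, spec.task, round_id, is_practice=is_practice)
                beliefs = [obs.TableBelief.fresh() for _ in range(spec.task.n_tables)]
                trials, beliefs = simulate_round(
                    agent, rc, beliefs, rng, spec.scaling,
                    participant_id=p, session=session,
                )
                all_trials.extend(trials)
                all_tests.extend(simulate_test_phase(
                    beliefs, rc, rng, participant_id=p, session=session,
                ))
                round_id += 1

    trials_df = pd.DataFrame([
        {fname: getattr(t, fname) for fname in SimTrial.__dataclass_fields__}
        for t in all_trials
    ])
    tests_df = pd.DataFrame([
        {fname: getattr(t, fname) for fname in TestRecord.__dataclass_fields__}
        for t in all_tests
    ])
    return SimDataset(
        trials=trials_df,
        tests=tests_df,
        agents=pd.DataFrame(agent_rows),
        scaling=dict(spec.scaling),
        meta={"name": spec.name,
              "n_participants": spec.n_participants,
              "task": spec.task.to_dict()},
    )
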