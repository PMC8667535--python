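"""SEIRD dynamics on the contact network and epidemic time-series summaries.

Compartments: susceptible (S), exposed (E), infected (I), recovered (R),
dead (D).  Per epoch a susceptible with k infected contacts becomes
exposed with probability 1 - (1 - beta)^k (a per-contact Bernoulli hazard
with parameter beta); an exposed becomes infected with probability sigma;
an infected exits with probability gamma, dying with case-fatality
fraction alpha and recovering otherwise, i.e. I -> R with gamma*(1-alpha)
and I -> D with gamma*alpha.  R and D are absorbing.

The rate of contagion is tracked by the infection growth rate
G_t = (I_t - I_{t-1}) / I_{t-1} and the effective reproduction number
R_t = 1 + G_t / gamma, optionally smoothed with a Savitzky-Golay filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .contact_network import ContactNetwork
from .population import EpidemicState, Population, STATE_CODES

__all__ = [
    "SEIRDParams",
    "EpochRecord",
    "seird_step",
    "growth_rate",
    "effective_reproduction_number",
    "smooth_series",
]

_S, _E, _I, _R, _D = (STATE_CODES[s] for s in EpidemicState)


@dataclass(frozen=True)
class SEIRDParams:
    """Per-epoch transition probabilities of the SEIRD model.

    Defaults follow common COVID-19 parameterizations: sigma=0.25,
    gamma=0.1, alpha=0.05, beta=0.55.  The basic reproduction number
    obeys beta = gamma * R0 (so the defaults give R0 = 5.5, inside the
    nominal 3-6 range).
    """

    beta: float = 0.55
    sigma: float = 0.25
    gamma: float = 0.1
    alpha: float = 0.05
    exposed_infective: bool = False  # if True, E nodes also transmit

    def __post_init__(self) -> None:
        for name in ("beta", "sigma", "gamma", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def R0(self) -> float:
        """Basic reproduction number, beta / gamma."""
        if self.gamma == 0:
            return math.inf
        return self.beta / self.gamma


@dataclass
class EpochRecord:
    """Per-epoch bookkeeping: compartment counts and contagion measures.

    ``cumulative_count`` is I + R + D, the headline measure of contagion
    progress; ``score`` is the relocation objective value after the
    strategy ran; ``growth_rate`` and ``effective_R`` are None when the
    previous infected count was zero (undefined growth).
    """

    t: int
    counts: tuple[int, int, int, int, int]  # (S, E, I, R, D)
    cumulative_count: int = 0
    score: float | None = None
    growth_rate: float | None = None
    effective_R: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s, e, i, r, d = self.counts
        self.cumulative_count = i + r + d


def seird_step(
    population: Population,
    network: ContactNetwork,
    params: SEIRDParams,
    rng: np.random.Generator,
) -> tuple[Population, dict[str, int]]:
    """Advance every individual one epoch, simultaneously.

    Transitions are computed on a snapshot of the current states and then
    applied at once, so ordering within the epoch cannot matter.  A single
    uniform draw per individual decides its transition, which keeps runs
    bit-reproducible under a fixed seed.

    Returns the (mutated) population and the transition counts
    ``{"S->E": ..., "E->I": ..., "I->R": ..., "I->D": ...}``.
    """
    states = population.states_array()
    n = len(states)
    u = rng.uniform(size=n)
    index_of = {ind.id: i for i, ind in enumerate(population.individuals)}

    infective = {_I, _E} if params.exposed_infective else {_I}
    new_states = states.copy()
    counts = {"S->E": 0, "E->I": 0, "I->R": 0, "I->D": 0}

    for idx, ind in enumerate(population.individuals):
        st = states[idx]
        if st == _S:
            k = sum(
                1
                for v in network.graph.neighbors(ind.id)
                if states[index_of[v]] in infective
            )
            if k and u[idx] < 1.0 - (1.0 - params.beta) ** k:
                new_states[idx] = _E
                counts["S->E"] += 1
        elif st == _E:
            if u[idx] < params.sigma:
                new_states[idx] = _I
                counts["E->I"] += 1
        elif st == _I:
            # one uniform decides exit and destination jointly
            if u[idx] < params.gamma * params.alpha:
                new_states[idx] = _D
                counts["I->D"] += 1
            elif u[idx] < params.gamma:
                new_states[idx] = _R
                counts["I->R"] += 1
        # R and D are absorbing

    code_to_state = list(EpidemicState)
    for idx, ind in enumerate(population.individuals):
        ind.state = code_to_state[new_states[idx]]
    return population, counts


def growth_rate(I_prev: int, I_curr: int) -> float | None:
    """G_t = (I_t - I_{t-1}) / I_{t-1}; None (missing) when I_{t-1} = 0."""
    if I_prev == 0:
        return None
    return (I_curr - I_prev) / I_prev


def effective_reproduction_number(G_t: float, gamma: float) -> float:
    """R_t = 1 + G_t / gamma — secondary cases per infected at time t."""
    if gamma <= 0:
        raise ValueError("gamma must be positive to compute R_t")
    return 1.0 + G_t / gamma


def smooth_series(series, window: int = 9, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing (same length out)."""
    series = np.asarray(series, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if series.size < window:
        raise ValueError("series shorter than the smoothing window")
    return savgol_filter(series, window_length=window, polyorder=polyorder)
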