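"""Threshold-linear rate model of the opponent gate ("toggle switch") motif.

The circuit: a state node S excites gate I1 directly and suppresses gate I2
through an inhibitory intermediate X; each gate inhibits the *output* of one
of two parallel visual channels (I1 gates C2, I2 gates C1); each channel
feeds back excitation onto the gate that protects it (C1 -> I1, C2 -> I2).

Because the gates synapse among the channels' axonal output synapses, their
inhibition is modeled as divisive gain on the channel's transmitted output,

    o_j = r_j / (1 + sum_k Gamma_kj * r_k),

rather than subtraction at the channel's input. All other connections are
conventional rectified-linear rate dynamics,

    tau_i dr_i/dt = -r_i + [ sum_j W_ij o_j + drive_i(t) ]_+ .

The model is qualitative: with the state drive on, I1 activates and I2 is
released from tonic drive, so channel 1 transmits and channel 2 is gated
off; with the state off the mirror image holds. Crossed feedback deepens
the separation (winner-take-all).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .motifs import DisinhibitionChain, ToggleSwitch

Drive = float | Callable[[float], float]

#: canonical node order of the toggle model
TOGGLE_ROLES = ("state", "gate_1", "gate_2", "intermediate", "channel_1", "channel_2")


@dataclass
class RateModel:
    """A named-node threshold-linear network with output-gain gating.

    ``weights[i, j]`` is the connection from node j onto node i acting on
    node j's (possibly gated) output; ``gating[k, j] > 0`` means node k
    divisively suppresses node j's output. ``tonic`` holds constant
    background drive per node (the disynaptically-inhibited gate needs a
    tonic source to be active when the state is silent).
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    gating: np.ndarray
    tau: np.ndarray
    tonic: np.ndarray
    roles: dict[str, str] = field(default_factory=dict)
    channel_nodes: tuple[str, ...] = ()
    state_node: str = "state"

    def __post_init__(self) -> None:
        n = len(self.nodes)
        for name, m in (("weights", self.weights), ("gating", self.gating)):
            if np.shape(m) != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
        if (self.gating < 0).any():
            raise ValueError("gating strengths must be non-negative")

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    def outputs(self, rates: np.ndarray) -> np.ndarray:
        """Gated outputs o = r / (1 + Gamma^T r)."""
        suppression = self.gating.T @ rates
        return rates / (1.0 + suppression)


@dataclass
class SimulationResult:
    """Traces and steady-state summary of one integration run."""

    model: RateModel
    t: np.ndarray
    rates: np.ndarray          # time x node
    steady_rates: dict[str, float]
    steady_outputs: dict[str, float]
    converged: bool

    def trace(self, node: str) -> np.ndarray:
        return self.rates[:, self.model.index(node)]


# ---------------------------------------------------------------------------
# construction


#: default dynamical parameters; chosen by a coarse grid search over the
#: region where all qualitative switch outcomes hold (see default_parameter_grid)
DEFAULT_PARAMS: dict[str, float] = {
    "w_state_gate": 1.5,    # S -> I1 and S -> X excitation
    "w_x_gate": 2.0,        # X -| I2 inhibition
    "w_feedback": 0.8,      # C -> its gate excitation
    "gamma": 2.0,           # divisive gating strength gate -> channel output
    "tonic_gate_2": 0.6,    # tonic drive keeping I2 active at state-off
    "tau_ms": 10.0,
}


def build_rate_model(motif: ToggleSwitch | DisinhibitionChain,
                     params: Mapping[str, float] | None = None) -> RateModel:
    """Build a rate model from a detected motif.

    Connection magnitudes are proportional to synapse counts, normalized by
    the largest count in the motif so absolute scale cancels (doubling every
    count leaves the weights unchanged); signs follow the motif's resolved
    signs. Gate-onto-channel links become divisive output gating.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    if isinstance(motif, ToggleSwitch):
        return _build_toggle(motif, p)
    if isinstance(motif, DisinhibitionChain):
        return _build_chain(motif, p)
    raise TypeError(f"cannot build a rate model from {type(motif).__name__}")


def _build_toggle(motif: ToggleSwitch, p: Mapping[str, float]) -> RateModel:
    nodes = TOGGLE_ROLES
    n = len(nodes)
    ix = {r: i for i, r in enumerate(nodes)}
    counts = {
        ("gate_1", "state"): motif.drive_syn_direct,
        ("intermediate", "state"): motif.drive_syn_disynaptic[0],
        ("gate_2", "intermediate"): motif.drive_syn_disynaptic[1],
        ("gate_1", "channel_1"): motif.feedback_syn_1,
        ("gate_2", "channel_2"): motif.feedback_syn_2,
    }
    scale = max(counts.values())
    if scale <= 0:
        raise ValueError("motif has no synapses to scale weights by")
    W = np.zeros((n, n))
    W[ix["gate_1"], ix["state"]] = p["w_state_gate"] * counts[("gate_1", "state")] / scale
    W[ix["intermediate"], ix["state"]] = \
        p["w_state_gate"] * counts[("intermediate", "state")] / scale
    W[ix["gate_2"], ix["intermediate"]] = \
        -p["w_x_gate"] * counts[("gate_2", "intermediate")] / scale
    W[ix["gate_1"], ix["channel_1"]] = \
        p["w_feedback"] * counts[("gate_1", "channel_1")] / scale
    W[ix["gate_2"], ix["channel_2"]] = \
        p["w_feedback"] * counts[("gate_2", "channel_2")] / scale
    G = np.zeros((n, n))
    gate_total_1 = motif.selectivity_1  # share of gate_1's group output on channel_2
    gate_total_2 = motif.selectivity_2
    G[ix["gate_1"], ix["channel_2"]] = p["gamma"] * gate_total_1
    G[ix["gate_1"], ix["channel_1"]] = p["gamma"] * (1.0 - gate_total_1)
    G[ix["gate_2"], ix["channel_1"]] = p["gamma"] * gate_total_2
    G[ix["gate_2"], ix["channel_2"]] = p["gamma"] * (1.0 - gate_total_2)
    tonic = np.zeros(n)
    tonic[ix["gate_2"]] = p["tonic_gate_2"]
    tau = np.full(n, p["tau_ms"] / 1000.0)
    roles = {motif.state: "state", motif.gate_1: "gate_1", motif.gate_2: "gate_2",
             motif.intermediate: "intermediate",
             motif.channel_1: "channel_1", motif.channel_2: "channel_2"}
    return RateModel(nodes=nodes, weights=W, gating=G, tau=tau, tonic=tonic,
                     roles=roles, channel_nodes=("channel_1", "channel_2"))


def _build_chain(motif: DisinhibitionChain, p: Mapping[str, float]) -> RateModel:
    nodes = ("state", "inhibitor_1", "inhibitor_2", "sensory")
    n = len(nodes)
    scale = max(motif.link_synapses)
    if scale <= 0:
        raise ValueError("motif has no synapses to scale weights by")
    W = np.zeros((n, n))
    W[1, 0] = p["w_state_gate"] * motif.link_synapses[0] / scale
    W[2, 1] = -p["w_x_gate"] * motif.link_synapses[1] / scale
    W[3, 2] = -p["w_x_gate"] * motif.link_synapses[2] / scale
    tonic = np.zeros(n)
    tonic[2] = p["tonic_gate_2"]  # the LC-dendrite inhibitor is tonically on
    tau = np.full(n, p["tau_ms"] / 1000.0)
    roles = dict(zip(motif.nodes, nodes))
    return RateModel(nodes=nodes, weights=W, gating=np.zeros((n, n)), tau=tau,
                     tonic=tonic, roles=roles, channel_nodes=("sensory",))


# ---------------------------------------------------------------------------
# integration


def _as_fn(drive: Drive) -> Callable[[float], float]:
    if callable(drive):
        return drive
    return lambda _t, v=float(drive): v


def simulate(model: RateModel, state_drive: Drive, visual_drive: Drive | Mapping[str, Drive],
             T: float = 1.0, dt: float = 5e-4, seed: int | None = None,
             noise_sd: float = 0.0, rate_cap: float = 1e6,
             clamp: Mapping[str, float] | None = None,
             steady_tol: float = 1e-7) -> SimulationResult:
    """Forward-Euler integration with rectification.

    ``state_drive`` feeds the state node; ``visual_drive`` feeds the channel
    nodes (a single value for all channels, or a per-node mapping). Optional
    white noise (default off) is reproducible given ``seed``. ``clamp`` pins
    named nodes to fixed rates. Raises on divergence past ``rate_cap``.
    """
    if dt >= model.tau.min() / 10.0:
        raise ValueError(f"dt={dt} too coarse for tau_min={model.tau.min()}")
    n = len(model.nodes)
    n_steps = int(round(T / dt))
    sfun = _as_fn(state_drive)
    if isinstance(visual_drive, Mapping):
        vfuns = {node: _as_fn(v) for node, v in visual_drive.items()}
    else:
        vfuns = {node: _as_fn(visual_drive) for node in model.channel_nodes}
    rng = np.random.default_rng(seed)
    clamp_ix = {model.index(k): float(v) for k, v in (clamp or {}).items()}

    rates = np.zeros((n_steps + 1, n))
    for k, v in clamp_ix.items():
        rates[0, k] = v
    t = np.arange(n_steps + 1) * dt
    s_ix = model.index(model.state_node)
    max_step = 0.0
    for i in range(n_steps):
        r = rates[i]
        o = model.outputs(r)
        drive = model.tonic.copy()
        drive[s_ix] += sfun(t[i])
        for node, fn in vfuns.items():
            drive[model.index(node)] += fn(t[i])
        inp = model.weights @ o + drive
        if noise_sd > 0:
            inp = inp + rng.normal(0.0, noise_sd, size=n)
        dr = (-r + np.maximum(inp, 0.0)) / model.tau * dt
        nxt = np.maximum(r + dr, 0.0)
        for k, v in clamp_ix.items():
            nxt[k] = v
        if not np.isfinite(nxt).all() or (nxt > rate_cap).any():
            raise RuntimeError(
                f"rate divergence at t={t[i]:.4f} (cap {rate_cap}); "
                f"weights max {np.abs(model.weights).max():.3g}, dt={dt}")
        max_step = float(np.abs(nxt - r).max())
        rates[i + 1] = nxt
    steady = rates[-1]
    out = model.outputs(steady)
    converged = noise_sd > 0 or max_step / dt < steady_tol * max(1.0, steady.max()) \
        or max_step < steady_tol
    return SimulationResult(
        model=model, t=t, rates=rates,
        steady_rates={nd: float(steady[j]) for j, nd in enumerate(model.nodes)},
        steady_outputs={nd: float(out[j]) for j, nd in enumerate(model.nodes)},
        converged=bool(converged))


def transmission_gains(model: RateModel, state_level: float,
                       visual_level: float = 1.0, delta: float = 0.05,
                       T: float = 1.0, dt: float = 5e-4,
                       clamp: Mapping[str, float] | None = None,
                       ) -> dict[str, float]:
    """Steady-state channel output per unit visual drive, per channel.

    Computed by a small-perturbation difference: each channel's visual drive
    is nudged by ``delta`` and the change in that channel's *gated output*
    divided by ``delta`` is its transmission gain at this state level.
    """
    base = simulate(model, state_level, visual_level, T=T, dt=dt, clamp=clamp)
    if not base.converged:
        raise RuntimeError("baseline simulation did not reach steady state")
    gains: dict[str, float] = {}
    for ch in model.channel_nodes:
        drives = {c: visual_level + (delta if c == ch else 0.0)
                  for c in model.channel_nodes}
        pert = simulate(model, state_level, drives, T=T, dt=dt, clamp=clamp)
        if not pert.converged:
            raise RuntimeError(f"perturbed simulation ({ch}) did not converge")
        gains[ch] = (pert.steady_outputs[ch] - base.steady_outputs[ch]) / delta
    return gains


def perturb(model: RateModel, node: str, mode: str,
            state_drive: Drive = 0.0, visual_drive: Drive = 1.0,
            high_rate: float = 3.0, T: float = 1.0, dt: float = 5e-4,
            ) -> SimulationResult:
    """Simulate with one node clamped (optogenetic-style perturbation).

    ``mode`` is ``"clamp_high"`` (tonic activation at ``high_rate``) or
    ``"clamp_zero"`` (silencing); the rest of the network integrates freely.
    """
    if node not in model.nodes:
        raise KeyError(f"unknown node {node!r}")
    if mode == "clamp_high":
        value = high_rate
    elif mode == "clamp_zero":
        value = 0.0
    else:
        raise ValueError(f"mode must be clamp_high or clamp_zero, got {mode!r}")
    return simulate(model, state_drive, visual_drive, T=T, dt=dt,
                    clamp={node: value})


# ---------------------------------------------------------------------------
# parameter grid


def default_parameter_grid() -> list[dict[str, float]]:
    """The shipped parameter grid over which the qualitative switch outcomes
    are asserted (state on -> channel 1 transmits / channel 2 gated; state
    off -> mirrored; perturbation directions)."""
    grid = []
    for w_sg, gamma, fb, tonic in itertools.product(
            (1.0, 1.5), (1.5, 2.0, 3.0), (0.5, 0.8), (0.5, 0.8)):
        grid.append({"w_state_gate": w_sg, "w_x_gate": 2.0, "w_feedback": fb,
                     "gamma": gamma, "tonic_gate_2": tonic, "tau_ms": 10.0})
    return grid


def remove_feedback(model: RateModel) -> RateModel:
    """Copy of the model with the crossed channel->gate feedback removed."""
    W = model.weights.copy()
    for gate, ch in (("gate_1", "channel_1"), ("gate_2", "channel_2")):
        if gate in model.nodes and ch in model.nodes:
            W[model.index(gate), model.index(ch)] = 0.0
    return replace(model, weights=W)
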