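"""Synthetic inputs with known ground truth.

Four generators, all bit-reproducible given (config, seed):

* :func:`generate_connectome` — a random background connectome with the
  state/visual circuit planted at configurable connection fractions, plus
  the exhaustive list of motifs the planting implies;
* :func:`generate_trajectories` — scripted multi-fly arena trajectories
  with known approach/aggression epochs and the matching ethogram;
* :func:`generate_fictive_target` — the oscillating fictive-conspecific
  stimulus (107° arc at ~75°/s, sizes 8–50° averaging 22.5°);
* :func:`generate_fluorescence` — noisy step-response fluorescence traces.

The planted circuit mirrors the female-aggression architecture: a state
type (aIPg-like) converging with a six-member visual channel group
(LC10a–f-like) onto downstream integrator types, a two-step dendritic
disinhibition chain through a centrifugal neuron (IB112-like) and a lobula
interneuron (Li22-like), and an opponent TuTuA-like gate pair with crossed
channel feedback. All planted counts are integers realized exactly against
the configured fraction targets (largest-remainder rounding for pies), so
an analyzer recovers the configured fractions to within integer rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .behavior import Ethogram
from .connectome import ConnectivityTable, UNTYPED
from .geometry import TrajectorySet


# ---------------------------------------------------------------------------
# planted connectome


@dataclass(frozen=True)
class ConnectomeConfig:
    """Parameters of the synthetic connectome.

    Fraction targets default to the printed connectivity of the real
    circuit (4.3% state->centrifugal input, 5.7% centrifugal->lobula
    interneuron, per-channel dendritic fractions, 98% gate selectivity).
    Background edges run only among background types, so planted fractions
    are exact by construction.
    """

    n_background_types: int = 15
    background_cells_per_type: int = 2
    background_edge_prob: float = 0.08
    background_lognormal_mu: float = 2.0
    background_lognormal_sigma: float = 1.0

    # channel group (sensory types)
    n_channels: int = 6
    channel_input_total: int = 20000
    channel_cells_per_type: int = 5

    # convergence planting
    n_convergence_targets: int = 3
    conv_input_total: int = 3000
    conv_syn_from_state: int = 150
    conv_syn_from_group: int = 900
    conv_pie: tuple[float, ...] = (0.35, 0.10, 0.25, 0.10, 0.10, 0.10)

    # disinhibition planting
    disinhibitor_input_total: int = 7000       # IB112-like
    state_to_disinhibitor_frac: float = 0.043
    li_input_total: int = 7000                 # Li22-like
    disinhibitor_to_li_frac: float = 0.057
    disinhibitor_out_lobula_other: int = 350
    disinhibitor_out_central: int = 80
    li_to_channel_fracs: tuple[float, ...] = (0.035, 0.011, 0.051, 0.059, 0.0, 0.0)

    # toggle planting
    gate_input_total: int = 2000
    gate_selectivity: float = 0.98
    gate_group_output: int = 1000              # gate synapses onto the channel group
    feedback_syn: int = 600
    state_to_gate1_syn: int = 300
    state_to_intermediate_syn: int = 250
    intermediate_input_total: int = 2000
    intermediate_to_gate2_syn: int = 400

    n_untyped_inputs_per_node: int = 30        # exercises the denominator rule


ROLE_NT = {
    "state": "ACh", "gate_1": "Glu", "gate_2": "Glu", "intermediate": "GABA",
    "disinhibitor": "Glu", "li": "Glu", "channel": "ACh", "conv": "ACh",
    "feeder": "ACh",
}

#: default thresholds under which the ground-truth motif lists are stated
GT_THRESHOLDS = {
    "min_syn_state": 100, "min_syn_sensory": 100,
    "min_frac_sensory": 0.25, "min_frac_state": 0.02,
    "chain_fracs": (0.02, 0.05, 0.01),
    "min_selectivity": 0.9,
}


@dataclass
class PlantedGroundTruth:
    """Every motif implied by the planted counts, derived by direct
    arithmetic over the planted link table (independent of the detectors)."""

    convergence_targets: list[dict]
    chains: list[tuple[str, str, str, str]]
    toggles: list[dict]
    link_counts: dict[tuple[str, str], int]
    input_totals: dict[str, int]
    thresholds: dict = field(default_factory=lambda: dict(GT_THRESHOLDS))


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer counts summing to ``total`` proportional to ``fractions``."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_connectome(config: ConnectomeConfig | None = None, seed: int = 0,
                        ) -> tuple[ConnectivityTable, PlantedGroundTruth]:
    """Random background connectome plus the planted circuit.

    Returns the connectivity table and the ground truth listing every
    planted motif with its parameters. Deterministic given (config, seed);
    two seeds give different background edge sets but identical planted
    ground truth.
    """
    cfg = config or ConnectomeConfig()
    rng = np.random.default_rng(seed)
    channels = [f"LC10{chr(ord('a') + i)}" for i in range(cfg.n_channels)]
    conv_targets = [f"AOTU{900 + i}" for i in range(cfg.n_convergence_targets)]
    feeders = ["Tm901", "Tm902", "Tm903"]

    types: dict[str, dict] = {}

    def add_type(name, nt, n_cells, hemisphere="right"):
        types[name] = {"nt": nt, "n_cells": n_cells, "hemisphere": hemisphere}

    add_type("aIPg", ROLE_NT["state"], 10)
    add_type("TuTuA_1", ROLE_NT["gate_1"], 1)
    add_type("TuTuA_2", ROLE_NT["gate_2"], 1)
    add_type("SMP054", ROLE_NT["intermediate"], 2)
    add_type("IB112", ROLE_NT["disinhibitor"], 2)
    add_type("Li22", ROLE_NT["li"], 4)
    for c in channels:
        add_type(c, ROLE_NT["channel"], cfg.channel_cells_per_type)
    for t in conv_targets:
        add_type(t, ROLE_NT["conv"], 2)
    for f in feeders:
        add_type(f, ROLE_NT["feeder"], 3)
    bg_types = [f"BG{i:03d}" for i in range(cfg.n_background_types)]
    nts = ["ACh", "GABA", "Glu"]
    for b in bg_types:
        add_type(b, nts[rng.integers(0, 3)], cfg.background_cells_per_type)

    # ---- planted type-to-type links: (pre, post) -> (count, roi) ----
    links: dict[tuple[str, str], tuple[int, str]] = {}

    def plant(pre, post, count, roi):
        if count <= 0:
            return
        key = (pre, post)
        if key in links:
            prev, r = links[key]
            links[key] = (prev + count, r)
        else:
            links[key] = (int(count), roi)

    input_budget: dict[str, int] = {}   # filler needed to hit input totals

    def claim(post, total, *contributions):
        used = sum(contributions)
        if used > total:
            raise ValueError(
                f"infeasible fraction targets for {post}: planted {used} "
                f"exceeds input total {total}")
        input_budget[post] = total - used

    # convergence targets: state + channel-group input on a fixed denominator
    pie = _largest_remainder(cfg.conv_syn_from_group, np.array(cfg.conv_pie))
    for t in conv_targets:
        plant("aIPg", t, cfg.conv_syn_from_state, "AOTU")
        for c, n in zip(channels, pie):
            plant(c, t, int(n), "AOTU")
        claim(t, cfg.conv_input_total, cfg.conv_syn_from_state,
              int(pie.sum()))

    # disinhibition chain: state -> IB112 -> Li22 -> channel dendrites
    n_sd = int(round(cfg.state_to_disinhibitor_frac * cfg.disinhibitor_input_total))
    plant("aIPg", "IB112", n_sd, "CB")
    claim("IB112", cfg.disinhibitor_input_total, n_sd)
    n_dl = int(round(cfg.disinhibitor_to_li_frac * cfg.li_input_total))
    plant("IB112", "Li22", n_dl, "LO")
    claim("Li22", cfg.li_input_total, n_dl)
    # spread the rest of IB112's lobula output thinly over feeder types
    spread = _largest_remainder(cfg.disinhibitor_out_lobula_other,
                                np.full(len(feeders), 1 / len(feeders)))
    for f, n in zip(feeders, spread):
        plant("IB112", f, int(n), "LO")
    central_sink = bg_types[0] if bg_types else feeders[0]
    plant("IB112", central_sink, cfg.disinhibitor_out_central, "CB")

    li_to_ch = [int(round(f * cfg.channel_input_total))
                for f in cfg.li_to_channel_fracs[:cfg.n_channels]]

    # toggle: gates, intermediate, feedback
    n_on = int(round(cfg.gate_selectivity * cfg.gate_group_output))
    n_off = cfg.gate_group_output - n_on
    plant("TuTuA_1", channels[2], n_on, "AOTU")    # LC10c-like
    plant("TuTuA_1", channels[0], n_off, "AOTU")
    plant("TuTuA_2", channels[0], n_on, "AOTU")    # LC10a-like
    plant("TuTuA_2", channels[2], n_off, "AOTU")
    plant(channels[0], "TuTuA_1", cfg.feedback_syn, "AOTU")
    plant(channels[2], "TuTuA_2", cfg.feedback_syn, "AOTU")
    plant("aIPg", "TuTuA_1", cfg.state_to_gate1_syn, "CB")
    plant("aIPg", "SMP054", cfg.state_to_intermediate_syn, "CB")
    plant("SMP054", "TuTuA_2", cfg.intermediate_to_gate2_syn, "CB")
    claim("TuTuA_1", cfg.gate_input_total,
          cfg.state_to_gate1_syn, cfg.feedback_syn)
    claim("TuTuA_2", cfg.gate_input_total,
          cfg.intermediate_to_gate2_syn, cfg.feedback_syn)
    claim("SMP054", cfg.intermediate_input_total, cfg.state_to_intermediate_syn)

    # channel dendritic inputs: interneuron + gate + feeder filler in LO
    gate_onto = {channels[0]: n_on + n_off, channels[2]: n_on + n_off}
    for i, c in enumerate(channels):
        plant("Li22", c, li_to_ch[i], "LO")
        claim(c, cfg.channel_input_total, li_to_ch[i], gate_onto.get(c, 0))

    # feeder filler to make every denominator exact
    for post, remaining in input_budget.items():
        if remaining <= 0:
            continue
        roi = "LO" if post in channels or post in ("Li22", *feeders) else "CB"
        per = _largest_remainder(remaining, np.full(len(feeders), 1 / len(feeders)))
        for f, n in zip(feeders, per):
            plant(f, post, int(n), roi)

    # ---- realize neurons and split type links over member pairs ----
    neurons = []
    body = 10_000
    members: dict[str, list[int]] = {}
    for name, meta in types.items():
        ids = list(range(body, body + meta["n_cells"]))
        body += meta["n_cells"]
        members[name] = ids
        for b in ids:
            neurons.append((b, name, meta["hemisphere"], meta["nt"]))
    untyped_ids = list(range(body, body + 50))
    for b in untyped_ids:
        neurons.append((b, UNTYPED, "unknown", "unknown"))
    neuron_df = pd.DataFrame(neurons, columns=["bodyId", "type", "hemisphere", "nt"])

    edge_rows: list[tuple[int, int, str, int]] = []

    def split_link(pre_t, post_t, count, roi):
        pres, posts = members[pre_t], members[post_t]
        pairs = [(p, q) for p in pres for q in posts if p != q]
        k = min(len(pairs), max(1, count))
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
        alloc = rng.multinomial(count, np.full(k, 1 / k))
        for (p, q), w in zip(chosen, alloc):
            if w > 0:
                edge_rows.append((p, q, roi, int(w)))

    for (pre_t, post_t), (count, roi) in sorted(links.items()):
        split_link(pre_t, post_t, count, roi)

    # untyped inputs onto planted nodes: must not move any fraction
    planted_nodes = ["aIPg", "TuTuA_1", "TuTuA_2", "SMP054", "IB112", "Li22",
                     *channels, *conv_targets]
    for post_t in planted_nodes:
        for _ in range(cfg.n_untyped_inputs_per_node // 10):
            u = untyped_ids[rng.integers(0, len(untyped_ids))]
            q = members[post_t][rng.integers(0, len(members[post_t]))]
            edge_rows.append((u, q, "CB", int(rng.integers(1, 20))))

    # background graph among background types only
    rois = np.array(["CB", "LO", "AOTU"])
    for pre_t in bg_types:
        for post_t in bg_types:
            if pre_t == post_t:
                continue
            if rng.random() < cfg.background_edge_prob:
                w = max(1, int(round(rng.lognormal(
                    cfg.background_lognormal_mu, cfg.background_lognormal_sigma))))
                split_link(pre_t, post_t, w, str(rois[rng.integers(0, 3)]))

    edges = pd.DataFrame(edge_rows,
                         columns=["bodyId_pre", "bodyId_post", "roi", "weight"])
    table = ConnectivityTable(edges=edges, neurons=neuron_df,
                              dataset_tag=f"synthetic-seed{seed}")

    gt = _ground_truth(cfg, channels, conv_targets,
                       {k: v[0] for k, v in links.items()}, input_budget)
    return table, gt


def _ground_truth(cfg: ConnectomeConfig, channels, conv_targets,
                  counts: dict[tuple[str, str], int],
                  input_budget) -> PlantedGroundTruth:
    """Motif list implied by the planted counts (plain arithmetic, no
    detector code). States the truth at the default thresholds."""
    totals = {
        "IB112": cfg.disinhibitor_input_total, "Li22": cfg.li_input_total,
        "TuTuA_1": cfg.gate_input_total, "TuTuA_2": cfg.gate_input_total,
        "SMP054": cfg.intermediate_input_total,
        **{c: cfg.channel_input_total for c in channels},
        **{t: cfg.conv_input_total for t in conv_targets},
    }
    th = GT_THRESHOLDS
    nt_sign = {"ACh": +1, "GABA": -1, "Glu": -1}
    sign = {"aIPg": +1, "TuTuA_1": -1, "TuTuA_2": -1, "SMP054": -1,
            "IB112": -1, "Li22": -1,
            **{c: +1 for c in channels}, **{t: +1 for t in conv_targets}}
    planted = sorted(totals)

    def n(pre, post):
        return counts.get((pre, post), 0)

    def frac(pre, post):
        return n(pre, post) / totals[post]

    # convergence: > thresholds from state AND summed channels, then fractions
    convergence = []
    for t in planted:
        n_state = n("aIPg", t)
        n_group = sum(n(c, t) for c in channels)
        if n_state > th["min_syn_state"] and n_group > th["min_syn_sensory"]:
            fg = n_group / totals[t]
            fs = n_state / totals[t]
            entry = {
                "target": t, "syn_state": n_state, "syn_group": n_group,
                "frac_group": fg, "frac_state": fs,
                "passes_fraction_filter": fg > th["min_frac_sensory"],
                "state_flag": fs > th["min_frac_state"],
                "pie": {c: n(c, t) / n_group for c in channels if n(c, t) > 0},
            }
            convergence.append(entry)

    f1, f2, f3 = th["chain_fracs"]
    chains = []
    for i1 in planted:
        if sign[i1] != -1 or frac("aIPg", i1) < f1 or n("aIPg", i1) == 0:
            continue
        for i2 in planted:
            if i2 == i1 or sign[i2] != -1 or i2 in channels:
                continue
            if frac(i1, i2) < f2 or n(i1, i2) == 0:
                continue
            for c in channels:
                if c in (i1, i2):
                    continue
                if frac(i2, c) >= f3 and n(i2, c) > 0:
                    chains.append(("aIPg", i1, i2, c))
    chains.sort()

    toggles = []
    sel = cfg.gate_selectivity
    if sel >= th["min_selectivity"] and n("aIPg", "TuTuA_1") > 0 \
            and n("SMP054", "TuTuA_2") > 0 and cfg.feedback_syn > 0:
        toggles.append({
            "gate_1": "TuTuA_1", "gate_2": "TuTuA_2",
            "channel_1": channels[0], "channel_2": channels[2],
            "intermediate": "SMP054",
            "selectivity": sel,
        })
    return PlantedGroundTruth(
        convergence_targets=convergence, chains=chains, toggles=toggles,
        link_counts=dict(counts), input_totals=totals)


# ---------------------------------------------------------------------------
# arena trajectories


@dataclass(frozen=True)
class ScriptedEpoch:
    """A scripted approach: the subject holds a nose-to-centroid distance to
    the target chosen so the target subtends ``target_width_deg``."""

    subject: int
    target: int
    start_s: float
    duration_s: float
    target_width_deg: float = 30.0


@dataclass(frozen=True)
class ArenaConfig:
    """Synthetic arena session: the standard 53.3 mm circular aggression arena
    filmed at 170 fps with 5–8 flies."""

    n_flies: int = 6
    fps: float = 170.0
    duration_s: float = 20.0
    arena_diameter_mm: float = 53.3
    body_a_mm: float = 1.3
    body_b_mm: float = 0.6
    speed_mm_s: float = 8.0
    heading_diffusion: float = 2.0        # rad/sqrt(s) of the heading walk
    epochs: tuple[ScriptedEpoch, ...] = (ScriptedEpoch(0, 1, 5.0, 10.0, 30.0),)
    frozen: bool = False                  # all flies motionless (diagnostics)


@dataclass
class TrajectoryGroundTruth:
    epochs: tuple[ScriptedEpoch, ...]
    hold_distance_mm: dict[int, float]    # per-epoch index
    expected_width_deg: dict[int, float]
    aggressing_flies: set


def generate_trajectories(config: ArenaConfig | None = None, seed: int = 0,
                          ) -> tuple[TrajectorySet, Ethogram, TrajectoryGroundTruth]:
    """Smooth random-walk locomotion with scripted approach epochs.

    During an epoch the subject faces the target with its nose at the
    distance where the target's angular width equals the scripted value
    (target broadside to the line of sight, so the half cross-section is
    its semi-major axis); the ethogram labels those frames as aggression
    for both flies. Deterministic given (config, seed).
    """
    cfg = config or ArenaConfig()
    rng = np.random.default_rng(seed)
    radius = cfg.arena_diameter_mm / 2.0
    margin = cfg.body_a_mm * 1.5
    n_frames = int(round(cfg.duration_s * cfg.fps))
    dt = 1.0 / cfg.fps
    if cfg.n_flies * math.pi * cfg.body_a_mm ** 2 > 0.5 * math.pi * radius ** 2:
        raise ValueError("infeasible packing: too many flies for the arena")
    for ep in cfg.epochs:
        if ep.subject >= cfg.n_flies or ep.target >= cfg.n_flies:
            raise ValueError(f"epoch references a fly outside 0..{cfg.n_flies - 1}")

    # free locomotion
    r0 = rng.uniform(0, radius - margin, cfg.n_flies)
    phi0 = rng.uniform(0, 2 * math.pi, cfg.n_flies)
    x = np.empty((n_frames, cfg.n_flies))
    y = np.empty_like(x)
    heading = np.empty_like(x)
    hx, hy = r0 * np.cos(phi0), r0 * np.sin(phi0)
    hd = rng.uniform(0, 2 * math.pi, cfg.n_flies)
    for f in range(n_frames):
        if not cfg.frozen:
            hd = hd + cfg.heading_diffusion * math.sqrt(dt) * rng.standard_normal(cfg.n_flies)
            step = cfg.speed_mm_s * dt
            hx = hx + step * np.cos(hd)
            hy = hy + step * np.sin(hd)
            out = np.hypot(hx, hy) > (radius - margin)
            if out.any():
                # turn toward the center and pull back inside
                hd = np.where(out, np.arctan2(-hy, -hx), hd)
                rr = np.hypot(hx, hy)
                shrink = np.where(out, (radius - margin) / np.maximum(rr, 1e-9), 1.0)
                hx, hy = hx * shrink, hy * shrink
        x[f], y[f], heading[f] = hx, hy, hd

    # scripted epochs override the pair's poses
    hold_d: dict[int, float] = {}
    exp_w: dict[int, float] = {}
    aggress_mask = np.zeros((n_frames, cfg.n_flies), dtype=bool)
    for k, ep in enumerate(cfg.epochs):
        d = cfg.body_a_mm / math.tan(math.radians(ep.target_width_deg) / 2.0)
        hold_d[k] = d
        exp_w[k] = ep.target_width_deg
        f0 = int(round(ep.start_s * cfg.fps))
        f1 = min(n_frames, f0 + int(round(ep.duration_s * cfg.fps)))
        # target near the center, broadside to the sight line along +x
        x[f0:f1, ep.target] = 0.0
        y[f0:f1, ep.target] = 0.0
        heading[f0:f1, ep.target] = math.pi / 2.0
        x[f0:f1, ep.subject] = -(d + cfg.body_a_mm)
        y[f0:f1, ep.subject] = 0.0
        heading[f0:f1, ep.subject] = 0.0
        aggress_mask[f0:f1, [ep.subject, ep.target]] = True

    frames = np.arange(n_frames)
    rows = {
        "frame": np.repeat(frames, cfg.n_flies),
        "fly_id": np.tile(np.arange(cfg.n_flies), n_frames),
        "x_mm": x.ravel(),
        "y_mm": y.ravel(),
        "heading_rad": np.mod(heading.ravel(), 2 * math.pi),
        "a_mm": np.full(n_frames * cfg.n_flies, cfg.body_a_mm),
        "b_mm": np.full(n_frames * cfg.n_flies, cfg.body_b_mm),
    }
    traj = TrajectorySet(data=pd.DataFrame(rows), fps=cfg.fps,
                         arena_diameter_mm=cfg.arena_diameter_mm)

    etho_df = pd.DataFrame({
        "frame": np.repeat(frames, cfg.n_flies),
        "fly_id": np.tile(np.arange(cfg.n_flies), n_frames),
        "behavior": "aggression",
        "score": aggress_mask.ravel().astype(float),
    })
    etho = Ethogram(data=etho_df, fps=cfg.fps)
    gt = TrajectoryGroundTruth(
        epochs=cfg.epochs, hold_distance_mm=hold_d, expected_width_deg=exp_w,
        aggressing_flies={f for ep in cfg.epochs for f in (ep.subject, ep.target)})
    return traj, etho, gt


# ---------------------------------------------------------------------------
# fictive-target stimulus


def generate_fictive_target(duration_s: float, arc_deg: float = 107.0,
                            angular_speed_deg_s: float = 75.0,
                            size_range_deg: tuple[float, float] = (8.0, 50.0),
                            mean_size_deg: float = 22.5,
                            rate_hz: float = 60.0, seed: int = 0,
                            size_timescale_s: float = 0.5) -> pd.DataFrame:
    """Oscillating fictive-conspecific stimulus: θ(t) sweeps a constant-speed
    triangle wave spanning ``arc_deg``, while the angular size wanders
    smoothly inside ``size_range_deg`` (a Gaussian-copula AR(1) process with
    a beta marginal, mimicking the size dynamics of a courted female whose
    distance varies), mean-corrected to ``mean_size_deg``.

    Returns a table with columns ``t_s, theta_deg, size_deg``.
    """
    from scipy import stats

    period = 2.0 * arc_deg / angular_speed_deg_s
    if duration_s <= period / 2.0:
        raise ValueError("duration must exceed one arc traversal")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    # triangle wave between ±arc/2 with |slope| = angular_speed
    phase = np.mod(t / period, 1.0)
    tri = np.where(phase < 0.5, phase * 2.0, 2.0 - phase * 2.0)  # 0..1..0
    theta = (tri - 0.5) * arc_deg

    lo, hi = size_range_deg
    m = (mean_size_deg - lo) / (hi - lo)
    if not 0 < m < 1:
        raise ValueError("mean size must lie inside the size range")
    nu = 8.0
    rng = np.random.default_rng(seed)
    rho = math.exp(-1.0 / (size_timescale_s * rate_hz))
    z = np.empty(n)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * math.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + eps[i - 1]
    u = stats.norm.cdf(z)
    size = lo + stats.beta.ppf(u, m * nu, (1 - m) * nu) * (hi - lo)
    # constant shift to pin the sample mean; re-clip keeps the bounds strict
    for _ in range(3):
        size = np.clip(size + (mean_size_deg - size.mean()),
                       lo + 1e-9, hi - 1e-9)
    return pd.DataFrame({"t_s": t, "theta_deg": theta, "size_deg": size})


# ---------------------------------------------------------------------------
# fluorescence


def generate_fluorescence(step_amplitude: float, onset_s: float = 15.0,
                          noise_sd: float = 0.05, rate_hz: float = 5.6,
                          duration_s: float = 40.0, seed: int = 0,
                          baseline: float = 1.0):
    """Noisy step-response fluorescence: F = baseline before onset, then
    baseline*(1 + step_amplitude), plus white noise; the true ΔF/F step is
    exactly ``step_amplitude``. Deterministic given seed."""
    from .behavior import FluorescenceTrace

    n = int(round(duration_s * rate_hz))
    onset = int(round(onset_s * rate_hz))
    if onset >= n:
        raise ValueError("onset beyond trace duration")
    rng = np.random.default_rng(seed)
    F = np.full(n, baseline, dtype=float)
    F[onset:] *= (1.0 + step_amplitude)
    F = F + rng.normal(0.0, noise_sd, size=n)
    return FluorescenceTrace(F=F, rate_hz=rate_hz, onset_index=onset)
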