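"""Detection of state-dependent circuit motifs in a connectivity table.

Three motifs, all defined at the cell-type level on a signed directed graph:

* **convergence** — a downstream type receiving strong excitatory input from
  both a state-encoding type and a group of visual feature detectors;
* **disinhibition chain** — state -> inhibitor -> inhibitor -> sensory type,
  signs (+, -, -), net positive: state activity relieves inhibition of the
  sensory type;
* **toggle switch** — two inhibitory gates, each selective for one of two
  parallel sensory channels, with crossed excitatory feedback from the
  channels and opposite-sign drive from the state type (direct excitation of
  one gate, disynaptic inhibition of the other).

Thresholds are parameterized with defaults taken from published screening
criteria on the fly hemibrain ("over 100 synapses from both", "more than 25%
of input from the group", "more than 2% from the state type"); "over"/"more
than" are implemented as strict inequalities (configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .connectome import (
    ConnectivityTable,
    DEFAULT_SIGN_MAP,
    edge_sign,
    input_fractions,
    output_fractions,
)


def _exceeds(value: float, threshold: float, strict: bool) -> bool:
    return value > threshold if strict else value >= threshold


@dataclass(frozen=True)
class ConvergenceTarget:
    """A cell type on which state and sensory inputs converge."""

    target: str
    state_type: str
    synapses_from_state: int
    synapses_from_sensory: dict[str, int]
    frac_from_state: float = 0.0
    frac_from_sensory_group: float = 0.0
    sensory_pie: dict[str, float] = field(default_factory=dict)
    state_fraction_flag: bool | None = None

    @property
    def total_sensory_synapses(self) -> int:
        return int(sum(self.synapses_from_sensory.values()))


@dataclass(frozen=True)
class DisinhibitionChain:
    """An ordered path state -> inhibitor1 -> inhibitor2 -> sensory target."""

    nodes: tuple[str, str, str, str]
    link_synapses: tuple[int, int, int]
    link_fractions: tuple[float, float, float]
    link_signs: tuple[int, int, int] = (+1, -1, -1)

    @property
    def net_sign(self) -> int:
        s = 1
        for x in self.link_signs:
            s *= x
        return s


@dataclass(frozen=True)
class ToggleSwitch:
    """Opponent gate pair flipping transmission between two channels."""

    state: str
    gate_1: str          # directly excited by state; gates channel_2
    gate_2: str          # disynaptically inhibited by state; gates channel_1
    channel_1: str
    channel_2: str
    intermediate: str    # inhibitory relay on the state -> gate_2 path
    selectivity_1: float  # gate_1's within-group fraction onto channel_2
    selectivity_2: float  # gate_2's within-group fraction onto channel_1
    feedback_syn_1: int   # channel_1 -> gate_1
    feedback_syn_2: int   # channel_2 -> gate_2
    drive_syn_direct: int        # state -> gate_1
    drive_syn_disynaptic: tuple[int, int]  # state -> intermediate, intermediate -> gate_2


# ---------------------------------------------------------------------------
# convergence


def find_convergence_targets(conn: ConnectivityTable, state_type: str,
                             sensory_types: Sequence[str],
                             min_syn_state: int = 100,
                             min_syn_sensory: int = 100,
                             strict: bool = True) -> list[ConvergenceTarget]:
    """Cell types receiving over ``min_syn_state`` synapses from the state
    type and over ``min_syn_sensory`` summed synapses from the sensory types.

    Results are sorted by total sensory synapses (descending), then type
    name, so output order is byte-stable.
    """
    if not sensory_types:
        raise ValueError("sensory_types must be non-empty")
    for t in (state_type, *sensory_types):
        if conn.neurons_of_type(t).empty:
            raise ValueError(f"cell type {t!r} not present in table")
    sensory = list(dict.fromkeys(sensory_types))
    exclude = {state_type, *sensory}
    out: list[ConvergenceTarget] = []
    for target in conn.cell_types:
        if target in exclude:
            continue
        n_state = conn.type_to_type_weight(state_type, target)
        if not _exceeds(n_state, min_syn_state, strict):
            continue
        per_member = {s: conn.type_to_type_weight(s, target) for s in sensory}
        if not _exceeds(sum(per_member.values()), min_syn_sensory, strict):
            continue
        out.append(ConvergenceTarget(
            target=target, state_type=state_type,
            synapses_from_state=n_state, synapses_from_sensory=per_member))
    out.sort(key=lambda t: (-t.total_sensory_synapses, t.target))
    return out


def filter_by_fractions(conn: ConnectivityTable,
                        candidates: Sequence[ConvergenceTarget],
                        state_type: str, sensory_group: Sequence[str],
                        min_frac_sensory: float = 0.25,
                        min_frac_state: float = 0.02,
                        strict: bool = True) -> list[ConvergenceTarget]:
    """Keep candidates whose sensory-group input fraction exceeds
    ``min_frac_sensory``; each kept target also records whether its state
    input fraction exceeds ``min_frac_state`` (reported, not filtered on).

    Fractions follow the typed-denominator convention of
    :func:`socivis.connectome.input_fractions`.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    kept: list[ConvergenceTarget] = []
    for cand in candidates:
        fv = input_fractions(conn, cand.target)
        frac_group = fv.group_fraction(sensory_group)
        if not _exceeds(frac_group, min_frac_sensory, strict):
            continue
        frac_state = fv[state_type]
        pie = decompose_sensory_input(conn, cand.target, sensory_group)
        kept.append(ConvergenceTarget(
            target=cand.target, state_type=state_type,
            synapses_from_state=cand.synapses_from_state,
            synapses_from_sensory=cand.synapses_from_sensory,
            frac_from_state=frac_state, frac_from_sensory_group=frac_group,
            sensory_pie=pie,
            state_fraction_flag=_exceeds(frac_state, min_frac_state, strict)))
    kept.sort(key=lambda t: (-t.total_sensory_synapses, t.target))
    return kept


def decompose_sensory_input(conn: ConnectivityTable, target_type: str,
                            sensory_group: Sequence[str]) -> dict[str, float]:
    """Pie fractions: how the target's input from the group splits over the
    group's member types. Fractions over contributing members sum to 1."""
    counts = {s: conn.type_to_type_weight(s, target_type) for s in sensory_group}
    total = sum(counts.values())
    if total == 0:
        raise ValueError(
            f"{target_type!r} receives no synapses from the sensory group")
    return {s: c / total for s, c in counts.items() if c > 0}


# ---------------------------------------------------------------------------
# disinhibition


def find_disinhibition_chains(conn: ConnectivityTable, state_type: str,
                              sensory_types: Sequence[str],
                              sign_map: Mapping[str, int] | None = None,
                              min_frac_per_link: tuple[float, float, float] = (0.02, 0.05, 0.01),
                              roi_constraint: Iterable[str] | None = None,
                              ) -> list[DisinhibitionChain]:
    """Enumerate state -> i1 -> i2 -> sensory paths with signs (+, -, -).

    Each link must carry at least its configured fraction of the *receiver's*
    typed input; the optional ROI constraint restricts the final link (both
    its numerator and denominator) to the given ROIs, e.g. the dendritic
    neuropil of the sensory types. Paths with repeated nodes are excluded;
    results are deduplicated by (i1, i2, sensory) and sorted deterministically.
    """
    if sign_map is None:
        sign_map = DEFAULT_SIGN_MAP
    f1, f2, f3 = min_frac_per_link
    sensory = list(dict.fromkeys(sensory_types))
    if edge_sign(conn, state_type, sign_map) != +1:
        return []

    signs = {t: edge_sign(conn, t, sign_map) for t in conn.cell_types}
    unknown_seen = False

    tw = conn.type_weight_table()
    totals = conn.typed_input_totals()
    tw_last = conn.type_weight_table(roi_constraint)
    totals_last = conn.typed_input_totals(roi_constraint)

    def frac(pre, post, table, tot):
        t = tot.get(post, 0)
        return table.get((pre, post), 0) / t if t else 0.0

    # candidate first inhibitors: types receiving >= f1 of input from state
    chains: list[DisinhibitionChain] = []
    for i1 in conn.cell_types:
        if i1 == state_type or i1 in sensory:
            continue
        q1 = frac(state_type, i1, tw, totals)
        if q1 < f1 or q1 == 0:
            continue
        if signs[i1] == 0:
            unknown_seen = True
            continue
        if signs[i1] != -1:
            continue
        n1 = tw[(state_type, i1)]
        for i2 in conn.cell_types:
            if i2 in (state_type, i1) or i2 in sensory:
                continue
            q2 = frac(i1, i2, tw, totals)
            if q2 < f2 or q2 == 0:
                continue
            if signs[i2] == 0:
                unknown_seen = True
                continue
            if signs[i2] != -1:
                continue
            n2 = tw[(i1, i2)]
            for s in sensory:
                if s in (state_type, i1, i2):
                    continue
                q3 = frac(i2, s, tw_last, totals_last)
                if q3 < f3 or q3 == 0:
                    continue
                n3 = tw_last[(i2, s)]
                chains.append(DisinhibitionChain(
                    nodes=(state_type, i1, i2, s),
                    link_synapses=(n1, n2, n3),
                    link_fractions=(q1, q2, q3)))
    if unknown_seen:
        warnings.warn("some intermediate types had unresolved signs and were "
                      "skipped", stacklevel=2)
    uniq = {c.nodes[1:]: c for c in chains}
    return sorted(uniq.values(),
                  key=lambda c: (-sum(c.link_synapses), c.nodes))


# ---------------------------------------------------------------------------
# toggle switch


def gate_selectivity(conn: ConnectivityTable, gate_type: str,
                     channel_group: Sequence[str]) -> float:
    """Max over group members of the gate's within-group output share.

    The denominator is the gate's synapses onto the whole channel group (not
    all of its outputs).
    """
    counts = [conn.type_to_type_weight(gate_type, c) for c in channel_group]
    total = sum(counts)
    if total == 0:
        raise ValueError(f"{gate_type!r} makes no synapses onto the channel group")
    return max(counts) / total


def find_toggle_switches(conn: ConnectivityTable, state_type: str,
                         channel_group: Sequence[str],
                         sign_map: Mapping[str, int] | None = None,
                         min_selectivity: float = 0.9,
                         min_feedback_syn: int = 0,
                         max_intermediates: int = 1) -> list[ToggleSwitch]:
    """Find opponent gate pairs over a channel group.

    A switch is a tuple (gate_1, gate_2, channel_1, channel_2, intermediate)
    with: both gates inhibitory; gate_1 selective for channel_2 and gate_2
    for channel_1 (within-group output share >= ``min_selectivity``);
    excitatory feedback channel_1 -> gate_1 and channel_2 -> gate_2 above
    ``min_feedback_syn``; a direct excitatory state -> gate_1 edge; and a
    disynaptic state -> intermediate -> gate_2 path through an inhibitory
    intermediate (net inhibition). Mirror-image duplicates (the same
    pairing found from both orderings) are collapsed to one canonical tuple.
    """
    if len(set(channel_group)) < 2:
        raise ValueError("channel_group needs at least 2 members")
    if max_intermediates != 1:
        raise NotImplementedError("only single-intermediate drive paths supported")
    if sign_map is None:
        sign_map = DEFAULT_SIGN_MAP
    channels = list(dict.fromkeys(channel_group))
    signs = {t: edge_sign(conn, t, sign_map) for t in conn.cell_types}
    if signs.get(state_type) != +1:
        return []

    inhibitory = [t for t in conn.cell_types
                  if signs[t] == -1 and t != state_type and t not in channels]
    # gates with any output onto the group, plus their selectivity argmax
    gate_pref: dict[str, tuple[str, float]] = {}
    for g in inhibitory:
        counts = {c: conn.type_to_type_weight(g, c) for c in channels}
        total = sum(counts.values())
        if total == 0:
            continue
        best = max(sorted(counts), key=lambda c: counts[c])
        gate_pref[g] = (best, counts[best] / total)

    results: list[ToggleSwitch] = []
    seen: set[frozenset] = set()
    for g1, (c2, sel1) in sorted(gate_pref.items()):
        if sel1 < min_selectivity:
            continue
        n_direct = conn.type_to_type_weight(state_type, g1)
        if n_direct == 0:
            continue
        for g2, (c1, sel2) in sorted(gate_pref.items()):
            if g2 == g1 or sel2 < min_selectivity or c1 == c2:
                continue
            fb1 = conn.type_to_type_weight(c1, g1)
            fb2 = conn.type_to_type_weight(c2, g2)
            if signs.get(c1) != +1 or signs.get(c2) != +1:
                continue
            if fb1 <= min_feedback_syn or fb2 <= min_feedback_syn:
                continue
            for x in inhibitory:
                if x in (g1, g2):
                    continue
                n_sx = conn.type_to_type_weight(state_type, x)
                n_xg = conn.type_to_type_weight(x, g2)
                if n_sx == 0 or n_xg == 0:
                    continue
                key = frozenset([(g1, c2), (g2, c1), x])
                if key in seen:
                    continue
                seen.add(key)
                results.append(ToggleSwitch(
                    state=state_type, gate_1=g1, gate_2=g2,
                    channel_1=c1, channel_2=c2, intermediate=x,
                    selectivity_1=sel1, selectivity_2=sel2,
                    feedback_syn_1=fb1, feedback_syn_2=fb2,
                    drive_syn_direct=n_direct,
                    drive_syn_disynaptic=(n_sx, n_xg)))
    results.sort(key=lambda s: (-(s.feedback_syn_1 + s.feedback_syn_2),
                                s.gate_1, s.gate_2, s.intermediate))
    return results
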