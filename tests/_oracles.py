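"""Independent brute-force oracles used to check the fast implementations.

Everything here works on plain Python rows/dicts with naive loops, sharing
no code path with the package's pandas/graph implementations.
"""

from __future__ import annotations

import math


def edge_rows(conn):
    """(pre_type, post_type, roi, weight) rows, plain tuples."""
    types = dict(zip(conn.neurons["bodyId"], conn.neurons["type"]))
    return [
        (types[r.bodyId_pre], types[r.bodyId_post], r.roi, int(r.weight))
        for r in conn.edges.itertuples()
    ]


def tally_fractions(rows, focal, direction, roi_filter=None, untyped="UNTYPED"):
    """Per-partner relative connection strengths by naive per-edge tally."""
    counts: dict[str, int] = {}
    for pre, post, roi, w in rows:
        if roi_filter is not None and roi not in roi_filter:
            continue
        if direction == "input" and post == focal and pre != untyped and post != untyped:
            counts[pre] = counts.get(pre, 0) + w
        if direction == "output" and pre == focal and post != untyped and pre != untyped:
            counts[post] = counts.get(post, 0) + w
    total = sum(counts.values())
    return ({k: v / total for k, v in counts.items()}, total)


def type_counts(rows, untyped="UNTYPED"):
    """(pre, post) -> weight and per-type typed-input totals."""
    tw: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for pre, post, _roi, w in rows:
        if pre == untyped or post == untyped:
            continue
        tw[(pre, post)] = tw.get((pre, post), 0) + w
        totals[post] = totals.get(post, 0) + w
    return tw, totals


def enumerate_convergence(rows, state, sensory, min_state=100, min_sensory=100,
                          untyped="UNTYPED"):
    """All cell types with > min_state synapses from the state type and
    > min_sensory summed synapses from the sensory types."""
    tw, _ = type_counts(rows, untyped)
    all_types = {t for k in tw for t in k}
    found = set()
    for t in sorted(all_types):
        if t == state or t in sensory:
            continue
        n_state = tw.get((state, t), 0)
        n_group = sum(tw.get((s, t), 0) for s in sensory)
        if n_state > min_state and n_group > min_sensory:
            found.add(t)
    return found


def enumerate_chains(rows, state, sensory, signs, fracs=(0.02, 0.05, 0.01),
                     untyped="UNTYPED"):
    """All state->i1->i2->sensory paths with signs (+,-,-) and per-link
    receiver-side input fractions above thresholds. Returns (i1,i2,s) set."""
    if signs.get(state) != +1:
        return set()
    tw, totals = type_counts(rows, untyped)
    all_types = sorted({t for k in tw for t in k} | set(signs))

    def frac(p, q):
        return tw.get((p, q), 0) / totals[q] if totals.get(q) else 0.0

    out = set()
    f1, f2, f3 = fracs
    for i1 in all_types:
        if signs.get(i1) != -1 or i1 == state or i1 in sensory:
            continue
        if tw.get((state, i1), 0) == 0 or frac(state, i1) < f1:
            continue
        for i2 in all_types:
            if signs.get(i2) != -1 or i2 in (state, i1) or i2 in sensory:
                continue
            if tw.get((i1, i2), 0) == 0 or frac(i1, i2) < f2:
                continue
            for s in sensory:
                if s in (state, i1, i2):
                    continue
                if tw.get((i2, s), 0) == 0 or frac(i2, s) < f3:
                    continue
                out.add((i1, i2, s))
    return out


def enumerate_toggles(rows, state, channels, signs, min_selectivity=0.9,
                      min_feedback=0, untyped="UNTYPED"):
    """All (g1, g2, c1, c2, x) tuples satisfying the opponent-switch
    definition, deduplicated by the unordered pairing key."""
    if signs.get(state) != +1:
        return set()
    tw, _ = type_counts(rows, untyped)
    all_types = sorted({t for k in tw for t in k} | set(signs))
    inhib = [t for t in all_types
             if signs.get(t) == -1 and t != state and t not in channels]
    out = set()
    seen = set()
    for g1 in inhib:
        counts1 = {c: tw.get((g1, c), 0) for c in channels}
        tot1 = sum(counts1.values())
        if tot1 == 0 or tw.get((state, g1), 0) == 0:
            continue
        c2 = min([c for c in channels if counts1[c] == max(counts1.values())])
        if counts1[c2] / tot1 < min_selectivity:
            continue
        for g2 in inhib:
            if g2 == g1:
                continue
            counts2 = {c: tw.get((g2, c), 0) for c in channels}
            tot2 = sum(counts2.values())
            if tot2 == 0:
                continue
            c1 = min([c for c in channels if counts2[c] == max(counts2.values())])
            if counts2[c1] / tot2 < min_selectivity or c1 == c2:
                continue
            if signs.get(c1) != +1 or signs.get(c2) != +1:
                continue
            if tw.get((c1, g1), 0) <= min_feedback or tw.get((c2, g2), 0) <= min_feedback:
                continue
            for x in inhib:
                if x in (g1, g2):
                    continue
                if tw.get((state, x), 0) == 0 or tw.get((x, g2), 0) == 0:
                    continue
                key = frozenset([(g1, c2), (g2, c1), x])
                if key in seen:
                    continue
                seen.add(key)
                out.add((g1, g2, c1, c2, x))
    return out


# ---------------------------------------------------------------------------
# geometry oracles


def ellipse_boundary_extent(nose, cx, cy, heading, a, b, n=200_000):
    """Angular extent of an ellipse seen from a point, by densely sampling
    boundary points and measuring the span of their bearing angles."""
    spread = []
    ch, sh = math.cos(heading), math.sin(heading)
    for i in range(n):
        t = 2 * math.pi * i / n
        ex, ey = a * math.cos(t), b * math.sin(t)
        px = cx + ch * ex - sh * ey
        py = cy + sh * ex + ch * ey
        spread.append(math.atan2(py - nose[1], px - nose[0]))
    spread.sort()
    gaps = [spread[i + 1] - spread[i] for i in range(len(spread) - 1)]
    gaps.append(spread[0] + 2 * math.pi - spread[-1])
    return math.degrees(2 * math.pi - max(gaps))


def chord_half_length_numeric(cx, cy, heading, a, b, direction):
    """Half-length of the ellipse chord through the centroid along a unit
    direction, via the quadratic of the line-ellipse intersection."""
    ch, sh = math.cos(-heading), math.sin(-heading)
    dx = ch * direction[0] - sh * direction[1]
    dy = sh * direction[0] + ch * direction[1]
    # (t*dx)^2/a^2 + (t*dy)^2/b^2 = 1
    coeff = dx * dx / (a * a) + dy * dy / (b * b)
    return 1.0 / math.sqrt(coeff)


# ---------------------------------------------------------------------------
# behavior oracles


def run_length_first_epoch(ok_flags, min_frames):
    """First index opening a True-run of length >= min_frames, else None."""
    i, n = 0, len(ok_flags)
    while i < n:
        if ok_flags[i]:
            j = i
            while j < n and ok_flags[j]:
                j += 1
            if j - i >= min_frames:
                return i
            i = j
        else:
            i += 1
    return None


def naive_bins(values, width):
    out = []
    for i in range(0, len(values), width):
        chunk = values[i:i + width]
        out.append(sum(chunk) / len(chunk))
    return out
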