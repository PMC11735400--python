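"""Typed synaptic-connectivity tables and relative connection strengths.

The central object is :class:`ConnectivityTable`: a directed, ROI-resolved
edge list of synapse counts between reconstructed neurons, together with a
neuron index carrying cell-type, hemisphere and neurotransmitter annotations
(the layout produced by neuPrint-style adjacency exports).

All "relative connection strength" computations follow the convention used
throughout fly connectomics work on typed circuits: synapses from partners
without a cell-type assignment (fragments, orphan bodies) are *excluded from
the denominator*, because unidentified fragments of already-counted cells
would otherwise deflate every fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: sentinel cell type for bodies with no type assignment
UNTYPED = "UNTYPED"

#: default neurotransmitter -> sign convention: acetylcholine is excitatory,
#: GABA and glutamate inhibitory (GluCl), anything else unresolved.
DEFAULT_SIGN_MAP: dict[str, int] = {
    "ACh": +1,
    "GABA": -1,
    "Glu": -1,
    "other": 0,
    "unknown": 0,
}

EDGE_COLUMNS = ("bodyId_pre", "bodyId_post", "roi", "weight")
NEURON_COLUMNS = ("bodyId", "type", "hemisphere", "nt")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Table contents violate a structural invariant."""


@dataclass(frozen=True)
class Neuron:
    body_id: int
    cell_type: str = UNTYPED
    hemisphere: str = "unknown"
    neurotransmitter: str = "unknown"


@dataclass(frozen=True)
class FractionVector:
    """Relative connection strengths of one cell type's partners.

    ``fractions`` maps partner cell type -> fraction of the focal type's
    typed synapses in ``direction``; ``denominator`` is the number of typed
    synapses used. Fractions over all typed partners sum to 1 whenever the
    denominator is positive.
    """

    focal: str
    direction: str  # "input" or "output"
    fractions: dict[str, float]
    denominator: int

    def __getitem__(self, partner: str) -> float:
        return self.fractions.get(partner, 0.0)

    def group_fraction(self, partners: Iterable[str]) -> float:
        """Summed fraction over a group of partner types."""
        return float(sum(self.fractions.get(p, 0.0) for p in partners))


@dataclass
class ConnectivityTable:
    """Directed, typed, ROI-resolved synapse-count edge list.

    Parameters
    ----------
    edges : DataFrame with columns ``bodyId_pre, bodyId_post, roi, weight``.
    neurons : DataFrame with columns ``bodyId, type, hemisphere, nt``;
        missing/empty types are normalized to the ``UNTYPED`` sentinel.
    dataset_tag : free-form provenance label (e.g. a release version).
    """

    edges: pd.DataFrame
    neurons: pd.DataFrame
    dataset_tag: str = ""
    allow_self_edges: bool = False
    _typed_edges: pd.DataFrame = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.edges = self.edges.reset_index(drop=True)
        self.neurons = _normalize_neurons(self.neurons)
        _validate(self.edges, self.neurons, self.allow_self_edges)
        types = self.neurons.set_index("bodyId")["type"]
        annotated = self.edges.copy()
        annotated["type_pre"] = annotated["bodyId_pre"].map(types)
        annotated["type_post"] = annotated["bodyId_post"].map(types)
        self._annotated = annotated
        self._typed_edges = annotated[
            (annotated["type_pre"] != UNTYPED) & (annotated["type_post"] != UNTYPED)
        ]
        self._type_weight_cache: dict = {}

    # -- introspection -------------------------------------------------

    @property
    def annotated_edges(self) -> pd.DataFrame:
        """Edges with ``type_pre``/``type_post`` columns attached."""
        return self._annotated

    @property
    def cell_types(self) -> list[str]:
        t = set(self.neurons["type"]) - {UNTYPED}
        return sorted(t)

    @property
    def rois(self) -> list[str]:
        return sorted(set(self.edges["roi"]))

    def neurons_of_type(self, cell_type: str) -> pd.DataFrame:
        return self.neurons[self.neurons["type"] == cell_type]

    def type_to_type_weight(self, pre_type: str, post_type: str,
                            roi_filter: Iterable[str] | None = None) -> int:
        """Total synapse count from one cell type onto another."""
        return self.type_weight_table(roi_filter).get((pre_type, post_type), 0)

    def type_weight_table(self, roi_filter: Iterable[str] | None = None,
                          ) -> dict[tuple[str, str], int]:
        """Aggregated (pre type, post type) -> synapse count over typed
        partners, optionally ROI-restricted. Cached per filter."""
        key = None if roi_filter is None else tuple(sorted(set(roi_filter)))
        cached = self._type_weight_cache.get(key)
        if cached is not None:
            return cached
        e = self._typed_edges
        if key is not None:
            e = e[e["roi"].isin(set(key))]
        grouped = e.groupby(["type_pre", "type_post"])["weight"].sum()
        table = {(str(p), str(q)): int(w) for (p, q), w in grouped.items()}
        self._type_weight_cache[key] = table
        return table

    def typed_input_totals(self, roi_filter: Iterable[str] | None = None,
                           ) -> dict[str, int]:
        """Per cell type: total synapses received from typed partners."""
        totals: dict[str, int] = {}
        for (_, post), w in self.type_weight_table(roi_filter).items():
            totals[post] = totals.get(post, 0) + w
        return totals


def _normalize_neurons(neurons: pd.DataFrame) -> pd.DataFrame:
    for col in NEURON_COLUMNS:
        if col not in neurons.columns:
            if col == "hemisphere":
                neurons = neurons.assign(hemisphere="unknown")
            elif col == "nt":
                neurons = neurons.assign(nt="unknown")
            else:
                raise SchemaError(f"neuron table is missing required column {col!r}")
    neurons = neurons.loc[:, list(NEURON_COLUMNS)].copy()
    neurons["type"] = neurons["type"].fillna(UNTYPED).replace("", UNTYPED)
    neurons["nt"] = neurons["nt"].fillna("unknown").replace("", "unknown")
    neurons["hemisphere"] = neurons["hemisphere"].fillna("unknown").replace("", "unknown")
    if neurons["bodyId"].duplicated().any():
        dup = neurons.loc[neurons["bodyId"].duplicated(), "bodyId"].iloc[0]
        raise ValidationError(f"duplicate bodyId in neuron table: {dup}")
    return neurons.reset_index(drop=True)


def _validate(edges: pd.DataFrame, neurons: pd.DataFrame, allow_self: bool) -> None:
    for col in EDGE_COLUMNS:
        if col not in edges.columns:
            raise SchemaError(f"edge table is missing required column {col!r}")
    w = edges["weight"]
    bad = ~(np.isfinite(w) & (w > 0) & (w == np.floor(w)))
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"non-positive or non-integer synapse weight at edge row {idx}: {w.iloc[idx]!r}"
        )
    known = set(neurons["bodyId"])
    for col in ("bodyId_pre", "bodyId_post"):
        missing = set(edges[col]) - known
        if missing:
            orphan = sorted(missing)[0]
            raise ValidationError(
                f"edge endpoint {orphan} ({col}) is absent from the neuron table"
            )
    if not allow_self and (edges["bodyId_pre"] == edges["bodyId_post"]).any():
        idx = int((edges["bodyId_pre"] == edges["bodyId_post"]).idxmax())
        raise ValidationError(f"self-edge at row {idx} (set allow_self_edges=True to keep)")


def load_connectivity(table_path: str | Path, neuron_table_path: str | Path,
                      dataset_tag: str = "", allow_self_edges: bool = False,
                      ) -> ConnectivityTable:
    """Load and validate a connectivity table from CSV/TSV/parquet files.

    ``table_path`` needs columns ``bodyId_pre, bodyId_post, roi, weight``;
    ``neuron_table_path`` needs ``bodyId, type, hemisphere, nt``. Untyped
    rows are retained but flagged with the :data:`UNTYPED` sentinel.
    """
    edges = _read_table(table_path)
    neurons = _read_table(neuron_table_path)
    if not dataset_tag:
        dataset_tag = Path(table_path).stem
    return ConnectivityTable(edges=edges, neurons=neurons, dataset_tag=dataset_tag,
                             allow_self_edges=allow_self_edges)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".parquet", ".pq"}:
        return pd.read_parquet(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def save_connectivity(conn: ConnectivityTable, edges_path: str | Path,
                      neurons_path: str | Path) -> None:
    """Write the table back out in the schema :func:`load_connectivity` reads."""
    conn.edges.loc[:, list(EDGE_COLUMNS)].to_csv(edges_path, index=False)
    conn.neurons.to_csv(neurons_path, index=False)


# ---------------------------------------------------------------------------
# relative connection strengths


def _partner_fractions(conn: ConnectivityTable, focal_type: str, direction: str,
                       roi_filter: Iterable[str] | None = None,
                       include_untyped: bool = False) -> FractionVector:
    if direction not in ("input", "output"):
        raise ValueError(f"direction must be 'input' or 'output', got {direction!r}")
    focal_col, partner_col = (
        ("type_post", "type_pre") if direction == "input" else ("type_pre", "type_post")
    )
    e = conn.annotated_edges
    m = e[focal_col] == focal_type
    if roi_filter is not None:
        m &= e["roi"].isin(set(roi_filter))
    if not include_untyped:
        m &= e[partner_col] != UNTYPED
    sub = e.loc[m]
    total = int(sub["weight"].sum())
    if total == 0:
        return FractionVector(focal=focal_type, direction=direction,
                              fractions={}, denominator=0)
    by_partner = sub.groupby(partner_col)["weight"].sum()
    fractions = {str(t): float(w) / total for t, w in by_partner.items()}
    return FractionVector(focal=focal_type, direction=direction,
                          fractions=fractions, denominator=total)


def input_fractions(conn: ConnectivityTable, post_cell_type: str,
                    roi_filter: Iterable[str] | None = None,
                    compartment_filter: Iterable[str] | None = None,
                    include_untyped: bool = False) -> FractionVector:
    """Relative input strengths onto ``post_cell_type``.

    fraction(pre_type) = synapses from pre_type onto the focal type, divided
    by the focal type's total synapses from *typed* partners; both restricted
    by the ROI filters. ``compartment_filter`` approximates compartment
    restriction (e.g. "dendritic inputs") by ROI names: datasets without
    explicit compartment labels fall back to ROI filtering.

    A focal type with zero typed input synapses under the filters yields an
    empty vector with denominator 0, never a division by zero.
    """
    rois = _merge_filters(roi_filter, compartment_filter)
    return _partner_fractions(conn, post_cell_type, "input", rois, include_untyped)


def output_fractions(conn: ConnectivityTable, pre_cell_type: str,
                     roi_filter: Iterable[str] | None = None,
                     include_untyped: bool = False) -> FractionVector:
    """Relative output strengths of ``pre_cell_type`` (mirror of inputs)."""
    return _partner_fractions(conn, pre_cell_type, "output", roi_filter, include_untyped)


def _merge_filters(roi_filter, compartment_filter):
    if compartment_filter is None:
        return roi_filter
    if roi_filter is None:
        warnings.warn(
            "no explicit compartment labels in this schema; treating the "
            "compartment filter as an ROI filter", stacklevel=3)
        return compartment_filter
    return set(roi_filter) & set(compartment_filter)


def neuropil_profile(conn: ConnectivityTable, cell_type: str,
                     direction: str) -> dict[str, float]:
    """Per-ROI synapse fractions of a cell type in one direction.

    ROI names pass through verbatim (no canonicalization); fractions sum to
    1 over the ROIs present. Untyped partners count here — the profile asks
    where the synapses sit, not who the partner is.
    """
    focal_col = "type_post" if direction == "input" else "type_pre"
    if direction not in ("input", "output"):
        raise ValueError(f"direction must be 'input' or 'output', got {direction!r}")
    e = conn.annotated_edges
    sub = e.loc[e[focal_col] == cell_type]
    total = int(sub["weight"].sum())
    if total == 0:
        raise ValidationError(
            f"{cell_type!r} has no {direction} synapses; neuropil profile undefined")
    by_roi = sub.groupby("roi")["weight"].sum().sort_index()
    return {str(r): float(w) / total for r, w in by_roi.items()}


def classify_centrifugal(conn: ConnectivityTable, cell_type: str,
                         central_rois: Iterable[str], optic_rois: Iterable[str],
                         majority_threshold: float = 0.5) -> bool | None:
    """Is a cell type centrifugal (central-brain inputs, optic-lobe outputs)?

    True iff the input fraction within ``central_rois`` and the output
    fraction within ``optic_rois`` both exceed ``majority_threshold``
    ("most" of the synapses). Returns None (undefined) when the cell has no
    synapses in either direction.
    """
    central, optic = set(central_rois), set(optic_rois)
    if not central or not optic:
        raise ValueError("both ROI sets must be non-empty")
    if central & optic:
        raise ValueError(f"ROI sets overlap: {sorted(central & optic)}")
    try:
        in_prof = neuropil_profile(conn, cell_type, "input")
        out_prof = neuropil_profile(conn, cell_type, "output")
    except ValidationError:
        return None
    in_central = sum(f for r, f in in_prof.items() if r in central)
    out_optic = sum(f for r, f in out_prof.items() if r in optic)
    return bool(in_central > majority_threshold and out_optic > majority_threshold)


def edge_sign(conn: ConnectivityTable, pre_cell_type: str,
              sign_map: Mapping[str, int] | None = None,
              majority: float = 0.8) -> int:
    """Putative sign (+1 excitatory / -1 inhibitory / 0 unresolved) of a type.

    The type's neurotransmitter is the label shared by its member neurons;
    when labeled members disagree, the majority label wins if at least
    ``majority`` of labeled members carry it, else the sign is 0 with a
    warning (cell types are treated as transmitter-homogeneous).
    """
    if sign_map is None:
        sign_map = DEFAULT_SIGN_MAP
    members = conn.neurons_of_type(pre_cell_type)
    labeled = members.loc[~members["nt"].isin(["unknown", ""]), "nt"]
    if labeled.empty:
        return 0
    counts = labeled.value_counts()
    top_label, top_n = counts.index[0], int(counts.iloc[0])
    if top_n / len(labeled) < majority:
        warnings.warn(
            f"mixed neurotransmitter labels for {pre_cell_type!r}: "
            f"{dict(counts)}; sign unresolved", stacklevel=2)
        return 0
    return int(sign_map.get(top_label, 0))
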