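"""Atlas bookkeeping and network-level connectivity summaries.

ROIs carry a network label from a 17-network-style cortical parcellation plus
a hippocampal set. Three networks play designated roles in the analysis:

* ``DMN-C`` — the memory-linked default-mode subnetwork of interest
  (retrosplenial / parahippocampal / posterior angular parcels),
* ``DMN-A`` — the core default-mode subnetwork,
* ``Hipp``  — hippocampal head/body/tail ROIs per hemisphere.

Edges of the connectome are classified by the roles of their two endpoints
and averaged into four scalar summaries per subject: *within* (DMN-C to
DMN-C), *between* (DMN-C to DMN-A), *extra* (DMN-C to the rest of cortex),
and *hipp* (hippocampus to everything else).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AtlasLabels",
    "EdgeVector",
    "NetworkSummary",
    "DEFAULT_ROLE_MAP",
    "edge_index_pairs",
    "vectorize",
    "devectorize",
    "classify_edges",
    "summarize",
]

#: network label -> designated role; labels not listed get role "other".
DEFAULT_ROLE_MAP = {"DefaultC": "DMN-C", "DefaultA": "DMN-A", "Hipp": "Hipp"}

ROLES = ("DMN-C", "DMN-A", "Hipp", "other")

EDGE_CLASSES = ("within", "between", "extra", "hipp_any", "other")


@dataclass
class AtlasLabels:
    """ROI label table: id, name, hemisphere, network, derived role.

    ``role_map`` maps network labels to the designated roles; every network
    label absent from the map gets role ``"other"``.
    """

    frame: pd.DataFrame
    role_map: dict = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))

    def __post_init__(self) -> None:
        required = {"roi_id", "roi_name", "hemisphere", "network"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        if self.frame["roi_id"].duplicated().any():
            raise ValueError("atlas roi_ids are not unique")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def n_rois(self) -> int:
        return len(self.frame)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.frame["roi_id"].to_numpy()

    @property
    def networks(self) -> np.ndarray:
        return self.frame["network"].to_numpy()

    @property
    def roles(self) -> np.ndarray:
        """Role per ROI, in atlas order. Total: every ROI gets exactly one."""
        return np.array(
            [self.role_map.get(n, "other") for n in self.frame["network"]]
        )

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, role_map: dict | None = None) -> "AtlasLabels":
        frame = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
        return cls(frame, role_map or dict(DEFAULT_ROLE_MAP))


def edge_index_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """Lower-triangle edge order: (i, j) with i > j, row-major over i.

    This is the canonical edge enumeration used everywhere a connectome is
    flattened to a vector; ``np.tril_indices`` yields exactly this order.
    """
    return np.tril_indices(n_rois, k=-1)


@dataclass
class EdgeVector:
    """Flattened lower triangle of a connectome with its index map."""

    values: np.ndarray
    roi_ids: np.ndarray
    row_idx: np.ndarray
    col_idx: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.values.size

    def pair(self, k: int) -> tuple:
        """ROI-id pair of edge ``k``."""
        return self.roi_ids[self.row_idx[k]], self.roi_ids[self.col_idx[k]]


@dataclass
class NetworkSummary:
    within: float
    between: float
    extra: float
    hipp: float

    def as_dict(self) -> dict:
        return {
            "within": self.within,
            "between": self.between,
            "extra": self.extra,
            "hipp": self.hipp,
        }


def vectorize(conn) -> EdgeVector:
    """Flatten a connectome's lower triangle into the canonical edge order."""
    m = np.asarray(conn.matrix, dtype=float)
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("connectome matrix is not symmetric")
    rows, cols = edge_index_pairs(m.shape[0])
    return EdgeVector(
        values=m[rows, cols].copy(),
        roi_ids=np.asarray(conn.roi_ids),
        row_idx=rows,
        col_idx=cols,
    )


def devectorize(ev: EdgeVector, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector."""
    r = len(ev.roi_ids)
    m = np.full((r, r), diagonal, dtype=float)
    m[ev.row_idx, ev.col_idx] = ev.values
    m[ev.col_idx, ev.row_idx] = ev.values
    return m


def classify_edges(atlas: AtlasLabels, n_rois: int | None = None) -> np.ndarray:
    """Assign each lower-triangle edge to one of the five edge classes.

    Classification is a function of the two endpoint roles, with the
    precedence: within (both DMN-C) > between (DMN-C with DMN-A) >
    hipp_any (at least one hippocampal ROI) > extra (DMN-C with a plain
    "other" ROI) > other. Hippocampal edges are therefore excluded from
    "extra" — the extra-network summary is defined over the cortical atlas.
    """
    roles = atlas.roles
    r = len(roles)
    if n_rois is not None and n_rois != r:
        raise ValueError(
            f"connectome has {n_rois} ROIs but atlas labels {r}"
        )
    rows, cols = edge_index_pairs(r)
    a, b = roles[rows], roles[cols]
    classes = np.full(rows.size, "other", dtype=object)
    is_c_a, is_c_b = a == "DMN-C", b == "DMN-C"
    is_a_a, is_a_b = a == "DMN-A", b == "DMN-A"
    is_h_a, is_h_b = a == "Hipp", b == "Hipp"
    classes[(is_c_a | is_c_b) & ~(is_h_a | is_h_b)] = "extra"
    classes[is_h_a | is_h_b] = "hipp_any"
    classes[(is_c_a & is_a_b) | (is_a_a & is_c_b)] = "between"
    classes[is_c_a & is_c_b] = "within"
    return classes.astype(str)


def summarize(
    conn,
    atlas: AtlasLabels,
    include_hipp_in_extra: bool = False,
    include_hipp_internal: bool = False,
) -> NetworkSummary:
    """Average edge strength (Pearson r) per edge class.

    ``within``/``between``/``extra`` follow :func:`classify_edges`. The
    hippocampal summary averages every edge incident to a hippocampal ROI;
    hippocampus-internal edges are excluded unless ``include_hipp_internal``.
    ``include_hipp_in_extra`` additionally counts DMN-C-to-hippocampus edges
    in the extra-network mean.
    """
    if conn.scale != "pearson_r":
        raise ValueError("network summaries are defined on the pearson_r scale")
    ev = vectorize(conn)
    if ev.values.size != edge_index_pairs(atlas.n_rois)[0].size:
        raise ValueError("atlas does not cover the connectome's ROIs")
    classes = classify_edges(atlas)
    roles = atlas.roles
    a, b = roles[ev.row_idx], roles[ev.col_idx]

    def class_mean(mask: np.ndarray, name: str) -> float:
        if not mask.any():
            raise ValueError(f"summary '{name}' undefined: no contributing edges")
        return float(ev.values[mask].mean())

    extra_mask = classes == "extra"
    if include_hipp_in_extra:
        c_h = ((a == "DMN-C") & (b == "Hipp")) | ((a == "Hipp") & (b == "DMN-C"))
        extra_mask = extra_mask | c_h
    hipp_mask = (a == "Hipp") | (b == "Hipp")
    if not include_hipp_internal:
        hipp_mask &= ~((a == "Hipp") & (b == "Hipp"))
    return NetworkSummary(
        within=class_mean(classes == "within", "within"),
        between=class_mean(classes == "between", "between"),
        extra=class_mean(extra_mask, "extra"),
        hipp=class_mean(hipp_mask, "hipp"),
    )
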