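"""Clonal lineage assignment.

Two clone definitions are supported. The default identity rule groups
sequences sharing the same V gene, the same J gene and an identical CDR3
amino-acid junction. The alternative threshold rule single-links sequences
within (V gene, J gene, junction length) groups whose normalized junction
nucleotide Hamming distance is at or below a sample-specific threshold,
detected from the bimodal distance-to-nearest distribution.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.signal import argrelextrema
from scipy.sparse.csgraph import connected_components
from scipy.stats import gaussian_kde

__all__ = [
    "ClonePartition",
    "ThresholdResult",
    "first_gene",
    "assign_clones_identity",
    "assign_clones_threshold",
    "distance_to_nearest",
    "find_threshold",
]


def first_gene(call: str) -> str:
    """Gene-level name: first of a comma-separated call list, allele stripped."""
    if not isinstance(call, str):
        return ""
    return call.split(",")[0].split("*")[0].strip()


@dataclass
class ClonePartition:
    """A sample's clone partition.

    ``assignments`` maps sequence_id -> clone_id for every partitioned
    record; ``clones`` has one row per clone (clone_id, size,
    weighted_size, v_call, j_call, junction_aa). Records excluded from
    partitioning (empty junction_aa) are listed in ``excluded``.
    """

    sample_id: str
    mode: str
    assignments: pd.Series
    clones: pd.DataFrame
    threshold: float | None = None
    excluded: tuple[str, ...] = ()

    @property
    def sizes(self) -> pd.Series:
        return self.clones.set_index("clone_id")["size"]

    def abundances(self, weighted: bool = False) -> np.ndarray:
        col = "weighted_size" if weighted else "size"
        return self.clones[col].to_numpy(dtype=float)


def _clone_hash(*parts: str) -> str:
    return hashlib.sha1("|".join(parts).encode()).hexdigest()[:12]


def _split_excluded(records: pd.DataFrame) -> tuple[pd.DataFrame, tuple[str, ...]]:
    empty = records["junction_aa"].astype(str).str.len() == 0
    excluded = tuple(records.loc[empty, "sequence_id"])
    if excluded:
        warnings.warn(
            f"{len(excluded)} record(s) with empty junction_aa excluded from "
            "clone assignment",
            stacklevel=3,
        )
    return records[~empty], excluded


def _partition_from_labels(
    records: pd.DataFrame,
    labels: pd.Series,
    sample_id: str,
    mode: str,
    threshold: float | None,
    excluded: tuple[str, ...],
) -> ClonePartition:
    assignments = pd.Series(labels.values, index=records["sequence_id"].values, name="clone_id")
    grp = records.assign(clone_id=labels.values).groupby("clone_id", sort=True)
    clones = grp.agg(
        size=("sequence_id", "size"),
        weighted_size=("consensus_count", "sum")
        if "consensus_count" in records.columns
        else ("sequence_id", "size"),
        v_call=("v_call", lambda s: first_gene(s.iloc[0])),
        j_call=("j_call", lambda s: first_gene(s.iloc[0])),
        junction_aa=("junction_aa", lambda s: s.mode().iloc[0]),
    ).reset_index()
    clones.insert(1, "sample_id", sample_id)
    clones["mode"] = mode
    return ClonePartition(sample_id, mode, assignments, clones, threshold, excluded)


def assign_clones_identity(records: pd.DataFrame) -> ClonePartition:
    """Partition by exact (V gene, J gene, junction_aa) identity.

    Clone ids are stable hashes of the defining triple, so the same clone
    gets the same id in every run. Records with an empty junction_aa are
    excluded and reported on the partition.
    """
    if not len(records):
        raise ValueError("cannot partition an empty sample")
    sample_id = str(records["sample_id"].iloc[0])
    kept, excluded = _split_excluded(records)
    v = kept["v_call"].map(first_gene)
    j = kept["j_call"].map(first_gene)
    labels = pd.Series(
        [_clone_hash(a, b, c) for a, b, c in zip(v, j, kept["junction_aa"])],
        index=kept.index,
    )
    return _partition_from_labels(kept, labels, sample_id, "identity", None, excluded)


def _junction_matrix(junctions: pd.Series) -> np.ndarray:
    """(n, L) uint8 matrix of equal-length junction strings."""
    joined = "".join(junctions)
    mat = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    return mat.reshape(len(junctions), -1)


def _pairwise_hamming(mat: np.ndarray, block: int = 256) -> np.ndarray:
    """Dense pairwise Hamming-count matrix, computed in row blocks."""
    n = mat.shape[0]
    out = np.empty((n, n), dtype=np.int32)
    for start in range(0, n, block):
        stop = min(start + block, n)
        out[start:stop] = (mat[start:stop, None, :] != mat[None, :, :]).sum(axis=2)
    return out


def distance_to_nearest(records: pd.DataFrame) -> pd.Series:
    """Per-record minimal normalized junction Hamming distance.

    Distances are computed only among records sharing V gene, J gene and
    junction length; records alone in their group have no defined distance
    and are omitted from the result.
    """
    kept = records[records["junction"].astype(str).str.len() > 0]
    out_idx: list[str] = []
    out_val: list[float] = []
    groups = kept.groupby(
        [
            kept["v_call"].map(first_gene),
            kept["j_call"].map(first_gene),
            kept["junction"].str.len(),
        ],
        sort=False,
    )
    for (_, _, L), g in groups:
        if len(g) < 2:
            continue
        mat = _junction_matrix(g["junction"])
        d = _pairwise_hamming(mat).astype(float) / float(L)
        np.fill_diagonal(d, np.inf)
        out_idx.extend(g["sequence_id"])
        out_val.extend(d.min(axis=1))
    if not out_val:
        warnings.warn("no group with >= 2 comparable records; no distances", stacklevel=2)
    return pd.Series(out_val, index=out_idx, name="dist_nearest", dtype=float)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    fallback_used: bool
    n_distances: int


def find_threshold(
    distances: np.ndarray | pd.Series,
    fallback: float = 0.1,
    min_distances: int = 50,
    grid_size: int = 512,
    bandwidth: float | str = "scott",
) -> ThresholdResult:
    """Sample-specific clonal threshold from a distance-to-nearest vector.

    Fits a Gaussian kernel density and returns the location of the density
    minimum between the two largest modes. A unimodal (or degenerate)
    distribution yields the configured fallback with a warning flag set.
    """
    d = np.asarray(distances, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < min_distances:
        raise ValueError(
            f"only {len(d)} finite distances (< {min_distances}); "
            "use identity-based clone assignment instead"
        )
    grid = np.linspace(0.0, max(d.max(), 1e-6), grid_size)
    try:
        dens = gaussian_kde(d, bw_method=bandwidth)(grid)
    except np.linalg.LinAlgError:
        # zero-variance distances: no structure to split
        return ThresholdResult(fallback, True, len(d))
    peaks = list(argrelextrema(dens, np.greater)[0])
    # modes at the grid boundary are real (e.g. a spike at 0)
    if dens[0] > dens[1]:
        peaks.insert(0, 0)
    if dens[-1] > dens[-2]:
        peaks.append(grid_size - 1)
    if len(peaks) < 2:
        warnings.warn("unimodal distance distribution; using fallback threshold", stacklevel=2)
        return ThresholdResult(fallback, True, len(d))
    top_two = sorted(sorted(peaks, key=lambda i: -dens[i])[:2])
    lo, hi = top_two
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return ThresholdResult(float(grid[valley]), False, len(d))


def assign_clones_threshold(records: pd.DataFrame, threshold: float) -> ClonePartition:
    """Single-linkage clones within (V gene, J gene, junction length) groups.

    Two records are linked when their normalized junction Hamming distance
    is <= threshold; clones are the connected components. threshold = 0 is
    the degenerate limit grouping identical junctions only.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not len(records):
        raise ValueError("cannot partition an empty sample")
    sample_id = str(records["sample_id"].iloc[0])
    kept, excluded = _split_excluded(records)

    labels = pd.Series("", index=kept.index, dtype=object)
    groups = kept.groupby(
        [
            kept["v_call"].map(first_gene),
            kept["j_call"].map(first_gene),
            kept["junction"].str.len(),
        ],
        sort=False,
    )
    for (vg, jg, L), g in groups:
        if len(g) == 1:
            comp = np.zeros(1, dtype=int)
        else:
            mat = _junction_matrix(g["junction"])
            d = _pairwise_hamming(mat).astype(float) / float(L)
            adj = sparse.csr_matrix(d <= threshold)
            _, comp = connected_components(adj, directed=False)
        # stable clone id: defining group plus lexicographically smallest junction
        for k in np.unique(comp):
            members = g.index[comp == k]
            rep = min(kept.loc[members, "junction"])
            labels.loc[members] = _clone_hash(str(vg), str(jg), str(L), rep)
    return _partition_from_labels(
        kept, labels, sample_id, "threshold", float(threshold), excluded
    )
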