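"""Repertoire dissimilarity index (RDI).

Five-step procedure for a pair of repertoires: (1) subsample each to a
common depth without replacement; (2) count V/D/J gene-segment usage over
a fixed shared feature space; (3) normalize the counts (default:
within-segment proportions; optionally centered log2 as in the original
RDI formulation); (4) compare the pair; (5) take the Euclidean distance,
and average over repeated subsamples (default 100 repeats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clones import first_gene
from .util import substream

__all__ = [
    "FeatureSpace",
    "UsageVector",
    "DissimilarityMatrix",
    "usage_counts",
    "normalize_usage",
    "rdi_pair",
    "rdi_matrix",
    "within_group_mean",
]

SEGMENTS = ("v", "d", "j")


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered shared V/D/J gene-segment feature space."""

    v: tuple[str, ...]
    d: tuple[str, ...]
    j: tuple[str, ...]
    segments: tuple[str, ...] = SEGMENTS

    @classmethod
    def from_samples(
        cls, samples: dict[str, pd.DataFrame], segments: tuple[str, ...] = SEGMENTS
    ) -> "FeatureSpace":
        pools: dict[str, set[str]] = {"v": set(), "d": set(), "j": set()}
        for df in samples.values():
            for seg in ("v", "d", "j"):
                genes = df[f"{seg}_call"].map(first_gene)
                pools[seg].update(g for g in genes if g)
        return cls(
            v=tuple(sorted(pools["v"])),
            d=tuple(sorted(pools["d"])),
            j=tuple(sorted(pools["j"])),
            segments=tuple(segments),
        )

    @classmethod
    def from_germline(
        cls, germline: dict[str, str], segments: tuple[str, ...] = SEGMENTS
    ) -> "FeatureSpace":
        names = sorted(first_gene(g) for g in germline)
        return cls(
            v=tuple(n for n in names if n.startswith("IGHV")),
            d=tuple(n for n in names if n.startswith("IGHD")),
            j=tuple(n for n in names if n.startswith("IGHJ")),
            segments=tuple(segments),
        )

    def block(self, seg: str) -> tuple[str, ...]:
        return getattr(self, seg)


@dataclass
class UsageVector:
    sample_id: str
    features: FeatureSpace
    counts: dict[str, np.ndarray]       # per-segment raw counts at depth
    normalized: dict[str, np.ndarray]
    depth: int
    normalization: str


@dataclass
class _Codes:
    """Integer-coded gene calls of one sample (code -1 = absent call)."""

    n: int
    codes: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_records(cls, df: pd.DataFrame, features: FeatureSpace) -> "_Codes":
        out = cls(n=len(df))
        for seg in features.segments:
            idx = {g: i for i, g in enumerate(features.block(seg))}
            out.codes[seg] = (
                df[f"{seg}_call"].map(first_gene).map(lambda g: idx.get(g, -1)).to_numpy()
            )
        return out

    def count(self, seg: str, size: int, idx: np.ndarray) -> np.ndarray:
        c = self.codes[seg][idx]
        c = c[c >= 0]  # records without a call for this segment contribute nothing
        return np.bincount(c, minlength=size).astype(float)


def normalize_usage(
    counts: dict[str, np.ndarray], method: str = "proportions"
) -> dict[str, np.ndarray]:
    """Normalize per-segment count blocks.

    ``proportions``: each segment block divided by its own total (the D
    block is computed over records with a D call only, then renormalized).
    ``log``: centered log2 of the proportions with a half-count pseudocount,
    the transformation used by the original RDI formulation.
    """
    out = {}
    for seg, c in counts.items():
        total = c.sum()
        if method == "proportions":
            out[seg] = c / total if total > 0 else np.zeros_like(c)
        elif method == "log":
            p = (c + 0.5) / (total + 0.5 * len(c)) if total > 0 else np.full_like(
                c, 1.0 / max(len(c), 1)
            )
            v = np.log2(p)
            out[seg] = v - v.mean()
        else:
            raise ValueError(f"unknown normalization: {method!r}")
    return out


def usage_counts(
    records: pd.DataFrame,
    depth: int,
    rng: np.random.Generator,
    features: FeatureSpace,
    normalization: str = "proportions",
) -> UsageVector:
    """Gene-segment usage of one subsample of ``depth`` records."""
    n = len(records)
    if depth > n:
        raise ValueError(f"subsample depth {depth} exceeds record count {n}")
    codes = _Codes.from_records(records, features)
    idx = rng.choice(n, size=depth, replace=False) if depth < n else np.arange(n)
    counts = {
        seg: codes.count(seg, len(features.block(seg)), idx)
        for seg in features.segments
    }
    return UsageVector(
        sample_id=str(records["sample_id"].iloc[0]) if n else "",
        features=features,
        counts=counts,
        normalized=normalize_usage(counts, normalization),
        depth=depth,
        normalization=normalization,
    )


def _euclidean(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> float:
    sq = 0.0
    for seg in a:
        diff = a[seg] - b[seg]
        sq += float(diff @ diff)
    return float(np.sqrt(sq))


def _mean_rdi_coded(
    codes_a: _Codes,
    codes_b: _Codes,
    rng_a: np.random.Generator,
    rng_b: np.random.Generator,
    features: FeatureSpace,
    depth: int,
    n_repeats: int,
    normalization: str,
) -> float:
    sizes = {seg: len(features.block(seg)) for seg in features.segments}
    if depth == codes_a.n and depth == codes_b.n:
        # full-depth subsamples are the whole samples: every repeat is identical
        full_a = np.arange(codes_a.n)
        full_b = np.arange(codes_b.n)
        ua = normalize_usage(
            {s: codes_a.count(s, sizes[s], full_a) for s in features.segments},
            normalization,
        )
        ub = normalize_usage(
            {s: codes_b.count(s, sizes[s], full_b) for s in features.segments},
            normalization,
        )
        return _euclidean(ua, ub)
    acc = 0.0
    for _ in range(n_repeats):
        ia = rng_a.choice(codes_a.n, size=depth, replace=False)
        ib = rng_b.choice(codes_b.n, size=depth, replace=False)
        ua = normalize_usage(
            {s: codes_a.count(s, sizes[s], ia) for s in features.segments}, normalization
        )
        ub = normalize_usage(
            {s: codes_b.count(s, sizes[s], ib) for s in features.segments}, normalization
        )
        acc += _euclidean(ua, ub)
    return acc / n_repeats


def rdi_pair(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    depth: int,
    n_repeats: int = 100,
    seed: int = 0,
    normalization: str = "proportions",
    features: FeatureSpace | None = None,
) -> float:
    """Averaged RDI between two repertoires.

    Each repeat independently subsamples both repertoires to ``depth``,
    builds normalized usage vectors over the shared feature space and takes
    their Euclidean distance; the mean over ``n_repeats`` is returned.
    Each sample's subsampling stream is keyed by its sample_id, so the
    result is symmetric in the argument order for a fixed seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    for name, df in (("first", records_a), ("second", records_b)):
        if len(df) < depth:
            raise ValueError(
                f"{name} sample ({df['sample_id'].iloc[0] if len(df) else '?'}) has "
                f"{len(df)} records, fewer than depth {depth}"
            )
    if features is None:
        features = FeatureSpace.from_samples({"a": records_a, "b": records_b})
    sid_a = str(records_a["sample_id"].iloc[0])
    sid_b = str(records_b["sample_id"].iloc[0])
    return _mean_rdi_coded(
        _Codes.from_records(records_a, features),
        _Codes.from_records(records_b, features),
        substream(seed, "rdi", sid_a),
        substream(seed, "rdi", sid_b),
        features,
        depth,
        n_repeats,
        normalization,
    )


@dataclass
class DissimilarityMatrix:
    sample_ids: tuple[str, ...]
    matrix: np.ndarray
    depth: int
    n_repeats: int
    normalization: str
    excluded: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        ids = self.sample_ids
        for i in range(len(ids)):
            for k in range(i + 1, len(ids)):
                rows.append(
                    {
                        "sample_a": ids[i],
                        "sample_b": ids[k],
                        "rdi": self.matrix[i, k],
                        "depth": self.depth,
                        "n_repeats": self.n_repeats,
                        "normalization": self.normalization,
                    }
                )
        return pd.DataFrame(rows)


def rdi_matrix(
    samples: dict[str, pd.DataFrame],
    depth: int | None = None,
    n_repeats: int = 100,
    seed: int = 0,
    normalization: str = "proportions",
    features: FeatureSpace | None = None,
) -> DissimilarityMatrix:
    """Averaged RDI for every unordered pair of samples.

    ``depth`` defaults to the minimum sample size across the set. Samples
    smaller than an explicit depth are excluded with a warning rather than
    silently dropped.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for a dissimilarity matrix")
    sizes = {sid: len(df) for sid, df in samples.items()}
    if depth is None:
        depth = min(sizes.values())
    excluded = tuple(sid for sid, n in sizes.items() if n < depth)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} sample(s) below depth {depth}: {excluded}",
            stacklevel=2,
        )
    kept = [sid for sid in samples if sid not in excluded]
    if len(kept) < 2:
        raise ValueError("fewer than 2 samples at or above the subsampling depth")
    if features is None:
        features = FeatureSpace.from_samples({s: samples[s] for s in kept})

    coded = {s: _Codes.from_records(samples[s], features) for s in kept}
    m = np.zeros((len(kept), len(kept)))
    for i, sa in enumerate(kept):
        for k in range(i + 1, len(kept)):
            sb = kept[k]
            val = _mean_rdi_coded(
                coded[sa],
                coded[sb],
                substream(seed, "rdi", sa),
                substream(seed, "rdi", sb),
                features,
                depth,
                n_repeats,
                normalization,
            )
            m[i, k] = m[k, i] = val
    return DissimilarityMatrix(tuple(kept), m, depth, n_repeats, normalization, excluded)


def within_group_mean(
    matrix: DissimilarityMatrix, groups: dict[str, str]
) -> pd.DataFrame:
    """Per-sample mean RDI to the other samples of its own group.

    This is the per-individual dissimilarity covariate used when
    correlating RDI with per-mouse outcomes; group means over it summarise
    inter-individual dissimilarity per age/diet cell.
    """
    ids = matrix.sample_ids
    rows = []
    for i, sid in enumerate(ids):
        peers = [
            k for k, other in enumerate(ids) if k != i and groups.get(other) == groups.get(sid)
        ]
        rows.append(
            {
                "sample_id": sid,
                "group": groups.get(sid),
                "rdi_within_group": float(matrix.matrix[i, peers].mean()) if peers else np.nan,
                "n_peers": len(peers),
            }
        )
    return pd.DataFrame(rows)
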