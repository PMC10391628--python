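"""Hill diversity spectra and the P20 clonal-expansion statistic.

The Hill number of order q of a clone abundance vector p is
``qD = (sum_i p_i^q)^(1/(1-q))``, with the q -> 1 limit equal to the
exponential of the Shannon entropy. q = 0 is clone richness, q = 1
"Shannon diversity", q = 2 "Simpson diversity" (inverse Simpson
concentration). Comparisons across samples use uniform-depth subsampling
without replacement with a bootstrap percentile band.

P20 is the summed relative frequency of the 20 largest clones: a direct
measure of how much of the repertoire the top expansions occupy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clones import ClonePartition

__all__ = [
    "hill_number",
    "hill_spectrum",
    "shannon_entropy",
    "simpson_index",
    "DiversitySpectrum",
    "diversity_with_resampling",
    "ClonalExpansion",
    "p20",
]


def _normalize(abundances) -> np.ndarray:
    p = np.asarray(abundances, dtype=float)
    if p.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector has no diversity")
    p = p[p > 0]
    return p / total


def hill_number(abundances, q: float) -> float:
    """Diversity of order q >= 0 of a (not necessarily normalized) vector."""
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    p = _normalize(abundances)
    if q == 0:
        return float(len(p))
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-(p * np.log(p)).sum()))
    return float((p**q).sum() ** (1.0 / (1.0 - q)))


def hill_spectrum(abundances, q_grid) -> np.ndarray:
    return np.array([hill_number(abundances, q) for q in np.asarray(q_grid, float)])


def shannon_entropy(abundances) -> float:
    """Raw Shannon entropy (nats); exp of this is the order-1 Hill number."""
    p = _normalize(abundances)
    return float(-(p * np.log(p)).sum())


def simpson_index(abundances) -> float:
    """Raw Simpson concentration sum p_i^2; reciprocal is the order-2 Hill number."""
    p = _normalize(abundances)
    return float((p**2).sum())


@dataclass
class DiversitySpectrum:
    sample_id: str
    q: np.ndarray
    mean_qd: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    depth: int
    n_boot: int

    def to_frame(self, isotype: str = "all") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "isotype": isotype,
                "q": self.q,
                "mean_qd": self.mean_qd,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "depth": self.depth,
                "n_boot": self.n_boot,
            }
        )


def diversity_with_resampling(
    clone_labels,
    q_grid,
    depth: int,
    n_boot: int,
    rng: np.random.Generator,
    sample_id: str = "",
    ci: float = 0.95,
) -> DiversitySpectrum:
    """Rarefied Hill spectrum from per-record clone labels.

    Each of ``n_boot`` replicates subsamples ``depth`` records without
    replacement, recomputes clone abundances and the Hill number at each q,
    and the mean and percentile band over replicates are reported.
    """
    labels = pd.Series(clone_labels)
    n = len(labels)
    if n == 0:
        raise ValueError(f"sample {sample_id!r}: no records")
    if depth > n:
        raise ValueError(
            f"sample {sample_id!r}: subsample depth {depth} exceeds sample size {n}"
        )
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    q_grid = np.asarray(q_grid, dtype=float)
    codes = pd.factorize(labels)[0]
    n_codes = codes.max() + 1

    qd = np.empty((n_boot, len(q_grid)))
    if depth == n:
        counts = np.bincount(codes, minlength=n_codes)
        qd[:] = hill_spectrum(counts, q_grid)
    else:
        for b in range(n_boot):
            idx = rng.choice(n, size=depth, replace=False)
            counts = np.bincount(codes[idx], minlength=n_codes)
            qd[b] = hill_spectrum(counts, q_grid)
    alpha = (1.0 - ci) / 2.0
    return DiversitySpectrum(
        sample_id=sample_id,
        q=q_grid,
        mean_qd=qd.mean(axis=0),
        ci_lo=np.quantile(qd, alpha, axis=0),
        ci_hi=np.quantile(qd, 1 - alpha, axis=0),
        depth=int(depth),
        n_boot=int(n_boot),
    )


@dataclass
class ClonalExpansion:
    sample_id: str
    p20: float
    rank_abundance: np.ndarray  # relative clone frequencies, rank order


def p20(partition: ClonePartition, weighted: bool = False, top: int = 20) -> ClonalExpansion:
    """Summed relative frequency of the ``top`` largest clones.

    Clones are ranked by size descending, ties broken by clone_id so the
    boundary at rank ``top`` is deterministic. With fewer than ``top``
    clones the statistic is 1 by definition.
    """
    clones = partition.clones
    if not len(clones):
        raise ValueError(f"sample {partition.sample_id!r}: empty partition")
    col = "weighted_size" if weighted else "size"
    ranked = clones.sort_values([col, "clone_id"], ascending=[False, True])
    freqs = ranked[col].to_numpy(dtype=float)
    freqs = freqs / freqs.sum()
    return ClonalExpansion(partition.sample_id, float(freqs[:top].sum()), freqs)
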