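"""Affinity-maturation profiling.

Somatic hypermutation is counted per sequence against the inferred
germline alignment, outside the junction, with each substitution
classified as synonymous (amino acid preserved) or non-synonymous by
translating the germline codon with and without the substitution.
Clones are staged by class-switch status (IgM+IgD+ naive-like with or
without SHM, versus fully switched IgM-IgD-), and per-sample isotype
fractions and CDR3-length Gaussian statistics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table as _std_table

from .airr_io import ISOTYPE_CLASSES

__all__ = [
    "MutationProfile",
    "count_shm",
    "shm_table",
    "stage_clone",
    "stage_clones",
    "isotype_fractions",
    "CDR3Stats",
    "cdr3_gaussian",
    "replicate_variability",
]

CODON_TO_AA: dict[str, str] = dict(_std_table.forward_table)
for _stop in _std_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class MutationProfile:
    sequence_id: str
    n_syn: int
    n_nonsyn: int
    n_informative: int

    @property
    def freq_syn(self) -> float:
        return self.n_syn / self.n_informative if self.n_informative else 0.0

    @property
    def freq_nonsyn(self) -> float:
        return self.n_nonsyn / self.n_informative if self.n_informative else 0.0


def count_shm(
    sequence_alignment: str,
    germline_alignment: str,
    junction_span: tuple[int, int],
    frame_offset: int = 0,
    sequence_id: str = "",
) -> MutationProfile:
    """Count synonymous and non-synonymous mutations outside the junction.

    Positions inside ``junction_span`` (half-open, alignment coordinates)
    are excluded; positions where either string has a gap (``.``/``-``) or
    N are not informative. Each mismatch is classified by translating the
    germline codon (frame anchored at ``frame_offset``) with the single
    observed substitution; the remaining codon positions are taken from
    germline, so multi-hit codons are classified per position against the
    germline context. Substitutions creating or destroying a stop codon
    count as non-synonymous.
    """
    if len(sequence_alignment) != len(germline_alignment):
        raise ValueError(
            f"{sequence_id}: alignment length mismatch "
            f"({len(sequence_alignment)} vs {len(germline_alignment)})"
        )
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    lo, hi = junction_span
    if not (0 <= lo <= hi <= len(germline_alignment)):
        raise ValueError(
            f"{sequence_id}: junction span {junction_span} outside alignment "
            f"of length {len(germline_alignment)}"
        )
    obs = np.frombuffer(sequence_alignment.upper().encode("ascii"), dtype=np.uint8)
    germ = np.frombuffer(germline_alignment.upper().encode("ascii"), dtype=np.uint8)

    is_base = np.isin(obs, np.frombuffer(b"ACGT", np.uint8)) & np.isin(
        germ, np.frombuffer(b"ACGT", np.uint8)
    )
    outside = np.ones(len(germ), dtype=bool)
    outside[lo:hi] = False
    informative = is_base & outside

    n_syn = n_nonsyn = 0
    for pos in np.flatnonzero(informative & (obs != germ)):
        cs = frame_offset + 3 * ((pos - frame_offset) // 3)
        if cs < 0 or cs + 3 > len(germ):
            continue  # incomplete edge codon: unclassifiable
        germ_codon = germline_alignment[cs : cs + 3].upper()
        if any(ch not in "ACGT" for ch in germ_codon):
            continue  # ambiguous codon context
        k = pos - cs
        mut_codon = germ_codon[:k] + chr(obs[pos]) + germ_codon[k + 1 :]
        if CODON_TO_AA[germ_codon] == CODON_TO_AA[mut_codon]:
            n_syn += 1
        else:
            n_nonsyn += 1
    return MutationProfile(sequence_id, n_syn, n_nonsyn, int(informative.sum()))


def _junction_span(row: pd.Series) -> tuple[int, int]:
    if "junction_start" in row.index and str(row["junction_start"]).strip() != "":
        start = int(row["junction_start"])
    else:
        start = str(row["germline_alignment"]).find(str(row["junction"]))
        if start < 0:
            raise ValueError(
                f"{row['sequence_id']}: junction not locatable in germline alignment"
            )
    return start, start + len(str(row["junction"]))


def shm_table(records: pd.DataFrame, frame_offset: int = 0) -> pd.DataFrame:
    """Per-sequence mutation profile table for one or more samples."""
    has_start = "junction_start" in records.columns
    cols = ["sequence_id", "sample_id", "isotype", "sequence_alignment",
            "germline_alignment", "junction"]
    cols.append("junction_start" if has_start else "junction")
    rows = []
    for tup in records[cols].itertuples(index=False):
        seq_id, sample_id, isotype, obs, germ, junction, extra = tup
        if has_start and str(extra).strip() != "":
            start = int(extra)
        else:
            start = germ.find(junction)
            if start < 0:
                raise ValueError(f"{seq_id}: junction not locatable in germline alignment")
        prof = count_shm(
            obs, germ, (start, start + len(junction)), frame_offset, sequence_id=seq_id
        )
        rows.append(
            (seq_id, sample_id, isotype, prof.n_syn, prof.n_nonsyn,
             prof.n_informative, prof.freq_syn, prof.freq_nonsyn)
        )
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "sample_id", "isotype", "n_syn", "n_nonsyn",
                 "n_informative", "freq_syn", "freq_nonsyn"],
    )


STAGES = ("IgM+IgD+SHM-", "IgM+IgD+SHM+", "IgM-IgD-")


def stage_clone(
    member_isotypes,
    member_mutation_totals,
    shm_min_mutations: int = 1,
    clone_id: str = "",
) -> str:
    """Class-switch stage of one clone.

    A clone retaining at least one IgM or IgD member is naive-lineage
    (IgM+IgD+), split into SHM- (no member reaches ``shm_min_mutations``
    mutations) and SHM+ (antigen-stimulated); a clone with no naive
    isotype left is post-antigenic (IgM-IgD-). Members with a missing
    isotype are ignored with a warning.
    """
    iso = list(member_isotypes)
    muts = list(member_mutation_totals)
    if len(iso) != len(muts):
        raise ValueError("isotype and mutation lists differ in length")
    keep = [i for i, x in enumerate(iso) if isinstance(x, str) and x in ISOTYPE_CLASSES]
    if len(keep) < len(iso):
        warnings.warn(
            f"clone {clone_id or '?'}: {len(iso) - len(keep)} member(s) with missing "
            "isotype ignored",
            stacklevel=2,
        )
    if not keep:
        raise ValueError(f"clone {clone_id or '?'}: no member has a usable isotype")
    naive = any(iso[i] in ("IgM", "IgD") for i in keep)
    if not naive:
        return "IgM-IgD-"
    mutated = any(muts[i] >= shm_min_mutations for i in keep)
    return "IgM+IgD+SHM+" if mutated else "IgM+IgD+SHM-"


def stage_clones(
    records: pd.DataFrame,
    assignments: pd.Series,
    mutations: pd.DataFrame,
    shm_min_mutations: int = 1,
) -> pd.DataFrame:
    """Stage every clone of a sample; returns clone_id, sample_id, stage."""
    mut_total = (
        mutations.set_index("sequence_id")[["n_syn", "n_nonsyn"]].sum(axis=1)
        if len(mutations)
        else pd.Series(dtype=float)
    )
    df = records[records["sequence_id"].isin(assignments.index)].copy()
    df["clone_id"] = assignments.loc[df["sequence_id"]].values
    df["mut_total"] = mut_total.reindex(df["sequence_id"]).fillna(0).values
    rows = []
    for cid, g in df.groupby("clone_id", sort=True):
        rows.append(
            {
                "clone_id": cid,
                "sample_id": g["sample_id"].iloc[0],
                "stage": stage_clone(
                    g["isotype"], g["mut_total"], shm_min_mutations, clone_id=cid
                ),
            }
        )
    return pd.DataFrame(rows)


def isotype_fractions(
    records: pd.DataFrame, weight_by_consensus: bool = False
) -> pd.Series:
    """Fraction of records (or consensus reads) per isotype class."""
    classified = records[records["isotype"].isin(ISOTYPE_CLASSES)]
    if not len(classified):
        raise ValueError("no records with a classified isotype")
    if weight_by_consensus:
        totals = classified.groupby("isotype")["consensus_count"].sum()
    else:
        totals = classified.groupby("isotype").size()
    frac = totals.reindex(ISOTYPE_CLASSES, fill_value=0).astype(float)
    return frac / frac.sum()


@dataclass(frozen=True)
class CDR3Stats:
    sample_id: str
    mean_aa: float
    sd_aa: float
    n: int
    ddof: int = 1


def cdr3_gaussian(lengths, sample_id: str = "", ddof: int = 1) -> CDR3Stats:
    """Gaussian center and deviation of CDR3 amino-acid lengths.

    The sample mean and standard deviation are the location/scale fit of a
    normal distribution; the deviation uses the ``ddof`` denominator
    convention (default n-1, recorded on the result).
    """
    x = np.asarray(list(lengths), dtype=float)
    if len(x) < 2:
        raise ValueError(f"sample {sample_id!r}: need >= 2 CDR3 lengths")
    return CDR3Stats(
        sample_id, float(x.mean()), float(x.std(ddof=ddof)), len(x), ddof
    )


def replicate_variability(per_replicate_means) -> float:
    """Between-replicate variability: sd of per-mouse means within a group."""
    x = np.asarray(list(per_replicate_means), dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 replicate means")
    return float(x.std(ddof=1))
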