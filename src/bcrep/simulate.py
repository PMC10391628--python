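"""Synthetic BCR-repertoire cohort generator.

Emulates the statistical structure of an aging dietary-restriction mouse
cohort so the whole analysis pipeline can be exercised and validated
without the deposited sequencing data:

* clone sizes follow a symmetric Dirichlet-multinomial whose concentration
  decays exponentially with age at a diet-specific rate, so clonal
  expansion (P20) grows with age, faster under ad libitum (AL) feeding
  than under dietary restriction (DR);
* each mouse has an idiosyncratic V/D/J usage vector drawn around the
  population vector with a precision that shrinks with age, driving growth
  of inter-individual dissimilarity (RDI);
* isotypes are drawn per tissue (spleen IgM-dominant, ileum IgA-dominant);
* somatic hypermutation is planted as independent substitutions outside
  the junction, at isotype-dependent rates, with each substitution
  recorded as synonymous or non-synonymous against the standard code;
* a latent morbidity score is coupled to each mouse's planted clonal
  expansion and discretised into a necropsy-style pathology record.

Clone identity is exact by construction (members of a clone share V call,
J call and the identical junction), so the ground-truth partition is
recoverable by identity-based clone assignment; an optional junction
mutation switch exercises the distance-threshold mode instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import airr_io
from .morbidity import FINDINGS_VOCABULARY, PathologyRecord
from .util import substream

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "CohortData",
    "make_germline_reference",
    "population_usage",
    "build_design",
    "generate_sample",
    "generate_morbidity",
    "generate_cohort",
    "write_cohort",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# 61 sense codons of the standard genetic code (no stops), used to build
# germline segments and junctions that translate cleanly in frame 0.
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class CohortSpec:
    """Generator parameters: the study conditions the cohort emulates.

    Clone-size skew: the per-clone Dirichlet concentration is
    ``alpha0 * exp(-s_d * months_d)`` summed over diet exposures, where
    ``s_d = expansion_slope[diet]`` (per month) and exposure starts at
    weaning/randomisation age 3 months; the mid-life-switch group AL_DR16M
    accrues AL-slope exposure until 16 months and DR-slope exposure after.
    Usage idiosyncrasy: per-mouse V/D/J usage is Dirichlet-resampled around
    the population vector with precision ``usage_precision0`` decaying at
    ``usage_idiosyncrasy[diet]`` per month of the same exposure.
    Defaults are illustrative effect sizes chosen to reproduce the
    qualitative trajectories of an AL/DR aging cohort (clonal abundance
    rising from roughly a third of the repertoire at 5 months to ~80% under
    AL and ~60% under DR by 24 months); they are not estimates from any
    particular dataset.
    """

    n_mice_per_group: int = 5
    ages: tuple[int, ...] = (5, 16, 20, 24)
    diets: tuple[str, ...] = ("AL", "DR", "AL_DR16M")
    tissues: tuple[str, ...] = ("spleen",)
    seqs_per_sample: int = 5000
    n_clones_base: int = 1000
    alpha0: float = 0.135
    expansion_slope: dict[str, float] = field(
        default_factory=lambda: {"AL": 0.097, "DR": 0.059}
    )
    usage_precision0: float = 800.0
    usage_idiosyncrasy: dict[str, float] = field(
        default_factory=lambda: {"AL": 0.12, "DR": 0.05}
    )
    shm_rate: dict[str, float] = field(
        default_factory=lambda: {
            "IgM": 1.5, "IgD": 1.0, "IgG": 8.0, "IgE": 5.0, "IgA": 8.0
        }
    )
    isotype_mix: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "spleen": {"IgM": 0.61, "IgG": 0.23, "IgA": 0.13, "IgD": 0.02, "IgE": 0.01},
            "ileum": {"IgA": 0.90, "IgM": 0.05, "IgG": 0.03, "IgD": 0.01, "IgE": 0.01},
        }
    )
    cdr3_length_mean_aa: float = 14.0
    cdr3_length_sd_aa: float = 2.0
    d_call_rate: float = 0.9
    morbidity_coupling: float = 1.5
    morbidity_noise_sd: float = 0.5
    junction_mutation_rate: float = 0.0
    fraction_unproductive: float = 0.0
    n_v: int = 20
    n_d: int = 10
    n_j: int = 4
    seed: int = 0

    def validate(self) -> None:
        for tissue, mix in self.isotype_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"isotype_mix[{tissue}] sums to {total}, not 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"isotype_mix[{tissue}] has negative entries")
        for name in ("alpha0", "usage_precision0", "morbidity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.shm_rate.values()):
            raise ValueError("shm_rate values must be >= 0")
        if self.seqs_per_sample < 0 or self.n_clones_base < 1:
            raise ValueError("seqs_per_sample >= 0 and n_clones_base >= 1 required")

    def diet_exposure_months(self, age_months: float, diet: str) -> dict[str, float]:
        """Months spent under each feeding regime since randomisation at 3 mo."""
        if diet == "AL_DR16M":
            m_al = max(0.0, min(age_months, 16) - 3)
            m_dr = max(0.0, age_months - 16)
            return {"AL": m_al, "DR": m_dr}
        return {diet: max(0.0, age_months - 3)}

    def _decay(self, age_months: float, diet: str, slopes: dict[str, float]) -> float:
        return sum(
            slopes.get(d, 0.0) * m
            for d, m in self.diet_exposure_months(age_months, diet).items()
        )

    def concentration(self, age_months: float, diet: str) -> float:
        """Dirichlet concentration per clone; smaller = more skewed."""
        return self.alpha0 * np.exp(-self._decay(age_months, diet, self.expansion_slope))

    def usage_precision(self, age_months: float, diet: str) -> float:
        return self.usage_precision0 * np.exp(
            -self._decay(age_months, diet, self.usage_idiosyncrasy)
        )


@dataclass
class GroundTruth:
    """Planted truth for one sample."""

    sample_id: str
    clone_of_seq: np.ndarray          # int clone index per emitted sequence
    clone_probs: np.ndarray           # true clone relative sizes (length C)
    clone_counts: np.ndarray          # realised clone counts (length C)
    v_usage: np.ndarray
    d_usage: np.ndarray
    j_usage: np.ndarray
    n_syn: np.ndarray                 # planted synonymous mutations per sequence
    n_nonsyn: np.ndarray
    true_p20: float                   # top-20 mass of clone_probs
    concentration: float


@dataclass
class CohortData:
    spec: CohortSpec
    design: pd.DataFrame
    germline: dict[str, str]
    samples: dict[str, pd.DataFrame]
    truths: dict[str, GroundTruth]
    pathology: list[PathologyRecord]


def make_germline_reference(
    n_v: int, n_d: int, n_j: int, seed: int
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random germline V/D/J reference.

    V segments are 252-300 nt, J segments 42-60 nt, both multiples of 3 and
    built from sense codons so the assembled V-junction-J sequence has a
    clean reading frame at offset 0; D segments are 10-30 nt labels only
    (the simulator does not embed D in the assembled sequence). Deterministic
    given the seed; gene names carry a *01 allele suffix.
    """
    if n_v < 2 or n_j < 2:
        raise ValueError("need at least 2 V genes and 2 J genes to define clones")
    if n_d < 0:
        raise ValueError("n_d must be >= 0")
    rng = substream(seed, "germline")
    genes: dict[str, str] = {}
    rows = []

    def _coding(length_nt: int) -> str:
        idx = rng.integers(0, len(SENSE_CODONS), size=length_nt // 3)
        return "".join(SENSE_CODONS[i] for i in idx)

    for i in range(n_v):
        length = 3 * int(rng.integers(84, 101))  # 252..300 nt
        name = f"IGHV{i + 1}*01"
        genes[name] = _coding(length)
        rows.append((name, "V", length))
    for i in range(n_d):
        length = int(rng.integers(10, 31))
        name = f"IGHD{i + 1}*01"
        genes[name] = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        rows.append((name, "D", length))
    for i in range(n_j):
        length = 3 * int(rng.integers(14, 21))  # 42..60 nt
        name = f"IGHJ{i + 1}*01"
        genes[name] = _coding(length)
        rows.append((name, "J", length))
    lengths = pd.DataFrame(rows, columns=["gene", "segment", "length_nt"])
    return genes, lengths


def population_usage(spec: CohortSpec, seed: int) -> dict[str, np.ndarray]:
    """Fixed, non-uniform population-level V/D/J usage vectors."""
    rng = substream(seed, "population_usage")
    return {
        "v": rng.dirichlet(np.full(spec.n_v, 3.0)),
        "d": rng.dirichlet(np.full(spec.n_d, 3.0)) if spec.n_d else np.array([]),
        "j": rng.dirichlet(np.full(spec.n_j, 3.0)),
    }


def build_design(spec: CohortSpec) -> pd.DataFrame:
    """Cross-sectional design table; AL_DR16M groups exist only from 16 mo."""
    rows = []
    for diet in spec.diets:
        for age in spec.ages:
            if diet == "AL_DR16M" and age < 16:
                continue
            for i in range(spec.n_mice_per_group):
                mouse = f"{diet}_{age}m_m{i + 1}"
                for tissue in spec.tissues:
                    rows.append(
                        {
                            "sample_id": f"{mouse}_{tissue}",
                            "mouse_id": mouse,
                            "tissue": tissue,
                            "diet": diet,
                            "age_months": age,
                        }
                    )
    return pd.DataFrame(rows)


_CYS_CODONS = ("TGT", "TGC")  # junctions start with the conserved Cys
_TRP_CODON = "TGG"            # and end with the conserved Trp

# codon -> amino acid, standard code (built once, stops as '*')
from Bio.Data.CodonTable import standard_dna_table as _std_table

CODON_TO_AA = dict(_std_table.forward_table)
for _s in _std_table.stop_codons:
    CODON_TO_AA[_s] = "*"


def _random_junction(rng: np.random.Generator, aa_len: int) -> str:
    """Random in-frame junction: Cys + (aa_len-2) sense codons + Trp."""
    inner = rng.integers(0, len(SENSE_CODONS), size=aa_len - 2)
    return (
        _CYS_CODONS[int(rng.integers(0, 2))]
        + "".join(SENSE_CODONS[i] for i in inner)
        + _TRP_CODON
    )


def _translate(nt: str) -> str:
    return "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, len(nt) - 2, 3))


def generate_sample(
    spec: CohortSpec,
    meta: dict,
    germline: dict[str, str],
    pop_usage: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one sample's rearrangement table and its ground truth.

    ``meta`` needs keys sample_id, tissue, diet, age_months. Sequences carry
    full V-junction-J alignments (observed and germline), an in-frame
    junction, planted SHM outside the junction, and an extra
    ``junction_start`` column giving the 0-based junction offset in the
    alignment (preserved by the reader as an opaque annotation).
    """
    spec.validate()
    sid = meta["sample_id"]
    tissue, diet, age = meta["tissue"], meta["diet"], meta["age_months"]
    n = int(spec.seqs_per_sample)
    C = int(spec.n_clones_base)

    alpha = spec.concentration(age, diet)
    probs = rng.dirichlet(np.full(C, alpha))
    counts = rng.multinomial(n, probs) if n else np.zeros(C, dtype=int)
    true_p20 = float(np.sort(probs)[::-1][:20].sum())

    kappa = spec.usage_precision(age, diet)
    v_usage = rng.dirichlet(kappa * pop_usage["v"] + 1e-9)
    j_usage = rng.dirichlet(kappa * pop_usage["j"] + 1e-9)
    d_usage = (
        rng.dirichlet(kappa * pop_usage["d"] + 1e-9)
        if len(pop_usage["d"])
        else np.array([])
    )

    v_names = [g for g in germline if g.startswith("IGHV")]
    d_names = [g for g in germline if g.startswith("IGHD")]
    j_names = [g for g in germline if g.startswith("IGHJ")]

    # per-clone gene assignments and junctions
    v_of_clone = rng.choice(len(v_names), size=C, p=v_usage)
    j_of_clone = rng.choice(len(j_names), size=C, p=j_usage)
    d_present = rng.random(C) < spec.d_call_rate
    d_of_clone = (
        rng.choice(len(d_names), size=C, p=d_usage)
        if len(d_names)
        else np.zeros(C, dtype=int)
    )
    aa_lens = np.clip(
        np.rint(rng.normal(spec.cdr3_length_mean_aa, spec.cdr3_length_sd_aa, size=C)),
        8,
        24,
    ).astype(int)
    junctions = [_random_junction(rng, int(L)) for L in aa_lens]

    clone_of_seq = np.repeat(np.arange(C), counts)
    rng.shuffle(clone_of_seq)
    n = len(clone_of_seq)

    iso_names = list(spec.isotype_mix[tissue])
    iso_p = np.array([spec.isotype_mix[tissue][k] for k in iso_names])
    iso_idx = rng.choice(len(iso_names), size=n, p=iso_p)
    isotypes = np.array(iso_names, dtype=object)[iso_idx]

    consensus = rng.geometric(0.7, size=n)
    lam = np.array([spec.shm_rate.get(k, 0.0) for k in iso_names])[iso_idx]
    n_mut = rng.poisson(lam)

    # assemble per-clone germline strings once
    germ_of_clone = [
        germline[v_names[v_of_clone[c]]] + junctions[c] + germline[j_names[j_of_clone[c]]]
        for c in range(C)
    ]
    v_len_of_clone = np.array([len(germline[v_names[i]]) for i in v_of_clone])
    jn_len_of_clone = np.array([len(j) for j in junctions])

    seq_align = np.empty(n, dtype=object)
    n_syn = np.zeros(n, dtype=int)
    n_nonsyn = np.zeros(n, dtype=int)
    mutated_junctions = np.empty(n, dtype=object)

    # pre-draw all mutation randomness in bulk; positions are sampled with
    # replacement and deduplicated (collisions are negligible at these rates)
    germ_len_of_clone = np.array([len(g) for g in germ_of_clone])
    nonjn_len = (germ_len_of_clone - jn_len_of_clone)[clone_of_seq]
    seq_of_mut = np.repeat(np.arange(n), n_mut)
    raw_pos = np.floor(rng.random(len(seq_of_mut)) * nonjn_len[seq_of_mut]).astype(int)
    base_shift = rng.integers(1, 4, size=len(seq_of_mut))
    mut_start = np.zeros(n + 1, dtype=int)
    np.cumsum(n_mut, out=mut_start[1:])

    base_index = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
    for i in range(n):
        c = clone_of_seq[i]
        germ = germ_of_clone[c]
        jn_start = int(v_len_of_clone[c])
        jn_end = jn_start + int(jn_len_of_clone[c])
        obs = bytearray(germ, "ascii")
        lo, hi = mut_start[i], mut_start[i + 1]
        if hi > lo:
            raw = raw_pos[lo:hi]
            pos = np.unique(np.where(raw >= jn_start, raw + (jn_end - jn_start), raw))
            for k, p in enumerate(pos):
                new = int(BASES[(base_index[obs[p]] + base_shift[lo + k]) % 4])
                cs = 3 * (p // 3)
                germ_codon = germ[cs : cs + 3]
                mut_codon = (
                    germ_codon[: p - cs] + chr(new) + germ_codon[p - cs + 1 :]
                )
                if CODON_TO_AA[germ_codon] == CODON_TO_AA[mut_codon]:
                    n_syn[i] += 1
                else:
                    n_nonsyn[i] += 1
                obs[p] = new
        jn = junctions[c]
        if spec.junction_mutation_rate > 0:
            k = rng.poisson(spec.junction_mutation_rate)
            jn_b = bytearray(jn, "ascii")
            for p in rng.integers(0, len(jn_b), size=k):
                jn_b[p] = int(BASES[(base_index[jn_b[p]] + int(rng.integers(1, 4))) % 4])
                obs[jn_start + p] = jn_b[p]
            jn = jn_b.decode()
        mutated_junctions[i] = jn
        seq_align[i] = obs.decode()

    junction_nt = mutated_junctions
    junction_aa = np.array([_translate(j) for j in junction_nt], dtype=object)

    productive = np.ones(n, dtype=bool)
    if spec.fraction_unproductive > 0 and n:
        knock = rng.random(n) < spec.fraction_unproductive
        productive[knock] = False
        for i in np.flatnonzero(knock):
            # frameshifted junction: drop one nucleotide
            junction_nt[i] = junction_nt[i][:-1]
            junction_aa[i] = ""

    df = pd.DataFrame(
        {
            "sequence_id": [f"{sid}_seq{i:05d}" for i in range(n)],
            "sample_id": sid,
            "v_call": [v_names[v_of_clone[c]] for c in clone_of_seq],
            "d_call": [
                d_names[d_of_clone[c]] if d_present[c] and d_names else ""
                for c in clone_of_seq
            ],
            "j_call": [j_names[j_of_clone[c]] for c in clone_of_seq],
            "junction": junction_nt,
            "junction_aa": junction_aa,
            "isotype": isotypes,
            "sequence_alignment": seq_align,
            "germline_alignment": [germ_of_clone[c] for c in clone_of_seq],
            "productive": productive,
            "consensus_count": consensus,
            "junction_start": [int(v_len_of_clone[c]) for c in clone_of_seq],
        }
    )
    truth = GroundTruth(
        sample_id=sid,
        clone_of_seq=clone_of_seq,
        clone_probs=probs,
        clone_counts=counts,
        v_usage=v_usage,
        d_usage=d_usage,
        j_usage=j_usage,
        n_syn=n_syn,
        n_nonsyn=n_nonsyn,
        true_p20=true_p20,
        concentration=alpha,
    )
    return df, truth


def generate_morbidity(
    drivers: dict[str, float],
    coupling: float,
    noise_sd: float,
    rng: np.random.Generator,
    vocabulary: tuple[str, ...] = FINDINGS_VOCABULARY,
) -> list[PathologyRecord]:
    """Pathology records coupled to a per-mouse expansion driver.

    The latent score is ``coupling * z(driver) + N(0, noise_sd)``; it is
    mapped monotonically to a tumor-organ count (0/1/2) and a nested count
    of non-neoplastic findings (0..len(vocabulary)), so a larger planted
    clonal expansion always means an equal-or-worse necropsy.
    """
    mice = sorted(drivers)
    x = np.array([drivers[m] for m in mice], dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    score = coupling * z + rng.normal(0.0, noise_sd, size=len(mice))

    records = []
    for mouse, s in zip(mice, score):
        organs = 0 if s < 0.7 else (1 if s < 1.4 else 2)
        burden = int(np.clip(np.floor(2.0 + 1.6 * s), 0, len(vocabulary)))
        records.append(PathologyRecord(mouse, organs, tuple(vocabulary[:burden])))
    return records


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Full synthetic cohort: design, germline, samples, truth, pathology.

    Deterministic for a given (spec, spec.seed): every sample and stage uses
    an independent named substream of the cohort seed.
    """
    spec.validate()
    design = build_design(spec)
    germline, _ = make_germline_reference(spec.n_v, spec.n_d, spec.n_j, spec.seed)
    pop = population_usage(spec, spec.seed)

    samples: dict[str, pd.DataFrame] = {}
    truths: dict[str, GroundTruth] = {}
    for _, meta in design.iterrows():
        rng = substream(spec.seed, "sample", meta["sample_id"])
        df, truth = generate_sample(spec, dict(meta), germline, pop, rng)
        samples[meta["sample_id"]] = df
        truths[meta["sample_id"]] = truth

    # morbidity driven by the planted expansion of each mouse's first tissue
    primary_tissue = spec.tissues[0]
    drivers = {
        meta["mouse_id"]: truths[meta["sample_id"]].true_p20
        for _, meta in design.iterrows()
        if meta["tissue"] == primary_tissue
    }
    pathology = generate_morbidity(
        drivers,
        spec.morbidity_coupling,
        spec.morbidity_noise_sd,
        substream(spec.seed, "morbidity"),
    )
    return CohortData(spec, design, germline, samples, truths, pathology)


def write_cohort(cohort: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the dialects the readers accept; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "rearrangements": outdir / "rearrangements.tsv",
        "germline": outdir / "germline.fasta",
        "design": outdir / "cohort_design.csv",
        "pathology": outdir / "pathology.csv",
    }
    airr_io.write_rearrangements(cohort.samples, paths["rearrangements"])
    airr_io.write_germline_fasta(cohort.germline, paths["germline"])
    airr_io.write_cohort_design(cohort.design, paths["design"])
    airr_io.write_pathology(cohort.pathology, paths["pathology"])
    return paths
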