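"""Reading and writing of the pipeline's external formats.

Rearrangement tables follow the AIRR Rearrangement TSV dialect (tab
separated, header row, one row per UMI-consensus sequence). Unknown columns
are preserved untouched. Germline references are plain FASTA. Pathology and
cohort-design tables are CSV.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .morbidity import FINDINGS_VOCABULARY, PathologyRecord

__all__ = [
    "AirrFormatError",
    "RearrangementTables",
    "MANDATORY_COLUMNS",
    "ISOTYPE_CLASSES",
    "collapse_isotype",
    "read_rearrangements",
    "write_rearrangements",
    "read_germline_fasta",
    "write_germline_fasta",
    "read_pathology",
    "write_pathology",
    "read_cohort_design",
    "write_cohort_design",
]

ISOTYPE_CLASSES = ("IgM", "IgD", "IgG", "IgE", "IgA")

#: Minimal column set the analysis requires (AIRR names; `sample_id` and
#: `isotype` are the study-level additions carried alongside).
MANDATORY_COLUMNS = (
    "sequence_id",
    "sample_id",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "isotype",
    "sequence_alignment",
    "germline_alignment",
    "productive",
    "consensus_count",
)

VALID_TISSUES = ("spleen", "ileum")
VALID_DIETS = ("AL", "DR", "AL_DR16M")
VALID_AGES = (5, 16, 20, 24)


class AirrFormatError(ValueError):
    """A table does not conform to the expected dialect."""


@dataclass
class RearrangementTables:
    """Rearrangements grouped by sample, plus per-row rejection report."""

    samples: dict[str, pd.DataFrame]
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["line", "sequence_id", "reason"])
    )

    def __len__(self) -> int:
        return sum(len(df) for df in self.samples.values())


_ISOTYPE_PREFIXES = {
    "IGHM": "IgM", "IGM": "IgM", "IGHD": "IgD", "IGD": "IgD",
    "IGHG": "IgG", "IGG": "IgG", "IGHE": "IgE", "IGE": "IgE",
    "IGHA": "IgA", "IGA": "IgA",
}


def collapse_isotype(call: str) -> str | None:
    """Collapse a constant-region call to one of the five isotype classes.

    Sub-isotypes collapse to their class (IghG1, IGHG2b -> IgG). Returns
    None for empty or unrecognisable calls.
    """
    if not isinstance(call, str) or not call.strip():
        return None
    c = call.strip()
    if c in ISOTYPE_CLASSES:
        return c
    cu = c.upper().replace("-", "").replace("*", "")
    for prefix in sorted(_ISOTYPE_PREFIXES, key=len, reverse=True):
        if cu.startswith(prefix):
            return _ISOTYPE_PREFIXES[prefix]
    return None


def _parse_bool(x) -> bool | None:
    if isinstance(x, bool):
        return x
    s = str(x).strip().upper()
    if s in ("T", "TRUE", "1"):
        return True
    if s in ("F", "FALSE", "0"):
        return False
    return None


def read_rearrangements(
    path: str | Path | io.IOBase,
    filter_productive: bool = True,
    column_map: dict[str, str] | None = None,
    collapse_duplicate_junctions: bool = False,
) -> RearrangementTables:
    """Read an AIRR rearrangement TSV, validate rows, group by sample.

    Parameters
    ----------
    path
        TSV file with a header row naming at least :data:`MANDATORY_COLUMNS`
        (after applying ``column_map``). Unknown columns are preserved.
    filter_productive
        Drop rows with ``productive == False`` (the default analysis mode).
    column_map
        Mapping from column names in the file to the canonical AIRR names,
        for tables written in another dialect (e.g. ``{"c_call": "isotype"}``).
    collapse_duplicate_junctions
        If True, keep a single row per (sample_id, v_call, j_call, junction)
        with consensus counts summed. Off by default.

    Returns
    -------
    RearrangementTables
        ``samples`` maps sample_id to its validated DataFrame; ``rejected``
        lists malformed rows with their 1-based file line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise AirrFormatError(f"missing mandatory column(s): {missing}")

    # 1-based file line of each row (header is line 1)
    df = df.reset_index(drop=True)
    lines = df.index + 2

    df["isotype"] = df["isotype"].map(lambda c: collapse_isotype(c) or "")
    df["consensus_count"] = pd.to_numeric(df["consensus_count"], errors="coerce")
    prod = df["productive"].map(_parse_bool)

    reasons = pd.Series("", index=df.index)
    bad_len = df["sequence_alignment"].str.len() != df["germline_alignment"].str.len()
    reasons[bad_len] = "sequence_alignment and germline_alignment differ in length"
    bad_count = df["consensus_count"].isna() | (df["consensus_count"] < 1)
    reasons[bad_count & (reasons == "")] = "consensus_count must be a positive integer"
    bad_prod = prod.isna()
    reasons[bad_prod & (reasons == "")] = "unparseable productive flag"
    bad_junc = prod.fillna(False).astype(bool) & (df["junction"].str.len() % 3 != 0)
    reasons[bad_junc & (reasons == "")] = (
        "junction length not a multiple of 3 on a productive row"
    )

    bad = reasons != ""
    rejected = pd.DataFrame(
        {
            "line": lines[bad],
            "sequence_id": df.loc[bad, "sequence_id"].values,
            "reason": reasons[bad].values,
        }
    ).reset_index(drop=True)
    if len(rejected):
        warnings.warn(
            f"rejected {len(rejected)} malformed row(s); first: line "
            f"{rejected['line'].iloc[0]}: {rejected['reason'].iloc[0]}",
            stacklevel=2,
        )

    df = df[~bad].copy()
    df["productive"] = prod[~bad].astype(bool)
    df["consensus_count"] = df["consensus_count"].astype(int)

    if filter_productive:
        df = df[df["productive"]].copy()

    if collapse_duplicate_junctions and len(df):
        key = ["sample_id", "v_call", "j_call", "junction"]
        agg = {c: "first" for c in df.columns if c not in key}
        agg["consensus_count"] = "sum"
        df = df.groupby(key, as_index=False, sort=False).agg(agg)
        # restore original column order
        df = df[[c for c in list(dict.fromkeys(list(agg) + key + list(df.columns)))
                 if c in df.columns]]

    samples: dict[str, pd.DataFrame] = {
        sid: g.reset_index(drop=True) for sid, g in df.groupby("sample_id", sort=True)
    }
    for sid, g in samples.items():
        if filter_productive and not len(g):
            warnings.warn(f"sample {sid}: zero productive records", stacklevel=2)
    return RearrangementTables(samples=samples, rejected=rejected)


def write_rearrangements(
    samples: dict[str, pd.DataFrame] | pd.DataFrame, path: str | Path
) -> None:
    """Write rearrangements (grouped dict or flat table) as AIRR TSV."""
    if isinstance(samples, dict):
        df = pd.concat(samples.values(), ignore_index=True) if samples else pd.DataFrame(
            columns=list(MANDATORY_COLUMNS)
        )
    else:
        df = samples
    out = df.copy()
    if "productive" in out.columns and out["productive"].dtype != object:
        out["productive"] = out["productive"].map({True: "T", False: "F"})
    out.to_csv(path, sep="\t", index=False)


def read_germline_fasta(path: str | Path) -> dict[str, str]:
    """Germline V/D/J reference: FASTA name -> uppercase nucleotide string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_germline_fasta(genes: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genes.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pathology(
    path: str | Path | io.IOBase,
    vocabulary: tuple[str, ...] = FINDINGS_VOCABULARY,
) -> list[PathologyRecord]:
    """Read the per-animal pathology CSV.

    Two layouts are accepted: a ``findings`` column with ``;``-delimited
    labels, or one 0/1 column per vocabulary label. Unknown labels, duplicate
    mouse ids and negative tumor counts are errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("mouse_id", "n_tumor_organs"):
        if col not in df.columns:
            raise AirrFormatError(f"pathology table missing column: {col}")
    if df["mouse_id"].duplicated().any():
        dup = df.loc[df["mouse_id"].duplicated(), "mouse_id"].iloc[0]
        raise ValueError(f"duplicate mouse_id in pathology table: {dup}")

    indicator_cols = [c for c in df.columns if c in vocabulary]
    records = []
    for _, row in df.iterrows():
        n_tumor = int(row["n_tumor_organs"])
        if n_tumor < 0:
            raise ValueError(f"mouse {row['mouse_id']}: negative tumor-organ count")
        if "findings" in df.columns:
            labels = [t.strip() for t in row["findings"].split(";") if t.strip()]
        else:
            labels = [c for c in indicator_cols if str(row[c]).strip() in ("1", "T", "True")]
        unknown = [l for l in labels if l not in vocabulary]
        if unknown:
            raise ValueError(
                f"mouse {row['mouse_id']}: unknown finding label(s): {unknown}"
            )
        records.append(PathologyRecord(row["mouse_id"], n_tumor, tuple(labels)))
    return records


def write_pathology(records: list[PathologyRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "mouse_id": [r.mouse_id for r in records],
            "n_tumor_organs": [r.n_tumor_organs for r in records],
            "findings": ["; ".join(r.non_neoplastic_findings) for r in records],
        }
    ).to_csv(path, index=False)


def read_cohort_design(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Cohort design CSV: sample_id, mouse_id, tissue, diet, age_months."""
    df = pd.read_csv(path, dtype={"age_months": int})
    required = ("sample_id", "mouse_id", "tissue", "diet", "age_months")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AirrFormatError(f"cohort design missing column(s): {missing}")
    bad_tissue = ~df["tissue"].isin(VALID_TISSUES)
    bad_diet = ~df["diet"].isin(VALID_DIETS)
    bad_age = ~df["age_months"].isin(VALID_AGES)
    for mask, what in ((bad_tissue, "tissue"), (bad_diet, "diet"), (bad_age, "age_months")):
        if mask.any():
            raise ValueError(f"invalid {what}: {df.loc[mask, what].unique().tolist()}")
    # diet switch happens at 16 months; the switched group cannot exist earlier
    early_switch = (df["diet"] == "AL_DR16M") & (df["age_months"] < 16)
    if early_switch.any():
        raise ValueError("AL_DR16M samples are only valid at ages >= 16 months")
    return df


def write_cohort_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, index=False)
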