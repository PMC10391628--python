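"""End-to-end pipeline: simulate -> clones -> diversity -> RDI -> SHM ->
morbidity -> cohort statistics, as one reproducible, seeded run.

Every stage reads its parameters from the RunConfig only; the config is
serialized verbatim into the output directory together with a manifest
(package and library versions, seed, parameter hash, per-stage record
counts). All randomness flows through named substreams of the single run
seed, so changing e.g. the bootstrap count of one stage does not perturb
any other stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import airr_io, cohort_stats, diversity, maturation, rdi
from .clones import ClonePartition, assign_clones_identity, assign_clones_threshold, distance_to_nearest, find_threshold
from .morbidity import morbidity_table
from .simulate import CohortSpec, generate_cohort, write_cohort
from .util import substream

__all__ = ["RunConfig", "run"]

log = logging.getLogger("bcrep")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (the single source of truth)."""

    outdir: str = "bcrep_run"
    seed: int = 0
    # input: either a directory with rearrangements.tsv/cohort_design.csv/
    # pathology.csv, or None to simulate
    input_dir: str | None = None
    simulate: dict = field(default_factory=dict)  # CohortSpec overrides
    clone_mode: str = "identity"                  # identity | threshold
    threshold_fallback: float = 0.1
    weight_by_consensus: bool = False
    q_grid: tuple[float, ...] = (0.0, 1.0, 2.0)
    depth_policy: str = "min_sample_size"
    diversity_depth: int | None = None
    n_boot: int = 200
    per_isotype: bool = True
    rdi_depth: int | None = None
    rdi_n_repeats: int = 100
    rdi_normalization: str = "proportions"
    shm_frame_offset: int = 0
    shm_min_mutations: int = 1
    bonferroni_scope: str = "per outcome panel (correlations); all timepoint tests (Mann-Whitney)"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.q_grid = tuple(float(q) for q in cfg.q_grid)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self._as_plain(), fh, sort_keys=True)

    def _as_plain(self) -> dict:
        d = asdict(self)
        d["q_grid"] = list(self.q_grid)
        return d

    def parameter_hash(self) -> str:
        payload = {k: v for k, v in self._as_plain().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        # default pipeline cohort: 3 diets x 3 post-switch ages x 5 mice
        params = {"ages": (16, 20, 24), "seed": self.seed}
        params.update(self.simulate)
        if isinstance(params.get("ages"), list):
            params["ages"] = tuple(params["ages"])
        for key in ("diets", "tissues"):
            if isinstance(params.get(key), list):
                params[key] = tuple(params[key])
        return CohortSpec(**params)


def _load_inputs(config: RunConfig, outdir: Path, manifest: dict):
    if config.input_dir is None:
        spec = config.cohort_spec()
        cohort = generate_cohort(spec)
        write_cohort(cohort, outdir / "input")
        manifest["stage_counts"]["simulate"] = {
            "samples": len(cohort.samples),
            "sequences": sum(len(df) for df in cohort.samples.values()),
        }
        samples = cohort.samples
        # apply the same productive filter real inputs get
        samples = {
            sid: df[df["productive"]].reset_index(drop=True) for sid, df in samples.items()
        }
        design = cohort.design
        pathology = cohort.pathology
        germline = cohort.germline
    else:
        indir = Path(config.input_dir)
        tables = airr_io.read_rearrangements(
            indir / "rearrangements.tsv", filter_productive=True
        )
        manifest["stage_counts"]["read"] = {
            "samples": len(tables.samples),
            "sequences": len(tables),
            "rejected_rows": len(tables.rejected),
        }
        samples = tables.samples
        design = airr_io.read_cohort_design(indir / "cohort_design.csv")
        pathology = airr_io.read_pathology(indir / "pathology.csv")
        gpath = indir / "germline.fasta"
        germline = airr_io.read_germline_fasta(gpath) if gpath.exists() else {}
    return samples, design, pathology, germline


def _assign_all_clones(
    samples: dict[str, pd.DataFrame], config: RunConfig, manifest: dict
) -> dict[str, ClonePartition]:
    parts: dict[str, ClonePartition] = {}
    thresholds = {}
    for sid, df in samples.items():
        try:
            if config.clone_mode == "identity":
                parts[sid] = assign_clones_identity(df)
            elif config.clone_mode == "threshold":
                dists = distance_to_nearest(df)
                res = find_threshold(dists.to_numpy(), fallback=config.threshold_fallback)
                thresholds[sid] = {
                    "threshold": res.threshold,
                    "fallback_used": res.fallback_used,
                }
                parts[sid] = assign_clones_threshold(df, res.threshold)
            else:
                raise ValueError(f"unknown clone_mode: {config.clone_mode!r}")
        except Exception as exc:
            raise RuntimeError(f"clone assignment failed for sample {sid}: {exc}") from exc
    manifest["stage_counts"]["clones"] = {
        sid: int(len(p.clones)) for sid, p in parts.items()
    }
    if thresholds:
        manifest["thresholds"] = thresholds
    return parts


def _isotype_slices(df: pd.DataFrame):
    yield "all", df
    for iso in airr_io.ISOTYPE_CLASSES:
        sub = df[df["isotype"] == iso]
        if len(sub):
            yield iso, sub


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "clone_mode": config.clone_mode,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": {},
        "substreams": ["diversity/<sample>", "rdi/<sample>"],
    }
    try:
        from importlib.metadata import version

        manifest["versions"]["bcrep"] = version("bcrep")
    except Exception:
        manifest["versions"]["bcrep"] = "unknown"

    samples, design, pathology, germline = _load_inputs(config, outdir, manifest)
    meta = design.set_index("sample_id", drop=False)

    # ---- clones -----------------------------------------------------------
    partitions = _assign_all_clones(samples, config, manifest)
    pd.concat([p.clones for p in partitions.values()], ignore_index=True).to_csv(
        outdir / "clones.tsv", sep="\t", index=False
    )

    # ---- diversity & P20 (per sample and per isotype) ---------------------
    sizes = {sid: len(df) for sid, df in samples.items()}
    if config.diversity_depth is not None:
        div_depth = {sid: config.diversity_depth for sid in samples}
    else:
        # uniform depth per tissue so ages and diets stay comparable
        depth_by_tissue = {
            t: min(sizes[s] for s in sizes if meta.loc[s, "tissue"] == t)
            for t in meta["tissue"].unique()
        }
        div_depth = {sid: depth_by_tissue[meta.loc[sid, "tissue"]] for sid in samples}
        log.info("diversity subsample depth per tissue: %s", depth_by_tissue)
        manifest["diversity_depth_by_tissue"] = {
            str(k): int(v) for k, v in depth_by_tissue.items()
        }

    div_rows, p20_rows = [], []
    profile_rows: dict[str, dict] = {sid: {"sample_id": sid} for sid in samples}
    for sid, df in samples.items():
        part = partitions[sid]
        labels_all = part.assignments
        for iso, sub in _isotype_slices(df):
            ids = sub["sequence_id"][sub["sequence_id"].isin(labels_all.index)]
            labels = labels_all.loc[ids]
            depth = min(div_depth[sid], len(labels))
            if len(labels) == 0:
                continue
            spec_rng = substream(config.seed, "diversity", sid, iso)
            sp = diversity.diversity_with_resampling(
                labels, config.q_grid, depth, config.n_boot, spec_rng, sample_id=sid
            )
            div_rows.append(sp.to_frame(isotype=iso))
            sizes_iso = labels.groupby(labels).size()
            ranked = sizes_iso.sort_index().sort_values(ascending=False, kind="stable")
            freqs = ranked.to_numpy(float) / ranked.sum()
            p20_rows.append(
                {
                    "sample_id": sid,
                    "isotype": iso,
                    "p20": float(freqs[:20].sum()),
                    "n_clones": len(freqs),
                    "n_records": int(len(labels)),
                }
            )
            if iso == "all":
                for q, val in zip(sp.q, sp.mean_qd):
                    profile_rows[sid][f"hill_q{q:g}"] = float(val)
                profile_rows[sid]["p20"] = float(freqs[:20].sum())
            if not config.per_isotype:
                break
    pd.concat(div_rows, ignore_index=True).to_csv(
        outdir / "diversity.tsv", sep="\t", index=False
    )
    pd.DataFrame(p20_rows).to_csv(outdir / "p20.tsv", sep="\t", index=False)

    # ---- RDI --------------------------------------------------------------
    by_tissue = {
        t: {s: samples[s] for s in samples if meta.loc[s, "tissue"] == t}
        for t in meta["tissue"].unique()
    }
    features = rdi.FeatureSpace.from_germline(germline) if germline else None
    long_parts, matrix_parts = [], []
    for tissue, tset in by_tissue.items():
        if len(tset) < 2:
            continue
        depth = config.rdi_depth
        if depth is not None:
            too_small = [s for s, df in tset.items() if len(df) < depth]
            if len(too_small) == len(tset) or len(tset) - len(too_small) < 2:
                raise RuntimeError(
                    f"rdi: depth {depth} exceeds the size of sample(s) "
                    f"{sorted(too_small)}"
                )
        dm = rdi.rdi_matrix(
            tset,
            depth=depth,
            n_repeats=config.rdi_n_repeats,
            seed=config.seed,
            normalization=config.rdi_normalization,
            features=features,
        )
        long_parts.append(dm.to_long())
        matrix_parts.append(dm.to_frame())
        groups = {
            s: f"{meta.loc[s, 'diet']}@{meta.loc[s, 'age_months']}" for s in dm.sample_ids
        }
        wg = rdi.within_group_mean(dm, groups)
        for _, row in wg.iterrows():
            profile_rows[row["sample_id"]]["rdi_within_group"] = row["rdi_within_group"]
        manifest["stage_counts"].setdefault("rdi", {})[str(tissue)] = {
            "depth": int(dm.depth),
            "n_samples": len(dm.sample_ids),
            "excluded": list(dm.excluded),
        }
    if long_parts:
        pd.concat(long_parts, ignore_index=True).to_csv(
            outdir / "rdi_long.tsv", sep="\t", index=False
        )
        pd.concat(matrix_parts).to_csv(outdir / "rdi_matrix.tsv", sep="\t")

    # ---- SHM, CSR staging, isotype, CDR3 ----------------------------------
    shm_parts, stage_parts, iso_rows, cdr3_rows = [], [], [], []
    for sid, df in samples.items():
        shm = maturation.shm_table(df, frame_offset=config.shm_frame_offset)
        shm_parts.append(shm)
        stage_parts.append(
            maturation.stage_clones(
                df, partitions[sid].assignments, shm, config.shm_min_mutations
            )
        )
        frac = maturation.isotype_fractions(df, config.weight_by_consensus)
        iso_rows.append({"sample_id": sid, **{f"frac_{k}": v for k, v in frac.items()}})
        lengths = df.loc[df["junction_aa"].str.len() > 0, "junction_aa"].str.len()
        st = maturation.cdr3_gaussian(lengths, sample_id=sid)
        cdr3_rows.append(
            {"sample_id": sid, "cdr3_mean": st.mean_aa, "cdr3_sd": st.sd_aa, "n": st.n}
        )
        profile_rows[sid].update(
            freq_syn=float(shm["freq_syn"].mean()),
            freq_nonsyn=float(shm["freq_nonsyn"].mean()),
            cdr3_mean=st.mean_aa,
            cdr3_sd=st.sd_aa,
            **{f"frac_{k}": float(v) for k, v in frac.items()},
        )
        stages = stage_parts[-1]["stage"].value_counts(normalize=True)
        for stage in maturation.STAGES:
            profile_rows[sid][f"stage_{stage}"] = float(stages.get(stage, 0.0))
    pd.concat(shm_parts, ignore_index=True).to_csv(outdir / "shm.tsv", sep="\t", index=False)
    pd.concat(stage_parts, ignore_index=True).to_csv(
        outdir / "clone_stages.tsv", sep="\t", index=False
    )
    pd.DataFrame(iso_rows).to_csv(outdir / "isotype.tsv", sep="\t", index=False)
    pd.DataFrame(cdr3_rows).to_csv(outdir / "cdr3.tsv", sep="\t", index=False)

    # ---- morbidity --------------------------------------------------------
    morb = morbidity_table(pathology)
    morb.to_csv(outdir / "morbidity.tsv", sep="\t", index=False)

    # ---- metric table and statistics --------------------------------------
    profiles = pd.DataFrame(list(profile_rows.values()))
    table = cohort_stats.build_metric_table(profiles, design, morb)
    table.to_csv(outdir / "metric_table.tsv", sep="\t", index=False)

    metric_cols = [
        c
        for c in profiles.columns
        if c != "sample_id" and pd.api.types.is_numeric_dtype(profiles[c])
    ]
    diets = [d for d in ("AL", "DR", "AL_DR16M") if d in set(design["diet"])]
    pairs = tuple(
        (diets[i], diets[k]) for i in range(len(diets)) for k in range(i + 1, len(diets))
    )
    cohort_stats.regression_table(table, metric_cols, diets=tuple(diets)).to_csv(
        outdir / "regression.tsv", sep="\t", index=False
    )
    cohort_stats.anova_table(table, metric_cols, diet_pairs=pairs).to_csv(
        outdir / "anova.tsv", sep="\t", index=False
    )
    cohort_stats.timepoint_table(table, metric_cols, diet_pairs=pairs).to_csv(
        outdir / "timepoint_tests.tsv", sep="\t", index=False
    )
    cohort_stats.morbidity_correlation(table, metric_cols).to_csv(
        outdir / "correlation.tsv", sep="\t", index=False
    )
    manifest["bonferroni_scope"] = config.bonferroni_scope

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
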