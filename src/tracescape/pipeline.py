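"""Seeded, configured, logged end-to-end runs.

A run config (YAML) names an input source — a synthetic cohort definition,
a trace table, or a serialized PWD stack — plus per-stage parameters, a
master seed and an output directory. ``run_pipeline`` executes the enabled
stages in dependency order (ensemble → pair correlation → locus metrics →
embedding), writes per-stage CSV artifacts, echoes every resolved parameter
to the log, and distils headline statistics into ``summary.json``.
"""

from __future__ import annotations

import difflib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import metrics as met
from . import similarity as sim
from .embedding import (
    cluster_composition,
    density_boundaries,
    embed_conformations,
    impute_per_category,
    leiden_partition,
    select_nuclei,
    stack_to_vectors,
)
from .io import read_library, read_pwd_stack, read_trace_table, serialize_pwd_stack
from .model import PWDStack, traces_to_pwd_stack
from .simulate import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "seed", "output_dir", "input", "stages"}
_INPUT_KEYS = {"synthetic", "stack", "trace_table", "library"}
_STAGE_KEYS = {"ensemble", "paircorr", "metrics", "embed"}
_STAGE_PARAM_KEYS = {
    "ensemble": {"enabled", "method", "bandwidth", "max_distance"},
    "paircorr": {"enabled", "min_detected", "min_overlap_frac", "n_shuffles"},
    "metrics": {
        "enabled", "intra_tad", "tad_pair", "rg_max_distance", "rg_min_frac",
        "is_cutoff", "contact_threshold", "n_boot",
    },
    "embed": {
        "enabled", "cutoffs", "n_neighbors", "min_dist", "n_epochs", "metric",
        "kde_bandwidth", "density_threshold", "diff_threshold", "resolution",
    },
}


class ValidationError(ValueError):
    pass


def _check_keys(given: dict, allowed: set[str], where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            suggestion = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ValidationError(f"unknown key {key!r} in {where}{suggestion}")


@dataclass
class RunConfig:
    """Validated run configuration."""

    raw: dict
    seed: int
    output_dir: Path
    input: dict
    stages: dict

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, _TOP_KEYS, "run config")
        if d.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
            raise ValidationError(f"unsupported schema_version {d['schema_version']}")
        inp = d.get("input", {})
        _check_keys(inp, _INPUT_KEYS, "input")
        if not inp:
            raise ValidationError("input section is required")
        stages = d.get("stages", {})
        _check_keys(stages, _STAGE_KEYS, "stages")
        for name, params in stages.items():
            _check_keys(params or {}, _STAGE_PARAM_KEYS[name], f"stages.{name}")
        if "seed" not in d:
            raise ValidationError("seed is mandatory")
        for key in ("stack", "trace_table", "library"):
            if key in inp and not Path(inp[key]).exists():
                raise ValidationError(f"input.{key} path does not exist: {inp[key]}")
        return cls(
            raw=d,
            seed=int(d["seed"]),
            output_dir=Path(d.get("output_dir", "tracescape_out")),
            input=inp,
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def stage_params(self, name: str) -> dict:
        p = dict(self.stages.get(name) or {})
        p.pop("enabled", None)
        return p

    def stage_enabled(self, name: str) -> bool:
        if name not in self.stages:
            return True  # all stages on by default
        return bool((self.stages[name] or {}).get("enabled", True))


def _load_stack(cfg: RunConfig) -> PWDStack:
    inp = cfg.input
    if "synthetic" in inp:
        regimes = inp["synthetic"]["regimes"]
        cfgs = []
        for k, r in enumerate(regimes):
            r = dict(r)
            if "tad_pair" in r:
                r.pop("tad_pair")
            r.setdefault("seed", cfg.seed + k)
            if "tad_blocks" in r:
                r["tad_blocks"] = tuple(
                    (t, tuple(rng)) for t, rng in r["tad_blocks"]
                )
            if "compaction" in r:
                r["compaction"] = dict(r["compaction"])
            cfgs.append(SyntheticConfig(**r))
        _, stack = generate_cohort(cfgs)
        return stack
    if "stack" in inp:
        return read_pwd_stack(inp["stack"])
    if "trace_table" in inp:
        lib = read_library(inp["library"])
        tc = read_trace_table(inp["trace_table"], lib)
        return traces_to_pwd_stack(tc)
    raise ValidationError("input must provide synthetic, stack, or trace_table")


def _write_map_csv(values: np.ndarray, ids: list[str], path: Path) -> None:
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return the summary dict also written
    to ``<output_dir>/summary.json``."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", json.dumps(cfg.raw, default=str, sort_keys=True))

    stack = _load_stack(cfg)
    serialize_pwd_stack(stack, out / "stack.h5")
    lib = stack.library
    ids = lib.barcode_ids
    cohorts = list(pd.unique(stack.meta["cohort"]))
    summary: dict[str, Any] = {
        "seed": cfg.seed,
        "n_nuclei": int(stack.n_nuclei),
        "n_barcodes": int(stack.n_barcodes),
        "cohorts": cohorts,
    }

    if cfg.stage_enabled("ensemble"):
        p = cfg.stage_params("ensemble")
        method = p.pop("method", "kde_mode")
        for cohort in cohorts:
            sub = stack.subset(np.flatnonzero((stack.meta["cohort"] == cohort).to_numpy()))
            emap = ens.ensemble_map(sub, method=method, **p)
            _write_map_csv(emap.values, ids, out / f"ensemble_{cohort}.csv")
        logger.info("ensemble maps written for %d cohort(s)", len(cohorts))

    if cfg.stage_enabled("paircorr"):
        p = cfg.stage_params("paircorr")
        n_shuffles = p.pop("n_shuffles", sim.DEFAULT_N_SHUFFLES)
        pc_stats = {}
        frames = []
        for cohort in cohorts:
            sub = stack.subset(np.flatnonzero((stack.meta["cohort"] == cohort).to_numpy()))
            try:
                res = sim.pair_correlation_distribution(sub, **p)
                null_mean, null_sd = sim.shuffled_null(
                    sub, n_shuffles=n_shuffles, seed=cfg.seed, **p
                )
            except ValueError as e:
                logger.warning("paircorr skipped for cohort %s: %s", cohort, e)
                continue
            frames.append(res.correlations.assign(cohort=cohort))
            pc_stats[cohort] = {
                "median_r": res.median_r,
                "fraction_positive": res.fraction_positive,
                "n_pairs": int(len(res.correlations)),
                "n_skipped": res.n_skipped,
                "null_mean": null_mean,
                "null_sd": null_sd,
            }
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(out / "paircorr.csv", index=False)
        summary["pair_correlation"] = pc_stats

    metric_table = None
    if cfg.stage_enabled("metrics"):
        p = cfg.stage_params("metrics")
        tads = lib.tad_ids
        intra_tad = p.get("intra_tad", tads[-1])
        tad_pair = tuple(p.get("tad_pair", (tads[0], tads[-1])))
        is_cutoff = p.get("is_cutoff", met.IS_CUTOFF)
        contact_threshold = p.get("contact_threshold", met.CONTACT_THRESHOLD)
        rows = []
        profiles = met.insulation_profiles(stack)
        for k in range(stack.n_nuclei):
            m = stack.values[k]
            summ = met.intra_inter_medians(
                m, lib, intra_tad, tad_pair,
                max_distance=p.get("rg_max_distance", met.RG_MAX_DISTANCE),
            )
            rows.append(
                dict(
                    nucleus_id=stack.meta["nucleus_id"][k],
                    cohort=stack.meta["cohort"][k],
                    rna_state=stack.meta["rna_state"][k],
                    rg_intra=met.radius_of_gyration(m, lib.tad_indices(intra_tad)),
                    rg_other=met.radius_of_gyration(m, lib.tad_indices(tad_pair[0])),
                    border_is=profiles[k, lib.border_index],
                    intra_median=summ.intra_median,
                    inter_median=summ.inter_median,
                    demixing=summ.demixing,
                    inter_tad_contacts=met.inter_tad_contacts(
                        m, lib, tad_pair, threshold=contact_threshold
                    ),
                )
            )
        metric_table = pd.DataFrame(rows)
        metric_table.to_csv(out / "metrics.csv", index=False)
        frac = {}
        for cohort in cohorts:
            mask = (stack.meta["cohort"] == cohort).to_numpy()
            try:
                frac[cohort] = met.fraction_insulated(
                    profiles[mask], lib.border_index, cutoff=is_cutoff
                )
            except ValueError:
                frac[cohort] = None
        summary["fraction_insulated_at_border"] = frac
        demix = {}
        for state, grp in metric_table.groupby("rna_state"):
            vals = grp["demixing"].dropna()
            if len(vals):
                demix[state] = float(vals.mean())
        summary["demixing_mean_by_state"] = demix

    if cfg.stage_enabled("embed"):
        p = cfg.stage_params("embed")
        cutoffs = p.pop("cutoffs", {c: stack.n_barcodes for c in cohorts})
        resolution = p.pop("resolution", 0.25)
        kde_bandwidth = p.pop("kde_bandwidth", 0.5)
        density_threshold = p.pop("density_threshold", 0.02)
        diff_threshold = p.pop("diff_threshold", 0.02)
        admitted = select_nuclei(stack, cutoffs)
        imputed, _ = impute_per_category(admitted)
        vectors = stack_to_vectors(imputed)
        emb = embed_conformations(
            vectors, admitted.meta["cohort"].to_numpy(), seed=cfg.seed, **p
        )
        emb_df = pd.DataFrame(
            dict(
                nucleus_id=admitted.meta["nucleus_id"],
                cohort=admitted.meta["cohort"],
                umap_1=emb.coords[:, 0],
                umap_2=emb.coords[:, 1],
            )
        )
        labels = leiden_partition(
            emb.coords, n_neighbors=min(emb.params["n_neighbors"], len(emb_df) - 1),
            resolution=resolution, seed=cfg.seed,
        )
        emb_df["leiden"] = labels
        emb_df.to_csv(out / "embedding.csv", index=False)
        summary["n_admitted"] = int(admitted.n_nuclei)
        summary["n_leiden_clusters"] = int(labels.max() + 1)
        if len(set(emb.categories)) == 2:
            cb = density_boundaries(
                emb, kde_bandwidth=kde_bandwidth,
                density_threshold=density_threshold, diff_threshold=diff_threshold,
            )
            comp = cluster_composition(emb, cb)
            comp.to_csv(out / "composition.csv", index=False)
            summary["composition"] = {
                r.category: {
                    "own_pct": r.own_pct,
                    "other_pct": r.other_pct,
                    "outside_pct": r.outside_pct,
                }
                for r in comp.itertuples()
            }

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2, sort_keys=True, default=float)
    logger.info("summary written to %s", out / "summary.json")
    return summary
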