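"""End-to-end orchestration: landmarks -> FA -> popgen -> linkage.

A single YAML config drives the run.  Either a synthetic study is
generated (``synthetic:`` block, parameters of
:func:`asymlink.simulate.make_study`) or existing files are named in
an ``inputs:`` block (TPS landmark files with classifier CSVs, a
genotype CSV, burden and membership CSVs).  Stages that lack their
inputs are skipped with a logged reason; any stage error aborts with a
nonzero exit through the CLI.  All outputs are CSV; a JSON manifest
records the config hash, seeds, input digests, package version and
per-stage row counts so identical configs yield identical outputs
(timestamps aside).

The top-level seed is fanned out to per-stage seeds by fixed offsets,
giving one reproducibility knob with independent random streams.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import datetime, timezone

import pandas as pd
import yaml

from . import __version__
from .landmark_io import read_tps
from .linkage import expand_pools, run_model_battery
from .popgen import GenotypeTable, inbreeding_indices, locus_screen
from .symmetry import decompose, error_study, fa_scores, procrustes_anova

log = logging.getLogger("asymlink")

STAGE_SEED_OFFSETS = {"simulate": 0, "popgen": 1000, "linkage": 2000}


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config):
    if isinstance(config, dict):
        return dict(config), json.dumps(config, sort_keys=True, default=str)
    with open(config) as fh:
        text = fh.read()
    return yaml.safe_load(text), text


def run_all(config, out_dir) -> dict:
    """Run the full workflow; returns the manifest dict.

    ``config`` is a YAML path or an equivalent dict.  Outputs written
    to ``out_dir``: anova.csv, scores.csv, locus_stats.csv,
    indices.csv, table5.csv, manifest.json and run.log.
    """
    cfg, cfg_text = _load_config(config)
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_all(cfg, cfg_text, out_dir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_all(cfg: dict, cfg_text: str, out_dir: str) -> dict:
    seed = int(cfg.get("seed", 0))
    alpha = float(cfg.get("alpha", 0.05))
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "stage_seeds": {k: seed + v for k, v in STAGE_SEED_OFFSETS.items()},
        "package_version": __version__,
        "input_digests": {},
        "stages": {},
        "started_utc": datetime.now(timezone.utc).isoformat(),
    }

    landmark_sets: dict = {}
    genotype_tables: dict = {}
    burdens = membership = None
    error_sets: dict = {}

    if "synthetic" in cfg:
        from .simulate import make_study

        spec = dict(cfg["synthetic"] or {})
        for key in ("n_bees", "n_aquilonia", "n_exsecta", "nests_aquilonia", "nests_exsecta"):
            if key in spec:
                spec[key] = tuple(spec[key])
        bundle = make_study(seed=seed + STAGE_SEED_OFFSETS["simulate"], **spec)
        landmark_sets["forewings"] = bundle.forewings
        landmark_sets["hindwings"] = bundle.hindwings
        for species, ds in bundle.heads.items():
            landmark_sets[f"heads_{species}"] = ds
        error_sets = bundle.error_study
        genotype_tables["bees"] = bundle.genotypes_bees
        genotype_tables["ants"] = bundle.genotypes_ants
        burdens, membership = bundle.burdens, bundle.membership
        log.info("simulate: generated synthetic study (seed %d)", seed)
        manifest["stages"]["simulate"] = {"landmark_datasets": len(landmark_sets)}
    elif "inputs" in cfg:
        inputs = cfg["inputs"] or {}
        for name, spec in (inputs.get("landmarks") or {}).items():
            ds = read_tps(spec["tps"], spec.get("classifiers"))
            if spec.get("pairing"):
                from .landmark_io import read_pairing_yaml

                pairs, midline = read_pairing_yaml(spec["pairing"])
                ds.symmetry_mode = "object"
                ds.pairing, ds.midline = pairs, midline
            landmark_sets[name] = ds
            manifest["input_digests"][spec["tps"]] = _digest(spec["tps"])
        for name, path in (inputs.get("genotypes") or {}).items():
            genotype_tables[name] = GenotypeTable.from_csv(
                path, motifs=(inputs.get("motifs") or {}).get(name)
            )
            manifest["input_digests"][path] = _digest(path)
        if inputs.get("burdens"):
            burdens = pd.read_csv(inputs["burdens"])
            manifest["input_digests"][inputs["burdens"]] = _digest(inputs["burdens"])
        if inputs.get("membership"):
            membership = pd.read_csv(inputs["membership"])
            manifest["input_digests"][inputs["membership"]] = _digest(inputs["membership"])
    else:
        raise ValueError("config needs a 'synthetic' or an 'inputs' block")
    if not landmark_sets:
        raise ValueError("no landmark datasets configured")

    # --- FA stage ----------------------------------------------------------
    anova_rows, score_frames = [], []
    for name, ds in landmark_sets.items():
        decomp = decompose(ds)
        table = procrustes_anova(decomp, alpha=alpha)
        table.insert(0, "dataset", name)
        anova_rows.append(table)
        scores = fa_scores(decomp).reset_index()
        scores.insert(0, "dataset", name)
        score_frames.append(scores)
        log.info("fa: %s -> %d ANOVA rows, %d scored individuals", name, len(table), len(scores))
    for name, ds in error_sets.items():
        decomp = decompose(ds)
        table, verdict = error_study(decomp, alpha=alpha)
        table.insert(0, "dataset", f"error_study_{name}")
        anova_rows.append(table)
        log.info("fa: error study %s -> %s", name, verdict)
    anova = pd.concat(anova_rows, ignore_index=True)
    scores = pd.concat(score_frames, ignore_index=True)
    anova.to_csv(os.path.join(out_dir, "anova.csv"), index=False)
    scores.to_csv(os.path.join(out_dir, "scores.csv"), index=False)
    manifest["stages"]["fa"] = {"anova_rows": len(anova), "scored_individuals": len(scores)}

    # --- popgen stage ------------------------------------------------------
    if genotype_tables:
        stats_frames, index_frames = [], []
        pg_seed = seed + STAGE_SEED_OFFSETS["popgen"]
        for name, table in genotype_tables.items():
            locus_stats, ld_stats = locus_screen(table, seed=pg_seed)
            locus_stats = locus_stats.reset_index()
            locus_stats.insert(0, "dataset", name)
            stats_frames.append(locus_stats)
            idx = inbreeding_indices(table).reset_index()
            idx.insert(0, "dataset", name)
            index_frames.append(idx)
            log.info("popgen: %s -> %d loci, %d individuals (%d LD pairs)",
                     name, len(locus_stats), len(idx), len(ld_stats))
        locus_stats = pd.concat(stats_frames, ignore_index=True)
        indices = pd.concat(index_frames, ignore_index=True)
        locus_stats.to_csv(os.path.join(out_dir, "locus_stats.csv"), index=False)
        indices.to_csv(os.path.join(out_dir, "indices.csv"), index=False)
        manifest["stages"]["popgen"] = {"loci": len(locus_stats), "individuals": len(indices)}
    else:
        indices = None
        log.info("popgen: skipped (no genotype inputs)")
        manifest["stages"]["popgen"] = {"skipped": "no genotype inputs"}

    # --- linkage stage -----------------------------------------------------
    if indices is not None and burdens is not None and membership is not None:
        table5 = run_study_battery(scores, indices, burdens, membership, alpha=alpha)
        table5.to_csv(os.path.join(out_dir, "table5.csv"), index=False)
        manifest["stages"]["linkage"] = {"models": len(table5)}
        log.info("linkage: %d models fit", len(table5))
    else:
        missing = [n for n, v in
                   (("genotypes", indices), ("burdens", burdens), ("membership", membership))
                   if v is None]
        log.info("linkage: skipped (missing %s)", ", ".join(missing))
        manifest["stages"]["linkage"] = {"skipped": f"missing {', '.join(missing)}"}

    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_study_battery(scores: pd.DataFrame, indices: pd.DataFrame, burdens: pd.DataFrame,
                      membership: pd.DataFrame, alpha: float = 0.05,
                      fa_column: str = "fa2_size") -> pd.DataFrame:
    """Model battery over a whole study's FA scores.

    Bumblebee wing responses (fore + hind) are fit without a location
    term (locations pooled); ant head responses include location as a
    fixed factor.  The modelled response is the magnitude of the
    chosen FA score (``|fa2_size|`` by default, or ``fa_shape``).
    """
    out = []
    analytes_all = expand_pools(burdens, membership)
    idx = indices.set_index("individual")

    def response_frame(dataset_names, label_map):
        cols = {}
        for ds_name, label in label_map.items():
            sub = scores[scores["dataset"] == ds_name].set_index("individual")
            if len(sub):
                vals = sub[fa_column]
                cols[label] = vals.abs() if fa_column == "fa2_size" else vals
        return pd.DataFrame(cols)

    bee_resp = response_frame(["forewings", "hindwings"],
                              {"forewings": "fore_fa", "hindwings": "hind_fa"})
    if not bee_resp.empty:
        bee_ids = bee_resp.index
        table = run_model_battery(
            bee_resp,
            idx.loc[idx.index.intersection(bee_ids), ["mlh", "d2"]],
            analytes_all.loc[analytes_all.index.intersection(bee_ids)],
            location=None,
            alpha=alpha,
        )
        table.insert(0, "organism", "Bombus")
        out.append(table)

    head_names = [n for n in scores["dataset"].unique() if n.startswith("heads")]
    head_resp_parts = []
    for name in head_names:
        sub = scores[scores["dataset"] == name].set_index("individual")
        vals = sub[fa_column].abs() if fa_column == "fa2_size" else sub[fa_column]
        head_resp_parts.append(pd.DataFrame({"head_fa": vals, "location": sub["location"]}))
    if head_resp_parts:
        heads = pd.concat(head_resp_parts)
        table = run_model_battery(
            heads[["head_fa"]],
            idx.loc[idx.index.intersection(heads.index), ["mlh", "d2"]],
            analytes_all.loc[analytes_all.index.intersection(heads.index)],
            location=heads["location"],
            alpha=alpha,
        )
        table.insert(0, "organism", "Formica")
        out.append(table)
    if not out:
        raise ValueError("no FA responses available for the model battery")
    return pd.concat(out, ignore_index=True)
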