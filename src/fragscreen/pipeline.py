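"""End-to-end orchestration: augment → featurize → split/train →
evaluate/gap → screen/filter → dose-response, writing every artifact into
a run directory with a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .augment import augment_dataset
from .chem import compute_properties, featurize
from .config import RunConfig, default_assay_configs, default_sar_config
from .doseresponse import classify_activity, fit_4pl, normalize_activity
from .screen import build_similarity_network, embed_2d, filter_hits
from .synth import (builtin_fragment_library, generate_dose_response,
                    generate_sar_dataset, generate_screening_library)
from .train import evaluate, generalization_gap, predict_proba, train_model

log = logging.getLogger("fragscreen")


class PipelineStageError(RuntimeError):
    """A stage failed; ``stage`` names it. Earlier artifacts are kept."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as err:
                raise PipelineStageError(name, str(err)) from err
        return inner
    return wrap


@_stage("seeds")
def _load_seeds(cfg: RunConfig):
    if cfg.demo or cfg.seeds_path is None:
        return generate_sar_dataset(default_sar_config(cfg))
    records, rejects = fio.read_molecule_table(cfg.seeds_path)
    if rejects:
        log.warning("%d seed rows rejected", len(rejects))
    return records


@_stage("screen")
def _load_library(cfg: RunConfig, actives):
    if cfg.demo or cfg.library_path is None:
        if not cfg.demo:
            raise FileNotFoundError("no screening library configured")
        records, planted = generate_screening_library(
            cfg.demo_library_size, cfg.stage_seeds()["library"],
            actives=actives)
        return records, planted
    path = Path(cfg.library_path)
    if not path.exists():
        raise FileNotFoundError(f"screening library not found: {path}")
    records, rejects = fio.read_molecule_table(path)
    if rejects:
        log.warning("%d library rows rejected", len(rejects))
    return records, []


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute all stages; returns a summary dict (also written as the
    manifest). Stage failures raise PipelineStageError naming the stage;
    artifacts written before the failure are retained for debugging."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds_map = cfg.stage_seeds()
    summary = {"stage_seeds": seeds_map, "config": cfg.to_dict()}

    # --- seeds + augmentation -------------------------------------------
    seed_records = _load_seeds(cfg)
    fio.write_molecule_csv(seed_records, out / "seeds.csv")
    lib = builtin_fragment_library(cfg.augmentation.radius)

    split_spec = cfg.split_spec()
    from .train import stratified_split
    train_seeds, test_seeds = stratified_split(seed_records, split_spec)

    aug_cfg = cfg.augmentation
    aug_cfg.rng_seed = seeds_map["augment"]
    try:
        train_set = augment_dataset(train_seeds, lib, aug_cfg)
        test_set = (test_seeds if cfg.paper_mode
                    else augment_dataset(test_seeds, lib, aug_cfg))
    except Exception as err:
        raise PipelineStageError("augment", str(err)) from err
    fio.write_molecule_csv([r for r in train_set + test_set
                            if r.provenance == "augmented"],
                           out / "augmented.csv")

    # --- train + evaluate ------------------------------------------------
    try:
        bundle = train_model(train_set, cfg.train, rng_seed=seeds_map["train"])
        train_report = evaluate(bundle, train_set)
        test_report = evaluate(bundle, test_set)
        gap = generalization_gap(train_report, test_report)
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError("train", str(err)) from err
    metrics = pd.DataFrame([
        {"set": "training", **train_report.to_dict()},
        {"set": "test", **test_report.to_dict()},
    ])
    fio.write_dataframe(metrics, out / "metrics.csv")
    fio.write_dataframe(pd.DataFrame([gap.to_dict()]), out / "gap.csv")
    summary["metrics"] = {"training": train_report.to_dict(),
                          "test": test_report.to_dict(),
                          "gap": gap.to_dict(),
                          "best_params": bundle.best_params}

    # --- screen -----------------------------------------------------------
    library, planted = _load_library(cfg, [r for r in seed_records
                                           if r.label == 1])
    try:
        proba = predict_proba(bundle, library)
        network = build_similarity_network(library, cfg.edge_threshold)
        feats, _ = featurize(library, bundle.scaler, bundle.featurizer)
        coords = embed_2d(feats, perplexity=min(cfg.tsne_perplexity,
                                                len(library) - 1),
                          rng_seed=seeds_map["screen"])
        rows = []
        for i, rec in enumerate(library):
            props = compute_properties(rec)
            rows.append({"id": rec.id, "smiles": rec.smiles,
                         "probability": proba[i],
                         "neighbor_count": network.degree(rec.id),
                         **props, "tsne_x": float(coords[i, 0]),
                         "tsne_y": float(coords[i, 1]),
                         "planted": rec.id in set(planted)})
        screen_table = pd.DataFrame(rows)
        hits, audit = filter_hits(screen_table, cfg.filters)
    except PipelineStageError:
        raise
    except Exception as err:
        raise PipelineStageError("screen", str(err)) from err
    edges = pd.DataFrame(
        [{"source": u, "target": v, "similarity": d["similarity"]}
         for u, v, d in network.edges(data=True)])
    fio.write_dataframe(edges, out / "network_edges.csv")
    fio.write_dataframe(audit, out / "screen_audit.csv")
    fio.write_dataframe(audit[audit["is_hit"]], out / "hits.csv")
    summary["screen"] = {"library_size": len(library), "n_hits": len(hits),
                         "n_planted": len(planted),
                         "n_edges": network.number_of_edges()}

    # --- dose-response (optional / demo) ---------------------------------
    fits = []
    if cfg.demo and cfg.assay_path is None:
        tables = [generate_dose_response(a)
                  for a in default_assay_configs(seeds_map["assay"])]
    elif cfg.assay_path is not None:
        tables = [fio.read_assay_csv(cfg.assay_path)]
    else:
        tables = []
    for table in tables:
        try:
            norm = normalize_activity(table)
        except Exception as err:
            raise PipelineStageError("dose_response", str(err)) from err
        for (compound, form), group in norm.groupby(["compound", "form"]):
            fit = fit_4pl(group)
            call = classify_activity(fit, cfg.r2_min)
            p = fit.params
            fits.append({"compound": compound, "form": form,
                         "ic50_um": fit.ic50,
                         "min_resp": p.min_resp if p else None,
                         "max_resp": p.max_resp if p else None,
                         "hill": p.hill if p else None,
                         "max_inhibition_pct": fit.max_inhibition,
                         "r_squared": fit.r_squared,
                         "reliable": fit.reliable,
                         "activity_call": call})
    if fits:
        fio.write_dataframe(pd.DataFrame(fits), out / "dose_response_fits.csv")
        summary["dose_response"] = fits

    # --- manifest ---------------------------------------------------------
    cfg_blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    summary["config_sha256"] = hashlib.sha256(cfg_blob).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonify))
    return summary


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
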