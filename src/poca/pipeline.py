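"""End-to-end drivers composing the analysis stages.

Two designs are orchestrated: the labeling-method comparison (per-
condition FRC crossings against a bead-slide optical floor) and the
bait-vs-bait proteomics chain (differential enrichment → annotation
fraction and ROC → interaction-network null test).  All randomness
derives from a single global seed via stable per-stage hashing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

import poca.enrichment as enrichment
import poca.frc as frc
import poca.network as network
import poca.simulate as simulate
from poca.io import write_curve_tsv

__all__ = [
    "derive_seed", "run_frc_comparison", "run_proteome_pipeline",
    "intersect_hit_sets",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: SHA-256 of ``"{seed}:{stage}"`` mod 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_frc_comparison(conditions: dict, n_fov: int = 3,
                       bead_config: simulate.ImageSimConfig | None = None,
                       threshold: float = frc.DEFAULT_THRESHOLD,
                       taper_fraction: float = 0.1, smooth_width: int = 5,
                       seed: int = 0, out_dir=None) -> dict:
    """FRC sweep over labeling conditions with an optional bead floor.

    ``conditions`` maps a condition name to an :class:`ImageSimConfig`;
    each condition is simulated at ``n_fov`` fields of view with derived
    seeds, its crossings aggregated to mean ± sd.  With a bead config the
    report adds the bead crossing and each condition's crossing ratio to
    that optical floor.
    """
    report: dict = {"threshold": threshold, "n_fov": n_fov, "conditions": {}}
    curves: dict = {}
    for name, cfg in conditions.items():
        crossings = []
        curves[name] = []
        for i in range(n_fov):
            fov_seed = derive_seed(seed, f"frc:{name}:fov{i}")
            pair, _ = simulate.simulate_image_pair(
                dataclasses.replace(cfg, seed=fov_seed), fov_id=f"{name}_{i}")
            curve = frc.frc_curve(pair, taper_fraction=taper_fraction,
                                  smooth_width=smooth_width)
            curves[name].append(curve)
            crossings.append(frc.threshold_crossing(curve, threshold))
        agg = frc.aggregate_fovs(crossings)
        report["conditions"][name] = {
            "mean_nm": agg.mean_nm, "sd_nm": agg.sd_nm,
            "per_fov_nm": agg.per_fov, "n_uncrossed": agg.n_uncrossed,
        }
    if bead_config is not None:
        bead_crossings = []
        for i in range(n_fov):
            fov_seed = derive_seed(seed, f"frc:beads:fov{i}")
            pair = simulate.simulate_bead_pair(
                dataclasses.replace(bead_config, seed=fov_seed),
                fov_id=f"beads_{i}")
            curve = frc.frc_curve(pair, taper_fraction=taper_fraction,
                                  smooth_width=smooth_width)
            curves.setdefault("beads", []).append(curve)
            bead_crossings.append(frc.threshold_crossing(curve, threshold))
        bead = frc.aggregate_fovs(bead_crossings)
        report["bead_floor_nm"] = bead.mean_nm
        report["bead_sd_nm"] = bead.sd_nm
        report["ratio_to_bead"] = {
            name: c["mean_nm"] / bead.mean_nm
            for name, c in report["conditions"].items()}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, cs in curves.items():
            for i, c in enumerate(cs):
                write_curve_tsv(c, out_dir / f"frc_{name}_fov{i}.tsv")
        (out_dir / "frc_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_proteome_pipeline(matrix: pd.DataFrame, groups: pd.Series,
                          positives: set | None = None,
                          interactome: network.InteractionNetwork | None = None,
                          fc_threshold: float = 1.0, q_threshold: float = 0.05,
                          two_sided: bool = False, n_random: int = 200,
                          seed: int = 0, out_dir=None) -> dict:
    """Enrichment table → hit set → annotation stats → network null test."""
    table = enrichment.run_differential_enrichment(
        matrix, groups, fc_threshold=fc_threshold, q_threshold=q_threshold,
        two_sided=two_sided, seed=derive_seed(seed, "impute"))
    hits = set(table.index[table["is_hit"]])
    report: dict = {"n_proteins": len(table), "n_hits": len(hits)}
    if positives is not None:
        roc = enrichment.annotation_roc(table, positives)
        annotated_hits = hits & set(positives)
        report["annotated_hit_fraction"] = (
            len(annotated_hits) / len(hits) if hits else None)
        report["roc"] = {
            "auc": roc.auc,
            "youden_optimal_threshold": roc.youden_optimal_threshold,
            "youden_max": roc.youden_max,
            "n_positive": roc.n_positive, "n_negative": roc.n_negative,
        }
    if interactome is not None:
        if len(hits & interactome.nodes) < 2:
            report["network"] = {
                "skipped": True,
                "reason": "fewer than 2 hits map to the interactome"}
        else:
            nd = network.null_test(hits, interactome, n_random=n_random,
                                   seed=derive_seed(seed, "netnull"))
            report["network"] = {
                "observed": nd.observed_count, "null_mean": nd.null_mean,
                "null_sd": nd.null_sd, "z": nd.z_score, "p": nd.p_value,
                "empirical_p": nd.empirical_p, "n_random": nd.n_random,
                "n_query_mapped": nd.n_query_mapped,
                "n_query_dropped": nd.n_query_dropped,
                "degenerate": nd.degenerate,
            }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "enrichment_table.tsv", sep="\t")
        (out_dir / "proteome_report.json").write_text(
            json.dumps(report, indent=2, default=float))
    report["table"] = table
    return report


def _annotated_fraction(ids: set, positives: set | None):
    if positives is None or not ids:
        return None
    return len(ids & positives) / len(ids)


def intersect_hit_sets(table_a: pd.DataFrame, table_b: pd.DataFrame,
                       positives: set | None = None) -> dict:
    """Shared / unique hits of two hit-called tables, with annotation rates.

    Cross-validation logic: proteins recovered by two independent
    targeting modalities at the same compartment form a high-confidence
    set; annotated fractions are reported per region.
    """
    for name, t in (("A", table_a), ("B", table_b)):
        if "is_hit" not in t.columns:
            raise ValueError(f"table {name} has no is_hit column")
    hits_a = set(table_a.index[table_a["is_hit"]])
    hits_b = set(table_b.index[table_b["is_hit"]])
    shared = hits_a & hits_b
    only_a = hits_a - hits_b
    only_b = hits_b - hits_a
    positives = set(positives) if positives is not None else None
    return {
        "shared": shared, "unique_to_a": only_a, "unique_to_b": only_b,
        "annotated_fraction_shared": _annotated_fraction(shared, positives),
        "annotated_fraction_unique_a": _annotated_fraction(only_a, positives),
        "annotated_fraction_unique_b": _annotated_fraction(only_b, positives),
    }
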