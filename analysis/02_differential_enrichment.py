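"""Differential enrichment of a simulated proximal proteome.

Simulates a two-condition LFQ experiment (target bait vs reference bait,
4 replicates each, abundance-dependent missingness) with 150 true
proximal proteins at a 2-log2 enrichment, runs the full chain —
normalization, downshifted-normal imputation, Welch tests, BH adjustment,
strict >2-fold / FDR<0.05 hit calling — and benchmarks the hit list and
the log2FC ranking against the ground truth.  Findings: the hit rule
recovers >80% of the proximal set at essentially zero false discovery,
and the truth-ROC AUC exceeds 0.99 with a Youden-optimal log2FC cutoff
near 1.

Writes results/enrichment_table.tsv, results/roc_curve.tsv and
results/enrichment_summary.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import poca

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix, groups, truth = poca.simulate_lfq(poca.LfqSimConfig(seed=SEED))
    table = poca.run_differential_enrichment(matrix, groups, seed=SEED + 1)
    hits = set(table.index[table["is_hit"]])
    tp = len(hits & truth.proximal_ids)
    roc = poca.annotation_roc(table, truth.proximal_ids)

    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "enrichment_table.tsv", sep="\t")
    pd.DataFrame({"threshold": roc.thresholds, "tpr": roc.tpr,
                  "fpr": roc.fpr, "youden": roc.youden}).to_csv(
        OUT / "roc_curve.tsv", sep="\t", index=False)
    summary = {
        "n_proteins": len(table),
        "n_hits": len(hits),
        "sensitivity": tp / len(truth.proximal_ids),
        "false_discovery_proportion": (len(hits) - tp) / max(len(hits), 1),
        "roc_auc": roc.auc,
        "youden_optimal_log2fc": roc.youden_optimal_threshold,
        "youden_max": roc.youden_max,
    }
    (OUT / "enrichment_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"{len(table)} proteins quantified, {len(hits)} hits "
          f"(>2-fold, FDR < 0.05)")
    print(f"sensitivity {summary['sensitivity']:.3f}, observed FDP "
          f"{summary['false_discovery_proportion']:.3f}")
    print(f"truth-ROC AUC {roc.auc:.4f}; Youden-optimal log2FC cutoff "
          f"{roc.youden_optimal_threshold:.2f} (J = {roc.youden_max:.3f})")


if __name__ == "__main__":
    sys.exit(main())
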