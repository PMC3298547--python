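#!/usr/bin/env python
"""Bow-tie structure versus differential expression.

Decomposes the orphan-pruned reference network into bow-tie
compartments (LSCC / IN / OUT / OTHER), computes per-vertex log2
fold-changes for genes detected in both conditions, and tests the
compartments for equal fold-change variances with Levene's test.  The
generator inflates expression-noise variance in the IN compartment, so
a significant Levene result here means topology-correlated expression
variability is recovered from counts.  Writes the per-vertex scatter
data (lfc, Dis, compartment) behind the expression-vs-topology plot.
"""

import argparse
from pathlib import Path

import pandas as pd

from priornet.filtering import map_detection, combine_conditions, strict_filter
from priornet.netcore import remove_orphans
from priornet.topology import (
    bowtie_decompose,
    dis_index,
    log_fold_change,
    compartment_variance_report,
)
from priornet.synthdata import SimConfig, simulate_all


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = simulate_all(SimConfig(seed=args.seed))
    ref = data.reference
    ref_pruned = remove_orphans(ref)
    bt = bowtie_decompose(ref_pruned)
    print(f"bow-tie: {bt.sizes} (degenerate: {bt.degenerate})")

    det_n = map_detection(data.normal, data.idmap, ref)
    det_d = map_detection(data.disease, data.idmap, ref)
    both = sorted(det_n.detected & det_d.detected)
    de = log_fold_change(data.normal, data.disease, data.idmap, vertices=both)
    table, lev = compartment_variance_report(bt, de)

    args.out.mkdir(parents=True, exist_ok=True)
    bt.to_tsv(args.out / "bowtie_compartments.tsv")
    table.to_csv(args.out / "compartment_variance.tsv", sep="\t",
                 index=False, float_format="%.6g")

    strict = remove_orphans(strict_filter(
        ref, combine_conditions(det_n, det_d)["union"]))
    ds = dis_index(strict)
    scatter = pd.DataFrame({
        "vertex": both,
        "log2_fold_change": [de.values[v] for v in both],
        "compartment": [bt.labels.get(v, "NA") for v in both],
        "dis_strict": [ds.value(v) if v in ds else float("nan")
                       for v in both],
    })
    scatter.to_csv(args.out / "lfc_vs_dis_scatter.tsv", sep="\t",
                   index=False, float_format="%.6g")

    print(table.to_string(index=False))
    print(f"Levene W={lev.W:.4f}, p={lev.p:.4g} "
          f"(df {lev.df_between}, {lev.df_within})")
    if lev.p < 0.05:
        print("-> fold-change variance differs between compartments: the "
              "IN compartment is more variable than the stably expressed "
              "core, as planted")
    else:
        print("-> no significant variance difference detected at this seed")


if __name__ == "__main__":
    main()
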