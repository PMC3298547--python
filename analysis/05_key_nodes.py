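#!/usr/bin/env python
"""Key-node analysis: pairwise disconnectivity and its filtering increase.

Scores every vertex of the orphan-pruned reference and strictly
filtered union networks by the pairwise disconnectivity index, ranks
the top key nodes per network, and computes the Dis-increase (the
max-normalized difference) identifying vertices whose mediator role
emerges only after filtering.  Writes per-vertex TSVs plus the scatter
data behind the filtered-vs-reference comparison plot.
"""

import argparse
from pathlib import Path

from priornet.filtering import map_detection, combine_conditions, strict_filter
from priornet.netcore import remove_orphans
from priornet.topology import dis_index, dis_increase
from priornet.synthdata import SimConfig, simulate_all


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    data = simulate_all(SimConfig(seed=args.seed))
    ref = data.reference
    det = combine_conditions(
        map_detection(data.normal, data.idmap, ref),
        map_detection(data.disease, data.idmap, ref),
    )["union"]
    strict = remove_orphans(strict_filter(ref, det))
    ref_pruned = remove_orphans(ref)

    ds_ref = dis_index(ref_pruned)
    ds_strict = dis_index(strict)
    comp = dis_increase(ds_strict, ds_ref)

    args.out.mkdir(parents=True, exist_ok=True)
    ds_ref.to_tsv(args.out / "dis_reference.tsv")
    ds_strict.to_tsv(args.out / "dis_strict.tsv")
    comp.to_tsv(args.out / "dis_increase_scatter.tsv")

    for name, ds in (("reference", ds_ref), ("strict", ds_strict)):
        top = ds.as_frame().nlargest(5, "dis")
        print(f"top key nodes [{name}]:")
        for _, row in top.iterrows():
            print(f"  {row.vertex}  Dis={row.dis:.4f}")
    gained = comp.as_frame().nlargest(5, "delta_dis")
    print("largest Dis-increase (influence emerging through filtering):")
    for _, row in gained.iterrows():
        print(f"  {row.vertex}  delta={row.delta_dis:+.4f} "
              f"(strict {row.dis_filtered_normalized:.3f} vs "
              f"reference {row.dis_reference_normalized:.3f})")


if __name__ == "__main__":
    main()
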