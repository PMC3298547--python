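#!/usr/bin/env python
"""Pathway over-representation against the expression-weighted null.

Tests every pathway (overlap >= 2) against the strictly filtered union
network with the exact noncentral Fisher test, against the 1-extended
network with Monte-Carlo empirical p-values, and with the classical
central Fisher test as baseline; q-values control the positive FDR.
Prints the top pathways per mode and whether the planted pathway is
recovered.
"""

import argparse
from pathlib import Path

from priornet.filtering import map_detection
from priornet.enrichment import compute_weights, enrich_all
from priornet.synthdata import SimConfig, simulate_all


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--samples", type=int, default=10_000)
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    data = simulate_all(cfg)
    ref = data.reference
    det = (map_detection(data.normal, data.idmap, ref).detected
           | map_detection(data.disease, data.idmap, ref).detected)
    w = compute_weights(data.tissue, ref.vertices)
    print(f"weight universe: {len(w.order)} vertices "
          f"({len(w.excluded)} without expression rows excluded)")

    args.out.mkdir(parents=True, exist_ok=True)
    for mode, fname in (
        ("strict_exact", "enrichment_strict.tsv"),
        ("central", "enrichment_central.tsv"),
        ("extended_mc", "enrichment_extended_mc.tsv"),
    ):
        res = enrich_all(ref, det, data.pathways, w, mode=mode,
                         T=args.samples, seed=args.seed)
        res.to_csv(args.out / fname, sep="\t", index=False,
                   float_format="%.6g")
        top = res.head(3)[["pathway", "k", "K", "p", "q"]]
        n_sig = int((res["q"] < 0.05).sum())
        rank = int((res["pathway"] == cfg.planted_pathway_id).idxmax()) + 1
        print(f"\n[{mode}] {len(res)} pathways tested, {n_sig} with q<0.05; "
              f"planted pathway {cfg.planted_pathway_id} ranks #{rank}")
        print(top.to_string(index=False))


if __name__ == "__main__":
    main()
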