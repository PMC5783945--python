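#!/usr/bin/env python
"""Community morphospace, motif proportions across K, and node diversity.

Classifies every community pair of every fitted partition into assortative /
core-periphery / disassortative motifs, contrasts the two methods' motif
proportions as a function of K with the aggregate permutation test, and
computes node-level motif participation, strength-binned dominance, and the
diversity (entropy) index.  Writes results/motif_proportions.tsv,
results/node_diversity.tsv and results/strength_bins.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import mesoscope as ms

FITS = Path("results/fits")
KS = range(2, 7)
SEED = 2024


def load(method, k):
    return [ms.read_partition(p)
            for p in sorted((FITS / method / f"K{k}").glob("restart*.tsv"))]


def class_labels(net, parts):
    out = []
    for p in parts:
        if p.K >= 2:
            out += [pt.motif.value
                    for pt in ms.morphospace_points(ms.block_densities(net, p))]
    return out


def main() -> None:
    net = ms.read_network("results/data/mixed_network.tsv")
    ens = {m: {k: load(m, k) for k in KS} for m in ("qmax", "wsbm")}
    props = {m: {k: class_labels(net, ens[m][k]) for k in KS} for m in ens}

    def permute(rng):
        null = {}
        for m in ens:
            null[m] = {k: class_labels(
                net, [ms.permute_partition_labels(p, rng.integers(2**31))
                      for p in ens[m][k]]) for k in KS}
        return null["qmax"], null["wsbm"]

    out = ms.motif_proportions_vs_k(props["qmax"], props["wsbm"],
                                    permute=permute, n_perm=199, seed=SEED)
    curves = pd.concat({m: out[f"curves_{t}"] for m, t in
                        (("qmax", "A"), ("wsbm", "B"))}, names=["method", "K"])
    curves.to_csv("results/motif_proportions.tsv", sep="\t")
    print(out["curves_A"].round(3))
    print(out["curves_B"].round(3))
    print(f"aggregate motif-proportion difference {out['statistic']:.3f}, "
          f"permutation p = {out['test'].p_value:.3g}")

    # node-level participation and diversity, averaged over the wsbm ensemble
    div_vectors, part_frames = [], []
    for k in KS:
        for p in ens["wsbm"][k]:
            if p.K < 2:
                continue
            pts = ms.morphospace_points(ms.block_densities(net, p))
            prof = ms.motif_participation(pts, p)
            div_vectors.append(ms.node_diversity(prof, p))
            part_frames.append(prof.node_participation)
    diversity = ms.average_node_scores(div_vectors)
    participation = sum(part_frames) / len(part_frames)
    pd.DataFrame({"node": net.node_ids, "diversity_bits": diversity}).to_csv(
        "results/node_diversity.tsv", sep="\t", index=False
    )
    print(f"mean node diversity (wsbm ensemble): {np.nanmean(diversity):.3f} bits; "
          f"max possible 2 bits")

    bins = ms.strength_binned_dominance(net.strength, participation, n_bins=5)
    bins.to_csv("results/strength_bins.tsv", sep="\t")
    print("strength-binned motif dominance (top bin should be core-dominated "
          "for a network with a dense high-strength core):")
    print(bins.round(3))


if __name__ == "__main__":
    main()
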