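#!/usr/bin/env python
"""Fit both community-detection methods to the mixed-motif network.

For K = 2..6 and 25 restarts per K, fits (a) the sparse weighted stochastic
blockmodel by variational Bayes and (b) fixed-K greedy modularity
maximization, writing every restart's partition under results/fits/.  These
ensembles are reused by all downstream comparisons.
"""

from pathlib import Path

import numpy as np

import mesoscope as ms
from mesoscope import ModularityConfig

SEED = 2024
KS = range(2, 7)
RESTARTS = 25
DATA = Path("results/data")
OUT = Path("results/fits")


def main() -> None:
    net = ms.read_network(DATA / "mixed_network.tsv")
    for method in ("wsbm", "qmax"):
        for k in KS:
            kdir = OUT / method / f"K{k}"
            kdir.mkdir(parents=True, exist_ok=True)
            children = np.random.SeedSequence([SEED, k]).spawn(RESTARTS)
            for rep, child in enumerate(children):
                if method == "wsbm":
                    part = ms.fit_wsbm(net, k, restarts=1, seed=child).map_partition
                else:
                    part = ms.greedy_fixed_k(
                        net, k, ModularityConfig(restarts=1), seed=child
                    ).partition
                ms.write_partition(part, kdir / f"restart{rep:03d}.tsv", net.node_ids)
            print(f"{method} K={k}: wrote {RESTARTS} restart partitions")
    print(f"fits under {OUT}/")


if __name__ == "__main__":
    main()
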