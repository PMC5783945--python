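"""End-to-end orchestration: fit both community-detection methods across K,
compute the comparison metrics, and write a reproducible results tree.

Every stage is a pure function of (inputs, config, seed); the run manifest
records parameters, the seed, package version, and a SHA-256 hash of every
derived file, making a run re-executable bit for bit.

Two named profiles mirror two operating points: ``desk`` (25 restarts per K)
for interactive work and testing, and ``paper`` (250 restarts per K), which
reflects the original study scale.  Restart count affects only how close
each fit gets to its objective's optimum, not the definition of any metric.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assort import (
    all_community_assortativity,
    block_densities,
    mas_node_frequency,
    maximally_assortative_set,
)
from .modmax import ModularityConfig, greedy_fixed_k
from .morphospace import morphospace_points, motif_participation, node_diversity
from .netio import Partition, WeightedNetwork, read_network, write_partition
from .partcompare import vi_within_between
from .richclub import rich_club_significance, rich_club_split
from .wsbm import fit_wsbm

__all__ = ["RunConfig", "run_full_analysis"]

_PROFILES = {"desk": 25, "paper": 250}


@dataclass
class RunConfig:
    network_path: str | None = None
    out_dir: str = "results/run"
    k_min: int = 2
    k_max: int = 10
    restarts: int | None = None  # per K and method; default from profile
    profile: str = "desk"
    alpha: float = 0.5
    gamma: float = 1.0
    n_moves: int = 10_000
    n_perm: int = 1000
    n_null: int = 100
    seed: int = 0
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("require 2 <= k_min <= k_max")
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {sorted(_PROFILES)}")
        if self.restarts is None:
            self.restarts = _PROFILES[self.profile]
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig, network: WeightedNetwork | None = None) -> dict:
    """Run fits, partition comparison, assortativity/MAS, motifs, rich club.

    Returns a results bundle (dict) and writes TSV/JSON outputs plus a
    manifest under ``config.out_dir``.
    """
    if network is None:
        if config.network_path is None:
            raise ValueError("provide a network or a network_path")
        network = read_network(config.network_path)
    if config.k_max > network.n_nodes:
        raise ValueError("k_max exceeds the number of nodes")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    ks = list(range(config.k_min, config.k_max + 1))
    seeds = {
        (method, k): child
        for (method, k), child in zip(
            [(m, k) for m in ("wsbm", "qmax") for k in ks], ss.spawn(2 * len(ks))
        )
    }

    ensembles: dict[str, dict[int, list[Partition]]] = {"wsbm": {}, "qmax": {}}
    stage = "fit"
    try:
        for k in ks:
            wsbm_children = np.random.SeedSequence(
                seeds[("wsbm", k)].entropy, spawn_key=seeds[("wsbm", k)].spawn_key
            ).spawn(config.restarts)
            ensembles["wsbm"][k] = [
                fit_wsbm(
                    network, k, alpha=config.alpha, restarts=1, seed=c,
                    max_iter=config.max_iter,
                ).map_partition
                for c in wsbm_children
            ]
            qcfg = ModularityConfig(
                gamma=config.gamma, n_moves=config.n_moves, restarts=1
            )
            qmax_children = seeds[("qmax", k)].spawn(config.restarts)
            ensembles["qmax"][k] = [
                greedy_fixed_k(network, k, qcfg, seed=c).partition for c in qmax_children
            ]
            for method in ("wsbm", "qmax"):
                pdir = out / "partitions" / method / f"K{k}"
                pdir.mkdir(parents=True, exist_ok=True)
                for r, part in enumerate(ensembles[method][k]):
                    write_partition(part, pdir / f"restart{r:03d}.tsv", network.node_ids)

        stage = "vi"
        vi_rows = []
        for k in ks:
            wk = [p for p in ensembles["wsbm"][k] if p.K == k]
            qk = [p for p in ensembles["qmax"][k] if p.K == k]
            if len(wk) >= 2 and len(qk) >= 2:
                s = vi_within_between(wk, qk)
                vi_rows.append(
                    {
                        "K": k,
                        "mean_within_wsbm": s.within_A.mean(),
                        "mean_within_qmax": s.within_B.mean(),
                        "mean_between": s.between.mean(),
                        "t_wsbm": s.t_A, "p_wsbm": s.p_A,
                        "t_qmax": s.t_B, "p_qmax": s.p_B,
                    }
                )
        pd.DataFrame(vi_rows).to_csv(out / "vi_summary.tsv", sep="\t", index=False)

        stage = "assortativity"
        assort_rows = []
        mas_freq = {}
        for method in ("wsbm", "qmax"):
            ens_all = [p for k in ks for p in ensembles[method][k]]
            mas_freq[method] = mas_node_frequency(ens_all, network)
            for k in ks:
                for part in ensembles[method][k]:
                    bdm = block_densities(network, part)
                    scores = all_community_assortativity(bdm)
                    for r, (nr, a) in enumerate(zip(bdm.sizes, scores), start=1):
                        assort_rows.append(
                            {"method": method, "K": k, "community": r,
                             "size": int(nr), "assortativity": a}
                        )
        pd.DataFrame(assort_rows).to_csv(
            out / "community_assortativity.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {"node": network.node_ids,
             "mas_frequency_wsbm": mas_freq["wsbm"],
             "mas_frequency_qmax": mas_freq["qmax"]}
        ).to_csv(out / "mas_node_frequency.tsv", sep="\t", index=False)

        stage = "morphospace"
        motif_rows = []
        div_rows = []
        for method in ("wsbm", "qmax"):
            for k in ks:
                for rep, part in enumerate(ensembles[method][k]):
                    if part.K < 2:
                        continue
                    bdm = block_densities(network, part)
                    pts = morphospace_points(bdm)
                    for pt in pts:
                        motif_rows.append(
                            {"method": method, "K": k, "restart": rep,
                             "r": pt.r, "s": pt.s, "omega_rr": pt.omega_rr,
                             "omega_ss": pt.omega_ss, "omega_rs": pt.omega_rs,
                             "motif": pt.motif.value, "core": pt.core}
                        )
                    prof = motif_participation(pts, part)
                    div_rows.append(
                        {"method": method, "K": k, "restart": rep,
                         **{f"H_{nid}": h for nid, h in
                            zip(network.node_ids, node_diversity(prof, part))}}
                    )
        pd.DataFrame(motif_rows).to_csv(out / "morphospace.tsv", sep="\t", index=False)
        pd.DataFrame(div_rows).to_csv(out / "diversity.tsv", sep="\t", index=False)

        stage = "richclub"
        rc = rich_club_significance(
            network, n_null=config.n_null, seed=ss.spawn(1)[0]
        )
        pd.DataFrame(
            {"k": rc.k, "phi": rc.phi, "null_mean": rc.null_mean,
             "normalized": rc.normalized, "p": rc.p, "significant": rc.significant}
        ).to_csv(out / "richclub.tsv", sep="\t", index=False)
        split = rich_club_split(network)
        pd.DataFrame(
            {"node": network.node_ids,
             "rich": [int(i in set(split.rich)) for i in range(network.n_nodes)]}
        ).to_csv(out / "richclub_split.tsv", sep="\t", index=False)
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "package_version": __version__,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "ensembles": ensembles,
        "mas_frequency": mas_freq,
        "richclub": rc,
        "manifest": manifest,
        "out_dir": str(out),
    }
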