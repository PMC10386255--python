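"""End-to-end orchestration: align -> propagate -> similarity -> threshold
-> structural distances -> multilayer -> walks -> skip-gram -> repeated
evaluation -> ranking -> benchmark overlap.

One master seed deterministically derives labeled per-stage substreams
(propagation itself is deterministic; walks, undersampling, splits and
model fits each get their own), so a rerun with the same config reproduces
every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import classify, metrics, net_io, propagation, struct_embed

log = logging.getLogger("drivnet")

__all__ = ["RunConfig", "derive_seed", "run_pipeline", "run_pipeline_on_data", "sweep_alpha"]


def derive_seed(master: int, label: str) -> int:
    """Stable labeled substream seed in [0, 2^31)."""
    digest = hashlib.blake2b(f"{master}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips through key=value text."""

    network_path: str = ""
    mutations_path: str = ""
    benchmark_path: str = ""
    benchmark_name: str = "benchmark"
    out_dir: str = "drivnet_out"
    restart_alpha: float = propagation.DEFAULT_ALPHA
    tol: float = propagation.DEFAULT_TOL
    max_iter: int = propagation.DEFAULT_MAX_ITER
    sim_method: str = "cosine"
    sim_cutoff: float = propagation.DEFAULT_SIM_CUTOFF
    k_max: int = struct_embed.DEFAULT_K_CAP
    num_walks: int = struct_embed.DEFAULT_NUM_WALKS
    walk_length: int = struct_embed.DEFAULT_WALK_LENGTH
    dim: int = struct_embed.DEFAULT_DIM
    stay_prob: float = struct_embed.DEFAULT_STAY_PROB
    window: int = struct_embed.DEFAULT_WINDOW
    epochs: int = struct_embed.DEFAULT_EPOCHS
    distance_mode: str = "global"
    model: str = "xgbt"
    n_undersamples: int = classify.DEFAULT_N_UNDERSAMPLES
    n_repeats: int = classify.DEFAULT_N_REPEATS
    top_n: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.restart_alpha < 1:
            raise ValueError("restart_alpha must be in (0, 1)")
        if not 0 < self.stay_prob < 1:
            raise ValueError("stay_prob must be in (0, 1)")
        if self.model not in classify.MODEL_NAMES:
            raise ValueError(f"model must be one of {classify.MODEL_NAMES}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k} = {v}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(raw)
            elif isinstance(current, float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def _stage(manifest: dict, name: str, t0: float) -> float:
    t1 = time.perf_counter()
    manifest["stage_seconds"][name] = round(t1 - t0, 3)
    log.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run_pipeline_on_data(
    cfg: RunConfig,
    net: net_io.GeneNetwork,
    mat: net_io.MutationMatrix,
    bench: net_io.BenchmarkGeneSet,
    out_dir: Path | None = None,
) -> dict:
    """Run all stages on in-memory inputs; returns the manifest dict.

    If ``out_dir`` is given, every intermediate artifact is written there.
    """
    manifest: dict = {
        "config": asdict(cfg),
        "stage_seconds": {},
        "dropped": {},
    }
    t = time.perf_counter()
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    net_al, mat_al = net_io.align_universe(net, mat)
    manifest["n_genes_aligned"] = net_al.n_nodes
    manifest["dropped"]["genes_outside_intersection"] = (
        net.n_nodes + mat.n - 2 * net_al.n_nodes
    )
    t = _stage(manifest, "align", t)

    W = propagation.normalize_adjacency(net_al)
    prop = propagation.propagate_all(W, mat_al, alpha=cfg.restart_alpha,
                                     tol=cfg.tol, max_iter=cfg.max_iter)
    manifest["propagation_iterations_max"] = int(prop.iterations_used.max())
    t = _stage(manifest, "propagate", t)

    sim = propagation.gene_similarity(prop, method=cfg.sim_method)
    integ = propagation.threshold_network(sim, cutoff=cfg.sim_cutoff)
    manifest["integration_nodes"] = integ.n_nodes
    manifest["integration_edges"] = integ.n_edges
    manifest["dropped"]["genes_isolated_after_threshold"] = len(sim.gene_ids) - integ.n_nodes
    t = _stage(manifest, "integrate", t)
    if out_dir is not None:
        net_io.write_edge_list(integ, out_dir / "integration_network.tsv")

    emb = struct_embed.embed_network(
        integ, k_cap=cfg.k_max, num_walks=cfg.num_walks, walk_length=cfg.walk_length,
        q=cfg.stay_prob, dim=cfg.dim, window=cfg.window, epochs=cfg.epochs,
        seed=derive_seed(cfg.seed, "walks"), mode=cfg.distance_mode,
    )
    manifest["n_genes_embedded"] = len(emb.gene_ids)
    t = _stage(manifest, "embed", t)
    if out_dir is not None:
        net_io.write_embeddings(emb, out_dir / "embeddings.txt")

    ds = classify.build_dataset(emb, bench)
    cv = classify.run_repeated_eval(
        ds, model=cfg.model, n_repeats=cfg.n_repeats,
        n_undersamples=cfg.n_undersamples, seed=derive_seed(cfg.seed, "eval"),
    )
    manifest["cv_summary"] = cv.summary()
    manifest["cv_runs"] = len(cv.runs)
    t = _stage(manifest, "evaluate", t)

    ranked = classify.train_final_and_rank(ds, model=cfg.model,
                                           seed=derive_seed(cfg.seed, "rank"))
    top_n = min(cfg.top_n, len(ranked.items))
    manifest["benchmark_overlap_top_n"] = metrics.benchmark_overlap(ranked, bench, top_n)
    manifest["top_n"] = top_n
    manifest["ranked"] = ranked.items
    t = _stage(manifest, "rank", t)

    if out_dir is not None:
        with (out_dir / "ranked_genes.tsv").open("w") as fh:
            for g, s in ranked.items:
                fh.write(f"{g}\t{s:.10g}\n")
        cfg.to_file(out_dir / "config.txt")
        with (out_dir / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest


def run_pipeline(cfg: RunConfig) -> dict:
    """File-based entry point: read the three inputs, then run all stages."""
    net = net_io.read_edge_list(cfg.network_path)
    mat = net_io.read_mutation_matrix(cfg.mutations_path)
    bench = net_io.read_gene_set(cfg.benchmark_path, cfg.benchmark_name)
    return run_pipeline_on_data(cfg, net, mat, bench, out_dir=Path(cfg.out_dir))


def sweep_alpha(
    cfg: RunConfig,
    alpha_grid,
    net: net_io.GeneNetwork,
    mat: net_io.MutationMatrix,
    bench: net_io.BenchmarkGeneSet,
) -> dict:
    """Rerun the pipeline per restart alpha and report mean precision.

    Returns {"rows": [(alpha, precision), ...], "best_alpha": argmax}.
    """
    rows: list[tuple[float, float]] = []
    for a in alpha_grid:
        if not 0 < a < 1:
            raise ValueError("alpha grid values must lie in (0, 1)")
        cfg_a = RunConfig(**{**asdict(cfg), "restart_alpha": float(a)})
        man = run_pipeline_on_data(cfg_a, net, mat, bench, out_dir=None)
        rows.append((float(a), man["cv_summary"]["precision"]["mean"]))
    best = max(rows, key=lambda t: (t[1], -t[0]))[0]
    return {"rows": rows, "best_alpha": best}
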