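"""Shared fixtures: the structural-twins graph and the planted-driver
recovery cohort, both built once per session because the embedding stage
dominates runtime."""

from __future__ import annotations

import numpy as np
import pytest

import drivnet as dn
from drivnet.pipeline import RunConfig, derive_seed
from drivnet.struct_embed import effective_diameter

RECOVERY_SEED = 7
TWINS_SEED = 3
TWINS_EMBED_SEED = 11


@pytest.fixture(scope="session")
def twins_bundle():
    """Twins network + counterpart pairs + distances + embeddings."""
    net, pairs = dn.make_structural_twins(seed=TWINS_SEED)
    k = min(effective_diameter(net), 6)
    table = dn.degree_sequences(net, k)
    dist = dn.structural_distances(table, k_star=k)
    mlg = dn.build_multilayer(dist)
    emb = dn.embed_network(net, seed=TWINS_EMBED_SEED)
    return dict(net=net, pairs=pairs, table=table, dist=dist, mlg=mlg, emb=emb, k=k)


@pytest.fixture(scope="session")
def recovery_bundle():
    """Full pipeline stages on the default planted-driver cohort.

    Mirrors run_pipeline_on_data stage by stage so tests can reuse the
    intermediate objects (embeddings, labeled dataset) without recomputing
    the expensive embedding step.
    """
    cfg = RunConfig(seed=RECOVERY_SEED)
    cohort = dn.make_recovery_cohort(seed=RECOVERY_SEED)
    net_al, mat_al = dn.align_universe(cohort.net, cohort.mat)
    W = dn.normalize_adjacency(net_al)
    prop = dn.propagate_all(W, mat_al, alpha=cfg.restart_alpha, tol=cfg.tol)
    sim = dn.gene_similarity(prop, method=cfg.sim_method)
    integ = dn.threshold_network(sim, cutoff=cfg.sim_cutoff)
    emb = dn.embed_network(
        integ, k_cap=cfg.k_max, num_walks=cfg.num_walks, walk_length=cfg.walk_length,
        q=cfg.stay_prob, dim=cfg.dim, window=cfg.window, epochs=cfg.epochs,
        seed=derive_seed(cfg.seed, "walks"),
    )
    ds = dn.build_dataset(emb, cohort.drivers)
    cv = dn.run_repeated_eval(ds, model="xgbt", n_repeats=cfg.n_repeats,
                              n_undersamples=cfg.n_undersamples,
                              seed=derive_seed(cfg.seed, "eval"))
    ranked = dn.train_final_and_rank(ds, model="xgbt", seed=derive_seed(cfg.seed, "rank"))
    return dict(cfg=cfg, cohort=cohort, integ=integ, emb=emb, ds=ds, cv=cv, ranked=ranked)


@pytest.fixture()
def small_cohort():
    """Desk-scale cohort for pipeline-level tests (seconds, not minutes)."""
    net = dn.make_scale_free(120, 2, seed=5)
    return dn.simulate_cohort(net, n_samples=60, n_drivers=12,
                              p_driver=0.25, p_passenger=0.03, seed=6)


def cosine_matrix(emb) -> tuple[np.ndarray, dict[str, int]]:
    V = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    return V @ V.T, {g: i for i, g in enumerate(emb.gene_ids)}
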