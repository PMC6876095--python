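"""End-to-end alignment pipeline and its configuration.

Stages, in order: PSO training of the pair-HMM on the input family;
pair-HMM posteriors P^a and partition-function posteriors P^b for every
sequence pair; root-mean-square fusion; MEA global scores and the
distance matrix; UPGMA guide tree and ClustalW-style weights; probabilistic
consistency transformation; progressive profile alignment along the tree;
random-bipartition refinement.  All randomness (PSO initialisation and
r1/r2 draws, refinement splits) flows from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .guidetree import TreeNode, clustalw_weights, upgma
from .matrices import blosum62
from .pairhmm import HmmParams, ParamVector, hmm_posterior, params_from_vector
from .pairwise import DEFAULT_CUTOFF, build_distance_matrix, fuse_posteriors
from .partition import PartitionParams, pf_posterior
from .progressive import (ConsistencyLibrary, consistency_transform,
                          iterative_refine, progressive_align)
from .pso import SwarmConfig, optimize
from .scoring import GapPenalties
from .seqio import MultipleAlignment, ProteinSequence

log = logging.getLogger(__name__)

_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, serialisable as flat key=value text.

    Keys in config files use the long CLI flag names (hyphens); they map
    to these fields with underscores.
    """

    particles: int = 10
    pso_iterations: int = 30
    w: float = 0.729
    f1: float = 1.49445
    f2: float = 1.49445
    temperature: float = 5.0
    gap_open: int = -11
    gap_extend: int = -1
    posterior_cutoff: float = 0.01
    consistency_passes: int = 1
    refine_iterations: int = 10
    refine_accept_all: bool = False
    gap_renorm: bool = False
    max_fitness_pairs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particles < 1 or self.pso_iterations < 0:
            raise ValueError("invalid swarm configuration")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("gap penalties must satisfy open <= extend <= 0")
        if not (0 <= self.posterior_cutoff < 1):
            raise ValueError("posterior cutoff must lie in [0, 1)")
        if self.consistency_passes < 0 or self.refine_iterations < 0:
            raise ValueError("pass/iteration counts must be non-negative")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if isinstance(value, bool):
                    value = "true" if value else "false"
                fh.write(f"{f.name.replace('_', '-')}={value}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"line {lineno}: expected key=value")
                key, _, value = line.partition("=")
                name = key.strip().replace("-", "_")
                value = value.strip()
                if name not in fields:
                    raise ValueError(f"line {lineno}: unknown key {key.strip()!r}")
                ftype = fields[name].type
                if ftype == "bool":
                    low = value.lower()
                    if low in _TRUE:
                        kwargs[name] = True
                    elif low in _FALSE:
                        kwargs[name] = False
                    else:
                        raise ValueError(f"line {lineno}: bad boolean {value!r}")
                elif ftype == "int":
                    kwargs[name] = int(value)
                else:
                    kwargs[name] = float(value)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything the pipeline computes, for inspection and reuse."""

    alignment: MultipleAlignment
    tree: TreeNode
    weights: np.ndarray
    distances: np.ndarray
    hmm_params: HmmParams
    pso_best: ParamVector
    pso_trace: list[float]
    config: PipelineConfig


def fused_posteriors(seqs: list[ProteinSequence], h: HmmParams,
                     pp: PartitionParams,
                     cutoff: float = DEFAULT_CUTOFF,
                     ) -> dict[tuple[int, int], np.ndarray]:
    """RMS-fused pair-HMM and partition-function posteriors for all pairs."""
    out = {}
    for i, j in itertools.combinations(range(len(seqs)), 2):
        pa = hmm_posterior(seqs[i], seqs[j], h)
        pb = pf_posterior(seqs[i], seqs[j], pp)
        fused = fuse_posteriors(pa, pb)
        fused[fused < cutoff] = 0.0
        out[(i, j)] = fused
    return out


def align(seqs: list[ProteinSequence],
          cfg: PipelineConfig | None = None) -> PipelineResult:
    """Align a protein family end to end; deterministic given cfg.seed."""
    cfg = cfg or PipelineConfig()
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")

    matrix = blosum62()
    sop_gaps = GapPenalties(cfg.gap_open, cfg.gap_extend)
    root_seed = np.random.SeedSequence(cfg.seed)
    pso_seed, refine_seed = root_seed.spawn(2)

    log.info("stage 1/6: PSO training (%d particles, %d iterations)",
             cfg.particles, cfg.pso_iterations)
    swarm_cfg = SwarmConfig(
        n_particles=cfg.particles, n_iterations=cfg.pso_iterations,
        w=cfg.w, f1=cfg.f1, f2=cfg.f2, seed=pso_seed,
        max_pairs=cfg.max_fitness_pairs,
    )
    best_vec, trace = optimize(seqs, swarm_cfg, matrix, sop_gaps)
    h = params_from_vector(best_vec)

    log.info("stage 2/6: pairwise posteriors (HMM + partition function)")
    pp = PartitionParams(T=cfg.temperature, matrix=matrix, gaps=sop_gaps)
    fused = fused_posteriors(seqs, h, pp, cfg.posterior_cutoff)

    log.info("stage 3/6: distance matrix and UPGMA guide tree")
    D = build_distance_matrix(seqs, fused)
    tree = upgma(D, labels=ids)
    weights = clustalw_weights(tree)

    log.info("stage 4/6: consistency transformation (%d pass(es))",
             cfg.consistency_passes)
    lib = consistency_transform(fused, weights, cfg.consistency_passes,
                                cfg.posterior_cutoff)

    log.info("stage 5/6: progressive alignment")
    initial = progressive_align(tree, lib, weights, seqs, cfg.gap_renorm)

    log.info("stage 6/6: iterative refinement (%d iterations)",
             cfg.refine_iterations)
    refined = iterative_refine(
        initial, lib, weights, seqs, iters=cfg.refine_iterations,
        rng=np.random.default_rng(refine_seed), matrix=matrix, gaps=sop_gaps,
        accept_all=cfg.refine_accept_all, gap_renorm=cfg.gap_renorm,
    )
    return PipelineResult(alignment=refined, tree=tree, weights=weights,
                          distances=D, hmm_params=h, pso_best=best_vec,
                          pso_trace=trace, config=cfg)


def align_pipeline(seqs: list[ProteinSequence],
                   cfg: PipelineConfig | None = None) -> MultipleAlignment:
    """Convenience wrapper returning only the final alignment."""
    return align(seqs, cfg).alignment
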