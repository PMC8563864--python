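"""Synthetic differential-expression data with planted network structure.

The generator emulates the statistical shape the analysis assumes, without
modelling reads or counts: most genes are differentially expressed in one
or a few conditions (a truncated power law over "breadth", the number of
conditions a gene is called in), a handful of co-regulated modules share a
single condition profile each (so they project to weight-1 cliques), and a
pan-condition module is differentially expressed in every condition (the
pan-cancer motif). Companion reference resources — an interaction network
covering a controlled fraction of intra-module pairs, a regulatory network
with one TF per module, and a gene-set collection with one term per module
plus decoys — carry the ground truth needed for recovery and calibration
tests. Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegnetError
from .io import DEGTable, GeneSetCollection, InteractionNetwork, RegulatoryNetwork


@dataclass
class SimulationParams:
    """Knobs for the synthetic DEG table and reference resources.

    Defaults mirror a pan-cancer-scale study: 18 conditions, 5000 genes,
    a 43-gene pan-condition module, and a breadth distribution decaying as
    k^-2 so the bulk of genes are specific to one or a few conditions.
    """

    n_conditions: int = 18
    n_genes: int = 5000
    breadth_alpha: float = 2.0
    n_modules: int = 8
    module_size_range: tuple[int, int] = (10, 40)
    pan_module_size: int = 43
    direction_mix: float = 0.5
    noise_flip_rate: float = 0.01
    ppi_overlap_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.module_size_range = tuple(self.module_size_range)
        lo, hi = self.module_size_range
        if lo < 2:
            raise DegnetError("module sizes must be >= 2")
        if not 0 <= self.noise_flip_rate <= 1:
            raise DegnetError("noise_flip_rate must be in [0, 1]")
        if not 0 <= self.direction_mix <= 1:
            raise DegnetError("direction_mix must be in [0, 1]")
        if not 0 <= self.ppi_overlap_frac <= 1:
            raise DegnetError("ppi_overlap_frac must be in [0, 1]")
        if self.breadth_alpha <= 0:
            raise DegnetError("breadth_alpha must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_size_range"] = list(self.module_size_range)
        return d


@dataclass
class GroundTruth:
    """Planted structure underlying a simulated DEG table."""

    module_assignments: dict[str, str]  # gene -> module id or "background"
    pan_module: frozenset[str]
    breadth: dict[str, int]  # pre-noise number of conditions per gene
    tf_module_map: dict[str, str] = field(default_factory=dict)
    module_profiles: dict[str, frozenset[str]] = field(default_factory=dict)
    module_direction: dict[str, str] = field(default_factory=dict)

    def module_members(self, module: str) -> frozenset[str]:
        return frozenset(
            g for g, m in self.module_assignments.items() if m == module
        )


PAN_MODULE = "pan"
BACKGROUND = "background"


def _truncated_power_law(rng, alpha: float, kmax: int, size: int) -> np.ndarray:
    """Sample integers on [1, kmax] with P(k) proportional to k^-alpha."""
    ks = np.arange(1, kmax + 1)
    probs = ks.astype(float) ** (-alpha)
    probs /= probs.sum()
    return rng.choice(ks, size=size, p=probs)


def simulate_deg_table(params: SimulationParams) -> tuple[DEGTable, GroundTruth]:
    """Generate a DEG table with planted modules and heavy-tailed breadth.

    Background genes get a condition subset of power-law-distributed size;
    genes of a module all share that module's condition profile and
    direction; pan-module genes are called in every condition. Each record
    carries |log_fc| >= 1 with sign matching its direction and a BH-style
    adjusted p uniform on (0, 0.05). Membership noise then flips each
    (gene, condition) cell independently with ``noise_flip_rate``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    conditions = [f"cond{i + 1:02d}" for i in range(p.n_conditions)]
    genes = [f"g{i + 1:05d}" for i in range(p.n_genes)]

    lo, hi = p.module_size_range
    module_sizes = rng.integers(lo, hi + 1, size=p.n_modules)
    n_planted = p.pan_module_size + int(module_sizes.sum())
    if n_planted > p.n_genes:
        raise DegnetError(
            f"planted modules need {n_planted} genes but n_genes={p.n_genes}"
        )

    assignments: dict[str, str] = {}
    cursor = 0
    pan_genes = genes[cursor:cursor + p.pan_module_size]
    cursor += p.pan_module_size
    for g in pan_genes:
        assignments[g] = PAN_MODULE
    module_ids = [f"module{i + 1}" for i in range(p.n_modules)]
    module_members: dict[str, list[str]] = {}
    for mid, size in zip(module_ids, module_sizes):
        module_members[mid] = genes[cursor:cursor + size]
        cursor += size
        for g in module_members[mid]:
            assignments[g] = mid
    background = genes[cursor:]
    for g in background:
        assignments[g] = BACKGROUND

    # per-module shared condition profile and direction
    profiles: dict[str, frozenset[str]] = {PAN_MODULE: frozenset(conditions)}
    direction_of: dict[str, str] = {
        PAN_MODULE: "up" if rng.random() < p.direction_mix else "down"
    }
    for mid in module_ids:
        breadth = int(
            _truncated_power_law(rng, p.breadth_alpha, p.n_conditions - 1, 1)[0] + 1
        )  # modules span >= 2 conditions so their cliques are non-trivial
        profiles[mid] = frozenset(
            rng.choice(conditions, size=breadth, replace=False)
        )
        direction_of[mid] = "up" if rng.random() < p.direction_mix else "down"

    cond_index = {c: i for i, c in enumerate(conditions)}
    membership = np.zeros((p.n_genes, p.n_conditions), dtype=bool)
    gene_direction: dict[str, str] = {}
    breadth_truth: dict[str, int] = {}
    bg_breadth = _truncated_power_law(rng, p.breadth_alpha, p.n_conditions, len(background))
    for g, b in zip(background, bg_breadth):
        chosen = rng.choice(p.n_conditions, size=int(b), replace=False)
        membership[int(g[1:]) - 1, chosen] = True
        gene_direction[g] = "up" if rng.random() < p.direction_mix else "down"
        breadth_truth[g] = int(b)
    for mid, members in [(PAN_MODULE, pan_genes)] + list(module_members.items()):
        cols = [cond_index[c] for c in profiles[mid]]
        for g in members:
            membership[int(g[1:]) - 1, cols] = True
            gene_direction[g] = direction_of[mid]
            breadth_truth[g] = len(cols)

    if p.noise_flip_rate > 0:
        flips = rng.random(membership.shape) < p.noise_flip_rate
        membership ^= flips

    gi, ci = np.nonzero(membership)
    n_rec = gi.size
    lfc_mag = 1.0 + rng.exponential(1.0, size=n_rec)
    adj_p = rng.uniform(0.0, 0.05, size=n_rec)
    adj_p = np.clip(adj_p, 1e-12, None)  # open interval at 0
    rows = {
        "gene": [genes[i] for i in gi],
        "condition": [conditions[j] for j in ci],
        "log_fc": [
            m if gene_direction[genes[i]] == "up" else -m
            for i, m in zip(gi, lfc_mag)
        ],
        "adj_p": adj_p,
    }
    table = DEGTable(pd.DataFrame(rows))
    truth = GroundTruth(
        module_assignments=assignments,
        pan_module=frozenset(pan_genes),
        breadth=breadth_truth,
        module_profiles=profiles,
        module_direction=direction_of,
    )
    return table, truth


def simulate_references(
    truth: GroundTruth, params: SimulationParams
) -> tuple[InteractionNetwork, RegulatoryNetwork, GeneSetCollection]:
    """Reference resources consistent with the planted modules.

    The interaction network contains each intra-module gene pair with
    probability ``ppi_overlap_frac`` plus random background pairs; the
    regulatory network assigns each module a dedicated TF targeting the
    module plus random decoy genes, alongside decoy TFs with random
    targets; the gene-set collection has one term per module plus decoy
    terms of matched sizes.
    """
    p = params
    rng = np.random.default_rng([p.seed, 1])
    genes = sorted(truth.module_assignments)
    modules = sorted(
        {m for m in truth.module_assignments.values() if m != BACKGROUND}
    )

    ppi_pairs: set[tuple[str, str]] = set()
    for mid in modules:
        members = sorted(truth.module_members(mid))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p.ppi_overlap_frac:
                    ppi_pairs.add((members[i], members[j]))
    n_background_pairs = len(genes)
    idx = rng.integers(0, len(genes), size=(n_background_pairs, 2))
    for a, b in idx:
        if a != b:
            u, v = genes[a], genes[b]
            ppi_pairs.add((u, v) if u <= v else (v, u))
    ppi = InteractionNetwork.from_pairs(ppi_pairs)

    targets_of: dict[str, frozenset[str]] = {}
    tf_map: dict[str, str] = {}
    for mid in modules:
        members = truth.module_members(mid)
        n_decoys = max(1, len(members) // 5)
        decoys = set(rng.choice(genes, size=n_decoys, replace=False))
        tf = f"TF_{mid}"
        targets_of[tf] = frozenset(members | decoys)
        tf_map[tf] = mid
    for i in range(len(modules)):
        size = int(rng.integers(10, 60))
        targets_of[f"TF_decoy{i + 1}"] = frozenset(
            rng.choice(genes, size=size, replace=False)
        )
    grn = RegulatoryNetwork(targets_of)
    truth.tf_module_map = tf_map

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for mid in modules:
        sets[f"SET_{mid}"] = (f"planted members of {mid}", truth.module_members(mid))
    for i in range(len(modules)):
        size = int(rng.integers(10, 60))
        sets[f"SET_decoy{i + 1}"] = (
            "random decoy term",
            frozenset(rng.choice(genes, size=size, replace=False)),
        )
    return ppi, grn, GeneSetCollection(sets)
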