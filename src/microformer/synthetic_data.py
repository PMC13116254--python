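"""Seeded simulator of sparse compositional microbiome tables.

Emulates the structure the rest of the toolkit assumes in real genus-level
surveys: heavy per-sample sparsity, class-specific marker genera of tunable
effect size, planted keystone taxa on which a block of companion taxa
depends, and paired (rank sequence, abundance vector) records obeying a
known rank-abundance law for reconstructor training.

Marker planting preserves the table's marginal presence rate: within a
marker's own class its presence probability is scaled by
``C*effect/(effect+C-1)`` and in the other classes by ``C/(effect+C-1)``,
so the own/other presence-frequency ratio equals ``marker_effect`` exactly
while overall sparsity stays at the configured value. Keystone-coupled taxa
are present only when their keystone is, with conditional probability
``p/p_keystone``, again leaving their marginal presence untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._utils import rng_for
from .corpus_io import AbundanceTable

__all__ = [
    "SimConfig",
    "simulate_corpus",
    "simulate_rank_abundance_pairs",
    "RankAbundancePair",
    "marker_genera",
    "keystone_genera",
    "coupled_genera",
]


class SimConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the community simulator.

    sparsity is the expected fraction of genera absent per sample;
    marker_effect is the multiplicative presence enrichment of a marker in
    its own class; keystone_coupling is the fraction of genera whose
    presence depends on a keystone. abundance_law picks how abundances are
    drawn over present taxa: symmetric Dirichlet, or geometric decay in a
    marker/keystone-biased random order.
    """

    n_samples: int = 500
    n_genera: int = 100
    n_classes: int = 2
    markers_per_class: int = 5
    marker_effect: float = 5.0
    keystone_genera: int = 1
    keystone_coupling: float = 0.3
    keystone_presence: float = 0.7
    keystone_boost: float = 8.0
    base_concentration: float = 1.0
    sparsity: float = 0.8
    abundance_law: Literal["dirichlet", "geometric_decay"] = "dirichlet"
    geometric_rate: float = 0.8
    rank_propensity: float = 3.0
    min_present: int = 0
    class_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sparsity < 1.0:
            raise SimConfigError("sparsity must lie in (0, 1)")
        if self.marker_effect < 1.0:
            raise SimConfigError("marker_effect must be >= 1")
        if self.n_classes < 1:
            raise SimConfigError("need at least one class")
        planted = (self.markers_per_class * self.n_classes + self.keystone_genera
                   + self.n_coupled)
        if planted > self.n_genera:
            raise SimConfigError(
                f"{planted} planted genera exceed n_genera={self.n_genera}"
            )
        p = 1.0 - self.sparsity
        if self.markers_per_class and p * self.marker_effect * self.n_classes / (
                self.marker_effect + self.n_classes - 1) > 1.0:
            raise SimConfigError("marker_effect too large for this sparsity")
        if self.min_present and (1.0 - self.sparsity) * self.n_genera < self.min_present:
            raise SimConfigError(
                f"sparsity {self.sparsity} leaves fewer than min_present="
                f"{self.min_present} genera expected per sample"
            )
        if not 0.0 < self.geometric_rate < 1.0:
            raise SimConfigError("geometric_rate must lie in (0, 1)")

    @property
    def n_coupled(self) -> int:
        if self.keystone_genera == 0:
            return 0
        return int(round(self.keystone_coupling * self.n_genera))

    @property
    def classes(self) -> list[str]:
        if self.class_names is not None:
            return list(self.class_names)
        return [f"class{c}" for c in range(self.n_classes)]


def _genus_names(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_genera))
    return [f"g{j:0{width}d}" for j in range(cfg.n_genera)]


def keystone_genera(cfg: SimConfig) -> list[str]:
    """Names of the planted keystone taxa (the first genus indices)."""
    return _genus_names(cfg)[: cfg.keystone_genera]


def coupled_genera(cfg: SimConfig) -> list[str]:
    """Names of taxa whose presence depends on a keystone."""
    names = _genus_names(cfg)
    return names[cfg.keystone_genera: cfg.keystone_genera + cfg.n_coupled]


def marker_genera(cfg: SimConfig) -> dict[str, list[str]]:
    """Class name -> marker genus names."""
    names = _genus_names(cfg)
    start = cfg.keystone_genera + cfg.n_coupled
    out = {}
    for c, cls in enumerate(cfg.classes):
        lo = start + c * cfg.markers_per_class
        out[cls] = names[lo: lo + cfg.markers_per_class]
    return out


def background_genera(cfg: SimConfig) -> list[str]:
    start = (cfg.keystone_genera + cfg.n_coupled
             + cfg.markers_per_class * cfg.n_classes)
    return _genus_names(cfg)[start:]


def simulate_corpus(cfg: SimConfig) -> tuple[AbundanceTable, dict[str, str]]:
    """Draw a labelled relative-abundance table under the planted model.

    Fully determined by ``cfg.seed``. Returns the table and a sample_id ->
    class-label map (also attached to the table).
    """
    rng = rng_for(cfg.seed, "simulate_corpus")
    names = _genus_names(cfg)
    n, g = cfg.n_samples, cfg.n_genera
    p = 1.0 - cfg.sparsity
    C = cfg.n_classes
    k_own = C * cfg.marker_effect / (cfg.marker_effect + C - 1)
    k_other = C / (cfg.marker_effect + C - 1)

    key_idx = np.arange(cfg.keystone_genera)
    coup_idx = np.arange(cfg.keystone_genera, cfg.keystone_genera + cfg.n_coupled)
    marker_idx = {}
    start = cfg.keystone_genera + cfg.n_coupled
    for c in range(C):
        lo = start + c * cfg.markers_per_class
        marker_idx[c] = np.arange(lo, lo + cfg.markers_per_class)
    # each coupled genus depends on one keystone, round-robin
    owner = (key_idx[coup_idx % max(cfg.keystone_genera, 1)]
             if cfg.keystone_genera else np.empty(0, dtype=int))

    classes = rng.integers(0, C, size=n)
    values = np.zeros((n, g))
    sample_ids = [f"s{i:05d}" for i in range(n)]

    p_coup_cond = min(1.0, p / cfg.keystone_presence) if cfg.keystone_genera else 0.0

    for i in range(n):
        c = classes[i]
        probs = np.full(g, p)
        for cc in range(C):
            probs[marker_idx[cc]] = p * (k_own if cc == c else k_other)
        present = rng.random(g) < probs
        if cfg.keystone_genera:
            present[key_idx] = rng.random(cfg.keystone_genera) < cfg.keystone_presence
            present[coup_idx] = present[owner] & (rng.random(len(coup_idx)) < p_coup_cond)
        if cfg.min_present and present.sum() < cfg.min_present:
            absent = np.flatnonzero(~present)
            top_up = rng.choice(absent, size=cfg.min_present - present.sum(),
                                replace=False)
            present[top_up] = True
        idx = np.flatnonzero(present)
        if idx.size == 0:
            idx = rng.choice(g, size=max(cfg.min_present, 2), replace=False)
            present[idx] = True
            idx = np.flatnonzero(present)

        conc = np.full(idx.size, cfg.base_concentration)
        conc[np.isin(idx, marker_idx[c])] *= cfg.marker_effect
        if cfg.keystone_genera:
            conc[np.isin(idx, key_idx)] *= cfg.keystone_boost
            conc[np.isin(idx, coup_idx)] *= 2.0
        draw = rng.gamma(conc)
        draw = np.maximum(draw, 1e-12)
        if cfg.abundance_law == "dirichlet":
            abund = draw / draw.sum()
        else:  # geometric decay in the concentration-biased random order
            order = np.argsort(-draw)
            ranks = np.empty(idx.size, dtype=int)
            ranks[order] = np.arange(1, idx.size + 1)
            abund = cfg.geometric_rate ** ranks
            abund = abund / abund.sum()
        values[i, idx] = abund

    labels = {sid: cfg.classes[c] for sid, c in zip(sample_ids, classes)}
    return AbundanceTable(sample_ids, names, values, labels), labels


@dataclass(frozen=True)
class RankAbundancePair:
    """A rank sequence and the abundance vector it was derived from.

    ``genus_indices`` lists present genera ordered by rank (rank 1 first);
    ``abundances`` is the dense length-``n_genera`` simplex vector.
    Self-consistent: re-ranking ``abundances`` reproduces ``genus_indices``.
    """

    genus_indices: tuple[int, ...]
    abundances: np.ndarray


def simulate_rank_abundance_pairs(cfg: SimConfig, n: int) -> list[RankAbundancePair]:
    """Draw paired (rank sequence, abundance vector) records.

    Under ``geometric_decay`` the abundance of the rank-r taxon is
    proportional to ``rate**r`` exactly; under ``dirichlet`` ranks are the
    descending order of a Dirichlet draw. Both laws are monotone in rank,
    which the reconstructor relies on.

    Which taxon occupies which rank follows a Plackett-Luce draw with
    per-genus weights exp(-rank_propensity * j / n_genera): as in real
    communities, low-index genera tend toward top ranks while any
    permutation stays possible. Presence itself is uniform, so the rank
    structure carries no information about which taxa occur.
    """
    rng = rng_for(cfg.seed, "simulate_rank_abundance_pairs")
    p = 1.0 - cfg.sparsity
    propensity = np.exp(-cfg.rank_propensity * np.arange(cfg.n_genera)
                        / cfg.n_genera)
    pairs = []
    for _ in range(n):
        m = max(2, rng.binomial(cfg.n_genera, p))
        subset = rng.choice(cfg.n_genera, size=m, replace=False)
        dense = np.zeros(cfg.n_genera)
        if cfg.abundance_law == "geometric_decay":
            gumbel = rng.gumbel(size=m)
            order = subset[np.argsort(-(np.log(propensity[subset]) + gumbel))]
            weights = cfg.geometric_rate ** np.arange(1, m + 1)
            dense[order] = weights / weights.sum()
        else:
            draw = rng.dirichlet(np.full(m, cfg.base_concentration))
            # enforce strict ordering so ranks are unambiguous
            draw = np.sort(draw)[::-1]
            order = rng.permutation(subset)
            dense[order] = draw
        ranked = tuple(int(j) for j in np.argsort(-dense)[:m])
        pairs.append(RankAbundancePair(ranked, dense))
    return pairs
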