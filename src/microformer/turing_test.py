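"""The two-phase Microbiome Turing Test: do generated tables imitate real ones?

Phase 1 measures distributional fidelity per class label and averages over
labels: paired cosine similarity, mean absolute error, and Spearman
correlation between real and generated samples; Shannon (natural log) and
Simpson alpha diversity; and a sparsity entropy — the entropy of the uniform
distribution over a sample's present taxa, ln(richness) — whose real/
generated distributions are compared with a Wilcoxon signed-rank test.

Phase 2 measures biological relevance: a Random Forest trained on real data
classifies the generated samples (macro one-vs-rest ROC-AUC); the top-500
important features of real- and generated-trained forests are intersected
(biomarker overlap); and Pearson co-occurrence networks of both tables are
compared on density, average degree, and modularity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio.diversity.alpha import shannon, simpson
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from ._utils import rng_for
from .corpus_io import AbundanceTable

__all__ = [
    "TuringReport",
    "phase1_metrics",
    "phase2_classifier",
    "correlation_network",
    "full_report",
]

TOP_FEATURES = 500
DEFAULT_R_THRESHOLD = 0.3


def _align(tables: Sequence[AbundanceTable]) -> list[pd.DataFrame]:
    """Outer-join the genus universes, zero-filling, shared column order."""
    frames = [t.to_dataframe() for t in tables]
    genera = sorted(set().union(*[set(f.columns) for f in frames]))
    return [f.reindex(columns=genera, fill_value=0.0) for f in frames]


def _labels_for(table: AbundanceTable, labels: dict[str, str] | None) -> pd.Series:
    src = labels if labels is not None else table.labels
    if src is None:
        raise ValueError("labels required: attach to table or pass explicitly")
    return pd.Series({s: src[s] for s in table.sample_ids})


def _sparsity_entropy(row: np.ndarray) -> float:
    richness = int((row > 0).sum())
    return float(np.log(richness)) if richness > 0 else 0.0


def _alpha_shannon(row: np.ndarray) -> float:
    nz = row[row > 0]
    return float(shannon(nz / nz.sum(), base=np.e)) if nz.size else 0.0


def _alpha_simpson(row: np.ndarray) -> float:
    nz = row[row > 0]
    return float(simpson(nz / nz.sum())) if nz.size else 0.0


def _pairwise_block(real: np.ndarray, gen: np.ndarray) -> dict[str, np.ndarray]:
    cos = _sk_cosine(real, gen).diagonal().copy()
    mae = np.abs(real - gen).mean(axis=1)
    spear = np.empty(len(real))
    for i in range(len(real)):
        if np.std(real[i]) == 0 or np.std(gen[i]) == 0:
            spear[i] = 0.0
        else:
            spear[i] = sps.spearmanr(real[i], gen[i]).statistic
    return {"cosine_similarity": cos, "mae": mae, "spearman": spear}


def _mean_ci(group_values: list[np.ndarray], rng: np.random.Generator,
             n_boot: int = 200) -> dict[str, float]:
    """Mean over group means, with a bootstrap 95% CI resampling within groups."""
    mean = float(np.mean([np.mean(v) for v in group_values]))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = np.mean([
            np.mean(v[rng.integers(0, len(v), len(v))]) for v in group_values])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo, hi = min(lo, mean), max(hi, mean)
    return {"mean": mean, "ci_low": float(lo), "ci_high": float(hi)}


def phase1_metrics(real: AbundanceTable, gen: AbundanceTable,
                   labels: dict[str, str] | None = None,
                   seed: int = 0, n_boot: int = 200) -> dict:
    """First-order metrics per group, averaged over groups with bootstrap CIs.

    Within each group both sides are sorted by sample id, the larger side is
    down-sampled (seeded) to the smaller, and samples are paired by index.
    """
    rdf, gdf = _align([real, gen])
    rl = _labels_for(real, labels)
    gl = _labels_for(gen, labels)
    rng = rng_for(seed, "phase1")
    groups = sorted(set(rl) & set(gl))
    per_group: dict[str, list[np.ndarray]] = {
        k: [] for k in ("cosine_similarity", "mae", "spearman")}
    alpha = {("shannon", side): [] for side in ("real", "gen")}
    alpha.update({("simpson", side): [] for side in ("real", "gen")})
    sparsity = {"real": [], "gen": []}
    wilcoxon_ps = []
    used_groups = []
    for grp in groups:
        r_ids = sorted(rl.index[rl == grp])
        g_ids = sorted(gl.index[gl == grp])
        if not r_ids or not g_ids:
            warnings.warn(f"group {grp!r} empty on one side; skipped", stacklevel=2)
            continue
        m = min(len(r_ids), len(g_ids))
        if len(r_ids) > m:
            r_ids = sorted(rng.choice(r_ids, size=m, replace=False))
        if len(g_ids) > m:
            g_ids = sorted(rng.choice(g_ids, size=m, replace=False))
        R = rdf.loc[r_ids].values
        G = gdf.loc[g_ids].values
        block = _pairwise_block(R, G)
        for k, v in block.items():
            per_group[k].append(v)
        alpha[("shannon", "real")].append(np.array([_alpha_shannon(r) for r in R]))
        alpha[("shannon", "gen")].append(np.array([_alpha_shannon(g) for g in G]))
        alpha[("simpson", "real")].append(np.array([_alpha_simpson(r) for r in R]))
        alpha[("simpson", "gen")].append(np.array([_alpha_simpson(g) for g in G]))
        se_r = np.array([_sparsity_entropy(r) for r in R])
        se_g = np.array([_sparsity_entropy(g) for g in G])
        sparsity["real"].append(se_r)
        sparsity["gen"].append(se_g)
        diff = se_r - se_g
        if np.allclose(diff, 0):
            wilcoxon_ps.append(1.0)
        else:
            wilcoxon_ps.append(float(sps.wilcoxon(se_r, se_g).pvalue))
        used_groups.append(grp)
    if not used_groups:
        raise ValueError("no group present on both sides")
    out = {k: _mean_ci(v, rng, n_boot) for k, v in per_group.items()}
    out["alpha_diversity"] = {
        "shannon_real": _mean_ci(alpha[("shannon", "real")], rng, n_boot),
        "shannon_gen": _mean_ci(alpha[("shannon", "gen")], rng, n_boot),
        "simpson_real": _mean_ci(alpha[("simpson", "real")], rng, n_boot),
        "simpson_gen": _mean_ci(alpha[("simpson", "gen")], rng, n_boot),
    }
    out["sparsity_entropy"] = {
        "real": _mean_ci(sparsity["real"], rng, n_boot),
        "gen": _mean_ci(sparsity["gen"], rng, n_boot),
    }
    out["wilcoxon_p"] = float(np.mean(wilcoxon_ps))
    out["groups"] = used_groups
    return out


def _fit_rf(X: np.ndarray, y: np.ndarray, seed: int) -> RandomForestClassifier:
    rf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def _macro_auc(rf: RandomForestClassifier, X: np.ndarray, y: np.ndarray) -> float:
    proba = rf.predict_proba(X)
    if len(rf.classes_) == 2:
        return float(roc_auc_score(y, proba[:, 1]))
    return float(roc_auc_score(y, proba, multi_class="ovr", average="macro",
                               labels=rf.classes_))


def phase2_classifier(real_train: AbundanceTable, gen: AbundanceTable,
                      labels: dict[str, str] | None = None, seed: int = 0,
                      top_k: int = TOP_FEATURES) -> dict:
    """Real-trained Random Forest scored on generated data + biomarker overlap.

    Overlap counts shared features among the top ``min(top_k, n_features)``
    importances of the real-trained and generated-trained forests.
    """
    rdf, gdf = _align([real_train, gen])
    y_r = _labels_for(real_train, labels).loc[rdf.index].values
    y_g = _labels_for(gen, labels).loc[gdf.index].values
    if len(set(y_r)) < 2 or len(set(y_g)) < 2:
        raise ValueError("phase 2 needs >= 2 classes on both sides")
    rf_real = _fit_rf(rdf.values, y_r, seed)
    rf_gen = _fit_rf(gdf.values, y_g, seed)
    auc = _macro_auc(rf_real, gdf.values, y_g)
    k = min(top_k, rdf.shape[1])
    top_real = set(np.argsort(-rf_real.feature_importances_)[:k])
    top_gen = set(np.argsort(-rf_gen.feature_importances_)[:k])
    return {"roc_auc": auc, "biomarker_overlap": len(top_real & top_gen),
            "n_features_compared": k}


def correlation_network(table: AbundanceTable,
                        r_threshold: float = DEFAULT_R_THRESHOLD) -> dict:
    """Pearson co-occurrence network statistics of one table.

    Nodes are genera (zero-variance genera excluded); an edge joins two
    genera when |r| >= r_threshold. Reports density = 2E/(V(V-1)), average
    degree = 2E/V, and the modularity of the greedy-community partition
    (0.0 for an edgeless graph).
    """
    if table.n_samples < 3 or table.n_genera < 2:
        raise ValueError("need >= 3 samples and >= 2 genera")
    vals = table.values
    keep = vals.std(axis=0) > 0
    names = [g for g, k in zip(table.genus_names, keep) if k]
    vals = vals[:, keep]
    if len(names) < 2:
        raise ValueError("fewer than 2 genera with nonzero variance")
    corr = np.corrcoef(vals.T)
    G = nx.Graph()
    G.add_nodes_from(names)
    iu, ju = np.triu_indices(len(names), k=1)
    for i, j in zip(iu, ju):
        if abs(corr[i, j]) >= r_threshold:
            G.add_edge(names[i], names[j])
    V, E = G.number_of_nodes(), G.number_of_edges()
    if E == 0:
        modularity = 0.0
    else:
        comms = nx.community.greedy_modularity_communities(G)
        modularity = float(nx.community.modularity(G, comms))
    return {
        "density": 2 * E / (V * (V - 1)) if V > 1 else 0.0,
        "avg_degree": 2 * E / V if V else 0.0,
        "modularity": modularity,
        "n_nodes": V,
        "n_edges": E,
    }


@dataclass
class TuringReport:
    """Assembled two-phase report; serializes to JSON and a plain table."""

    phase1: dict
    phase2: dict
    networks: dict
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=float)

    @classmethod
    def from_json(cls, text: str) -> "TuringReport":
        obj = json.loads(text)
        return cls(obj["phase1"], obj["phase2"], obj["networks"],
                   obj.get("seed", 0))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    def to_text(self) -> str:
        lines = ["Microbiome Turing Test", "=" * 40, "Phase 1 (distributional)"]
        for k in ("cosine_similarity", "mae", "spearman"):
            m = self.phase1[k]
            lines.append(f"  {k:18s} {m['mean']:8.4f}  "
                         f"[{m['ci_low']:.4f}, {m['ci_high']:.4f}]")
        sh = self.phase1["alpha_diversity"]
        lines.append(f"  shannon (real/gen) {sh['shannon_real']['mean']:.4f} / "
                     f"{sh['shannon_gen']['mean']:.4f}")
        lines.append(f"  simpson (real/gen) {sh['simpson_real']['mean']:.4f} / "
                     f"{sh['simpson_gen']['mean']:.4f}")
        sp = self.phase1["sparsity_entropy"]
        lines.append(f"  sparsity entropy   {sp['real']['mean']:.4f} / "
                     f"{sp['gen']['mean']:.4f}  (wilcoxon p="
                     f"{self.phase1['wilcoxon_p']:.3g})")
        lines.append("Phase 2 (biological)")
        lines.append(f"  roc_auc            {self.phase2['roc_auc']:.4f}")
        lines.append(f"  biomarker_overlap  {self.phase2['biomarker_overlap']}"
                     f" / {self.phase2['n_features_compared']}")
        for side in ("real", "gen"):
            n = self.networks[side]
            lines.append(f"  network[{side}] density={n['density']:.4f} "
                         f"avg_degree={n['avg_degree']:.2f} "
                         f"modularity={n['modularity']:.4f}")
        return "\n".join(lines)


def full_report(real_train: AbundanceTable, real_test: AbundanceTable,
                gen: AbundanceTable, labels: dict[str, str] | None = None,
                seed: int = 0, r_threshold: float = DEFAULT_R_THRESHOLD,
                n_boot: int = 200) -> TuringReport:
    """Run both phases: phase 1 and networks compare real_test with gen;
    phase 2 trains on real_train and scores gen."""
    merged = None
    if labels is None:
        merged = {}
        for t in (real_train, real_test, gen):
            if t.labels:
                merged.update(t.labels)
    lab = labels if labels is not None else merged
    p1 = phase1_metrics(real_test, gen, lab, seed=seed, n_boot=n_boot)
    p2 = phase2_classifier(real_train, gen, lab, seed=seed)
    networks = {"real": correlation_network(real_test, r_threshold),
                "gen": correlation_network(gen, r_threshold)}
    return TuringReport(p1, p2, networks, seed)
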