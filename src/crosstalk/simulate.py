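"""Synthetic case-control scRNA-seq generator with a known interaction network.

The generator works top-down from a ground-truth Bayesian network over
cell-type abundance states: for every sample it ancestrally samples a binary
low/high state per cell type, maps states to composition fractions (Gaussian
around a low or high mean, renormalized to sum to 1), draws cell counts
multinomially and then draws each cell's expression as Poisson counts —
elevated on the cell type's marker genes, baseline elsewhere — optionally
followed by independent Bernoulli dropout (zeroing).

Dropout degrades the pipeline through cell-type annotation: the recovery
experiments re-annotate cells from their marker expression
(:func:`annotate_by_markers`) rather than using the generator's true labels,
so noisier expression means noisier compositions and a harder network to
recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .bn import BnModel, Dag
from .bootstrap import EdgeCountTable, bootstrap_edges

__all__ = [
    "SimulationTruth",
    "RecoveryMetrics",
    "make_truth",
    "simulate_dataset",
    "simulate_case_control",
    "annotate_by_markers",
    "evaluate_recovery",
    "dropout_sweep",
    "recovery_experiment",
    "simulate_ligand_effect",
]


@dataclass
class SimulationTruth:
    """Ground truth of a simulation: the network, the state-to-fraction map
    and the expression model."""

    model: BnModel
    fraction_map: dict[str, tuple[float, float, float]]  # type -> (low, high, sd)
    markers: dict[str, list[str]]
    genes: list[str]
    baseline_expr: float
    marker_expr: float
    dropout: float = 0.0
    background_type: str | None = None  # stable non-modeled population
    background_mass: float = 0.0  # its raw composition mass before renormalization

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        for t, (low, high, _sd) in self.fraction_map.items():
            if not low < high:
                raise ValueError(f"fraction map for {t!r}: low mean must be < high mean")

    @property
    def cell_types(self) -> tuple[str, ...]:
        return self.model.dag.nodes

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.model.dag.edges)

    def with_dropout(self, rate: float) -> "SimulationTruth":
        return replace(self, dropout=rate)


def make_truth(
    n_types: int = 10,
    n_edges: int = 6,
    seed: int = 0,
    edge_strengths: Sequence[float] = (0.9, 0.9, 0.9, 0.9, 0.7, 0.3),
    leak: float = 0.1,
    low_mean: float = 0.03,
    high_mean: float = 0.12,
    fraction_sd: float = 0.025,
    n_genes: int = 200,
    markers_per_type: int = 5,
    baseline_expr: float = 0.2,
    marker_expr: float = 1.8,
    dropout: float = 0.0,
    background_mass: float = 2.0,
) -> SimulationTruth:
    """Random ground truth: a DAG with exactly ``n_edges`` edges and
    noisy-OR conditional probability tables.

    Each non-root node follows a noisy-OR of its parents: with no active
    parent it is high with probability ``leak``; each active parent
    independently pushes it high with its edge's transmission strength, so
    P(high | parents) = 1 - (1 - leak) * prod(1 - s_e) over active parents.
    Roots are Bernoulli(0.5).  ``edge_strengths`` is cycled over the edges
    in placement order; the default ladder mixes strong interactions with a
    medium and a near-threshold one, because interaction strengths in real
    tissues are heterogeneous and a generator in which every interaction is
    equally strong says nothing about behaviour at the detection margin.
    Marker sets are disjoint, ``markers_per_type`` genes per type.

    ``background_mass > 0`` adds a stable non-modeled cell population
    ("Other") carrying that much raw composition mass.  Real tissues are
    dominated by populations whose abundance does not track the interactions
    of interest; without this ballast the renormalization to fractions
    couples every modeled type to every other through the shared denominator
    and the abundance states stop being separable no matter how clean the
    expression data are.
    """
    n_marker_sets = n_types + (1 if background_mass > 0 else 0)
    if n_edges > n_types * (n_types - 1) // 2:
        raise ValueError(f"cannot place {n_edges} edges among {n_types} nodes acyclically")
    if markers_per_type * n_marker_sets > n_genes:
        raise ValueError("not enough genes for disjoint marker sets")
    rng = np.random.default_rng(seed)
    types = [f"CT{i:02d}" for i in range(n_types)]
    order = rng.permutation(n_types)
    # Edge placement: first pair up nodes disjointly (so interactions are
    # spread across the tissue rather than concentrated on hubs), then wire
    # any remaining edges between already-covered nodes under a degree cap
    # of 2 — hub nodes with many noisy-OR parents have near-constant states,
    # which makes their edges undetectable in principle.
    max_degree = 2
    if n_edges > n_types * max_degree // 2:
        raise ValueError("too many edges for the degree cap")
    chosen: list[tuple[str, str]] = []
    degree = {t: 0 for t in types}
    # all edges point forward along the permutation, so the graph is acyclic
    for i in range(min(n_edges, n_types // 2)):
        u, v = types[order[2 * i]], types[order[2 * i + 1]]
        chosen.append((u, v))
        degree[u] += 1
        degree[v] += 1
    if len(chosen) < n_edges:
        pairs = [
            (types[order[i]], types[order[j]])
            for i in range(n_types)
            for j in range(i + 1, n_types)
        ]
        for k in rng.permutation(len(pairs)):
            if len(chosen) == n_edges:
                break
            u, v = pairs[k]
            if (
                (u, v) not in chosen
                and degree[u] < max_degree
                and degree[v] < max_degree
            ):
                chosen.append((u, v))
                degree[u] += 1
                degree[v] += 1
        if len(chosen) < n_edges:
            raise RuntimeError("could not place all edges under the degree cap")
    dag = Dag(tuple(types), set(chosen))

    if not 0 < leak < 1:
        raise ValueError("leak must be in (0, 1)")
    strength = {
        e: float(edge_strengths[i % len(edge_strengths)]) for i, e in enumerate(chosen)
    }
    cpts, orders = {}, {}
    for t in types:
        pa = dag.parents(t)
        orders[t] = pa
        k = len(pa)
        table = np.empty((1 << k, 2))
        if k == 0:
            table[0] = [0.5, 0.5]
        else:
            s = [strength[(p, t)] for p in pa]
            for c in range(1 << k):
                off = np.prod([1 - s[i] for i in range(k) if (c >> i) & 1])
                p1 = 1 - (1 - leak) * off
                table[c] = [1 - p1, p1]
        cpts[t] = table
    model = BnModel(dag=dag, cpts=cpts, parent_order=orders)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    marker_types = types + (["Other"] if background_mass > 0 else [])
    markers = {
        t: genes[i * markers_per_type : (i + 1) * markers_per_type]
        for i, t in enumerate(marker_types)
    }
    fraction_map = {t: (low_mean, high_mean, fraction_sd) for t in types}
    return SimulationTruth(
        model=model,
        fraction_map=fraction_map,
        markers=markers,
        genes=genes,
        baseline_expr=baseline_expr,
        marker_expr=marker_expr,
        dropout=dropout,
        background_type="Other" if background_mass > 0 else None,
        background_mass=background_mass,
    )


def _all_types(truth: SimulationTruth) -> list[str]:
    out = list(truth.cell_types)
    if truth.background_type is not None:
        out.append(truth.background_type)
    return out


def sample_fractions(
    truth: SimulationTruth, states: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Map binary abundance states to composition fractions (rows sum to 1).

    Columns follow the modeled cell types, with the background population
    (if any) appended last."""
    low = np.array([truth.fraction_map[t][0] for t in truth.cell_types])
    high = np.array([truth.fraction_map[t][1] for t in truth.cell_types])
    sd = np.array([truth.fraction_map[t][2] for t in truth.cell_types])
    s = states[list(truth.cell_types)].to_numpy()
    mean = np.where(s == 1, high, low)
    sdm = np.broadcast_to(sd, mean.shape)
    if truth.background_type is not None:
        mean = np.column_stack([mean, np.full(len(mean), truth.background_mass)])
        sdm = np.column_stack([sdm, np.full(len(mean), sd.mean())])
    raw = np.maximum(rng.normal(mean, sdm), 1e-4)
    return raw / raw.sum(axis=1, keepdims=True)


def _rate_matrix(truth: SimulationTruth) -> np.ndarray:
    """Poisson rate per (cell type, gene); background row last if present."""
    gene_idx = {g: i for i, g in enumerate(truth.genes)}
    types = _all_types(truth)
    rates = np.full((len(types), len(truth.genes)), truth.baseline_expr)
    for i, t in enumerate(types):
        for g in truth.markers[t]:
            rates[i, gene_idx[g]] = truth.marker_expr
    return rates


def simulate_dataset(
    truth: SimulationTruth,
    n_samples: int = 30,
    cells_per_sample: int = 1000,
    seed: int = 0,
    condition: str = "case",
) -> ad.AnnData:
    """Generate one condition's worth of samples from the ground truth.

    The returned AnnData carries the generator's *true* cell-type labels in
    ``obs['cell_type']``; recovery pipelines that want dropout to matter
    should re-annotate with :func:`annotate_by_markers`.
    """
    rng = np.random.default_rng(seed)
    states = truth.model.sample(n_samples, rng)
    fractions = sample_fractions(truth, states, rng)
    rates = _rate_matrix(truth)
    types = _all_types(truth)

    xs, sample_ids, type_labels = [], [], []
    for s in range(n_samples):
        counts = rng.multinomial(cells_per_sample, fractions[s])
        for i in range(len(types)):
            if counts[i] == 0:
                continue
            xs.append(rng.poisson(rates[i], size=(counts[i], len(truth.genes))))
            type_labels.extend([types[i]] * counts[i])
        sample_ids.extend([f"{condition}_s{s:03d}"] * cells_per_sample)
    X = np.concatenate(xs).astype(np.float32)
    if truth.dropout > 0:
        X[rng.random(X.shape) < truth.dropout] = 0.0

    obs = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": condition,
            "cell_type": type_labels,
        },
        index=[f"{condition}_c{i:06d}" for i in range(len(sample_ids))],
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=truth.genes))


def simulate_case_control(
    truth_case: SimulationTruth,
    truth_control: SimulationTruth,
    n_samples: int = 30,
    cells_per_sample: int = 1000,
    seed: int = 0,
) -> ad.AnnData:
    """Two conditions, one AnnData; case and control may differ in their
    ground-truth networks (e.g. an edge planted only in the case generator)."""
    ss = np.random.SeedSequence(seed).generate_state(2) % 2**31
    case = simulate_dataset(truth_case, n_samples, cells_per_sample, int(ss[0]), "case")
    control = simulate_dataset(
        truth_control, n_samples, cells_per_sample, int(ss[1]), "control"
    )
    out = ad.concat([case, control], index_unique=None)
    out.obs = out.obs.astype(str)
    return out


def annotate_by_markers(expr: ad.AnnData, markers: dict[str, list[str]]) -> ad.AnnData:
    """Re-annotate cells by their strongest marker set.

    Each cell is assigned the type whose marker genes have the highest summed
    expression (ties break on type order).  This is the stand-in for the
    upstream clustering/annotation step of a real pipeline, and the channel
    through which expression noise (dropout) corrupts composition fractions.
    """
    types = list(markers)
    gene_idx = {g: i for i, g in enumerate(expr.var_names)}
    M = np.zeros((expr.n_vars, len(types)))
    for j, t in enumerate(types):
        for g in markers[t]:
            M[gene_idx[g], j] = 1.0
    scores = np.asarray(expr.X @ M)
    out = expr.copy()
    out.obs["cell_type"] = [types[j] for j in scores.argmax(axis=1)]
    return out


@dataclass(frozen=True)
class RecoveryMetrics:
    """Edge-recovery scores of a predicted network against the ground truth."""

    tp: int
    fp: int
    n_predicted: int
    n_truth: int
    precision_flagged: bool  # True when nothing was predicted (precision = 1 by convention)

    @property
    def accuracy(self) -> float:
        return self.tp / self.n_truth

    @property
    def precision(self) -> float:
        return 1.0 if self.n_predicted == 0 else self.tp / self.n_predicted

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "n_predicted": self.n_predicted,
            "n_truth": self.n_truth,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "precision_flagged": self.precision_flagged,
        }


def evaluate_recovery(
    predicted: EdgeCountTable,
    truth: SimulationTruth,
    threshold: int = 20,
    direction_sensitive: bool = False,
) -> RecoveryMetrics:
    """Score thresholded bootstrap counts against the ground-truth edges.

    accuracy = tp / #truth edges, precision = tp / #predicted.  Matching is
    undirected by default because edge orientation within a Markov
    equivalence class is not identifiable from observational data; the
    threshold always applies to a single directed count (two directions of
    one pair are collapsed only after thresholding), so an association whose
    orientation wobbles between bootstrap iterations must still be
    consistently present in one direction to be called.
    """
    called = {p for p, c in predicted.counts.items() if c >= threshold}
    if direction_sensitive:
        pred_set, truth_set = called, set(truth.edges)
    else:
        pred_set = {frozenset(p) for p in called}
        truth_set = {frozenset(e) for e in truth.edges}
    tp = len(pred_set & truth_set)
    return RecoveryMetrics(
        tp=tp,
        fp=len(pred_set) - tp,
        n_predicted=len(pred_set),
        n_truth=len(truth_set),
        precision_flagged=len(pred_set) == 0,
    )


def recovery_experiment(
    seed: int = 0,
    dropout: float = 0.0,
    n_replicates: int = 5,
    n_types: int = 10,
    n_edges: int = 6,
    n_samples: int = 30,
    cells_per_sample: int = 300,
    n_iter: int = 100,
    threshold: int = 20,
    cell_frac: float = 0.8,
    min_cells: int = 100,
) -> pd.DataFrame:
    """The full simulate -> annotate -> bootstrap -> score loop, replicated.

    Each replicate draws a fresh ground truth, simulates ``n_samples``
    samples per condition for two conditions from that same truth (the
    case-control layout with a shared generative regime), re-annotates cells
    from marker expression, runs the bootstrapped structure learning on the
    pooled samples and scores edge recovery.  Returns one row per replicate;
    summaries (e.g. the median replicate) are left to the caller.
    """
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_replicates) % 2**31
    rows = []
    for r in range(n_replicates):
        truth = make_truth(
            n_types=n_types, n_edges=n_edges, seed=int(seeds[3 * r]), dropout=dropout
        )
        expr = simulate_case_control(
            truth, truth, n_samples=n_samples, cells_per_sample=cells_per_sample,
            seed=int(seeds[3 * r + 1]),
        )
        expr = annotate_by_markers(expr, truth.markers)
        counts = bootstrap_edges(
            expr, None, n_iter=n_iter, cell_frac=cell_frac,
            min_cells=min_cells, seed=int(seeds[3 * r + 2]),
            cell_types=list(truth.cell_types),
        )
        metrics = evaluate_recovery(counts, truth, threshold=threshold)
        rows.append({"replicate": r, "dropout": dropout, **metrics.as_dict()})
    return pd.DataFrame(rows)


def dropout_sweep(
    truth: SimulationTruth,
    rates: Sequence[float],
    seed: int = 0,
    n_samples: int = 30,
    cells_per_sample: int = 300,
    n_iter: int = 100,
    threshold: int = 20,
    cell_frac: float = 0.8,
    min_cells: int = 100,
) -> pd.DataFrame:
    """One full simulate -> bootstrap -> score run per dropout rate,
    holding the ground-truth network fixed."""
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(rates)) % 2**31
    rows = []
    for i, rate in enumerate(rates):
        t = truth.with_dropout(rate)
        expr = simulate_case_control(
            t, t, n_samples=n_samples, cells_per_sample=cells_per_sample,
            seed=int(seeds[2 * i]),
        )
        expr = annotate_by_markers(expr, t.markers)
        counts = bootstrap_edges(
            expr, None, n_iter=n_iter, cell_frac=cell_frac,
            min_cells=min_cells, seed=int(seeds[2 * i + 1]),
            cell_types=list(t.cell_types),
        )
        metrics = evaluate_recovery(counts, t, threshold=threshold)
        rows.append({"rate": rate, **metrics.as_dict()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted ligand effect (for the regression stage)


def simulate_ligand_effect(
    n_ligands: int = 20,
    n_targets: int = 200,
    n_active: int = 3,
    seed: int = 0,
    autocrine: bool = False,
    n_samples: int = 3,
    cells_per_group: int = 200,
    density: float = 0.3,
    ligand_base: float = 5.0,
    target_base: float = 5.0,
    noise_sd: float = 0.4,
):
    """Two cell types where targets in the receiver respond to a sparse set
    of active ligands in the sender (or in the receiver itself when
    ``autocrine=True``).

    Returns ``(expr, prior, true_alpha, info)`` where ``info`` names the
    sender/receiver types and conditions.  Target log fold changes are built
    as I @ (L * alpha) plus Gaussian noise of scale ``noise_sd``; the
    non-causal cell type's ligands carry an unrelated decoy fold-change
    pattern, so the within-cell-type control has signal-free but non-trivial
    inputs — exactly the situation the control must reject.
    """
    from .io import LigandTargetMatrix  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    ligands = [f"LG{i:02d}" for i in range(n_ligands)]
    targets = [f"TG{i:03d}" for i in range(n_targets)]
    potential = rng.uniform(0.2, 1.0, size=(n_targets, n_ligands)) * (
        rng.random((n_targets, n_ligands)) < density
    )
    # every target needs at least one ligand link, every ligand one target
    for t in range(n_targets):
        if potential[t].sum() == 0:
            potential[t, rng.integers(n_ligands)] = rng.uniform(0.2, 1.0)
    for l in range(n_ligands):
        if potential[:, l].sum() == 0:
            potential[rng.integers(n_targets), l] = rng.uniform(0.2, 1.0)
    prior = LigandTargetMatrix(
        table=pd.DataFrame(potential, index=targets, columns=ligands)
    )

    active = rng.choice(n_ligands, size=n_active, replace=False)
    alpha = np.zeros(n_ligands)
    alpha[active] = rng.uniform(0.8, 1.5, size=n_active) * rng.choice([-1, 1], n_active)
    lfc = rng.normal(0.0, 0.15, size=n_ligands)
    lfc[active] = rng.uniform(0.6, 1.0, size=n_active) * np.sign(rng.normal(size=n_active))
    decoy_lfc = rng.normal(0.0, 0.3, size=n_ligands)  # unrelated ligand changes
    delta = potential @ (lfc * alpha)
    delta = np.clip(delta + rng.normal(0.0, noise_sd, size=n_targets), -1.5, 1.5)

    source = "receiver" if autocrine else "sender"
    genes = ligands + targets
    gene_idx = {g: i for i, g in enumerate(genes)}

    def means(cell_type: str, cond: str) -> np.ndarray:
        m = np.full(len(genes), 0.5)
        pattern = lfc if cell_type == source else decoy_lfc
        if cond == "a":
            m[: n_ligands] = np.maximum((ligand_base + 1) * np.exp(pattern) - 1, 0.01)
        else:
            m[: n_ligands] = np.full(n_ligands, ligand_base)
        if cell_type == "receiver":
            if cond == "a":
                m[n_ligands:] = np.maximum((target_base + 1) * np.exp(delta) - 1, 0.01)
            else:
                m[n_ligands:] = target_base
        return m

    xs, rows = [], []
    for cell_type in ("sender", "receiver"):
        for cond in ("a", "b"):
            for s in range(n_samples):
                mu = means(cell_type, cond)
                xs.append(rng.poisson(mu, size=(cells_per_group, len(genes))))
                rows.extend(
                    {"sample_id": f"{cond}_s{s}", "condition": cond, "cell_type": cell_type}
                    for _ in range(cells_per_group)
                )
    X = np.concatenate(xs).astype(np.float32)
    obs = pd.DataFrame(rows, index=[f"c{i:06d}" for i in range(len(rows))])
    expr = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    info = {
        "sender": "sender",
        "receiver": "receiver",
        "cond_a": "a",
        "cond_b": "b",
        "active_ligands": [ligands[i] for i in active],
    }
    return expr, prior, pd.Series(alpha, index=ligands, name="alpha"), info
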