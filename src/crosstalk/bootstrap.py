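"""Bootstrap edge confidence and differential-edge statistics.

A single structure-learning run on a handful of samples is noisy, so edge
confidence comes from repetition: each iteration subsamples a fixed fraction
of the condition's cells without replacement, recomputes per-sample
composition fractions, re-binarizes them and relearns the network; the count
of each directed edge across iterations is its bootstrap score.  Differential
edges between case and control are scored as (case count - control count),
and an enhancement/permutation machinery quantifies whether adding an
independent dataset reinforces previously seen differential edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .bn import learn_network
from .discretize import discretize_fractions
from .exceptions import VocabularyMismatchError
from .io import FractionTable, compute_fractions

__all__ = [
    "EdgeCountTable",
    "DifferentialEdge",
    "bootstrap_edges",
    "differential_edges",
    "differential_frame",
    "enhancement_analysis",
    "permutation_test",
    "PermutationResult",
]


@dataclass
class EdgeCountTable:
    """Directed-edge bootstrap counts for one condition (each in [0, n_iter])."""

    condition: str
    n_iter: int
    counts: dict[tuple[str, str], int]
    cell_types: tuple[str, ...]

    def __post_init__(self) -> None:
        for (u, v), c in self.counts.items():
            if u == v:
                raise ValueError(f"self-pair {u!r} in edge counts")
            if not 0 <= c <= self.n_iter:
                raise ValueError(f"count {c} for ({u}, {v}) outside [0, {self.n_iter}]")

    def count(self, u: str, v: str) -> int:
        return self.counts.get((u, v), 0)

    def undirected(self) -> dict[frozenset, int]:
        """Diagnostic tally summing both directions of each pair."""
        out: dict[frozenset, int] = {}
        for (u, v), c in self.counts.items():
            key = frozenset((u, v))
            out[key] = out.get(key, 0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cell_type1": u, "cell_type2": v, "count": c}
            for (u, v), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["cell_type1", "cell_type2", "count"])


@dataclass(frozen=True)
class DifferentialEdge:
    """A directed pair scored by case bootstrap count minus control count."""

    pair: tuple[str, str]
    case_count: int
    control_count: int

    @property
    def score(self) -> int:
        return self.case_count - self.control_count


def _composition_codes(obs: pd.DataFrame, cell_types: list[str]):
    samples = sorted(obs["sample_id"].unique())
    sample_code = obs["sample_id"].map({s: i for i, s in enumerate(samples)}).to_numpy()
    type_code = (
        obs["cell_type"].map({t: i for i, t in enumerate(cell_types)}).fillna(-1)
    ).to_numpy(dtype=np.int64)
    return samples, sample_code.astype(np.int64), type_code


def bootstrap_edges(
    expr: ad.AnnData,
    condition: str | None,
    n_iter: int = 100,
    cell_frac: float = 0.8,
    min_cells: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    strategy: str = "gmm",
    max_condition_size: int = 3,
    cell_types: list[str] | None = None,
) -> EdgeCountTable:
    """Bootstrap directed-edge counts for one condition.

    The retained cell-type vocabulary (``min_cells`` filter) is fixed once on
    the full dataset pooled over conditions, so case and control tables share
    the same nodes; ``cell_types`` optionally restricts the network to a
    subset of the annotated populations (cells of other types still count in
    the fraction denominators).  Each iteration draws ``floor(cell_frac * n_cells)`` of
    the condition's cells without replacement; fractions keep the full-sample
    denominator semantics (all annotated cells of the subsample).  An
    iteration in which some sample loses all its cells is redrawn once, then
    raises.  ``condition=None`` pools all samples regardless of condition —
    the mode used when every sample comes from the same generative regime
    (e.g. the simulation study).
    """
    if not 0 < cell_frac <= 1:
        raise ValueError("cell_frac must be in (0, 1]")
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    full = compute_fractions(expr, min_cells=min_cells)
    if cell_types is None:
        cell_types = full.cell_types
    else:
        missing = sorted(set(cell_types) - set(full.cell_types))
        if missing:
            raise ValueError(
                f"requested cell types absent after the min_cells filter: {missing}"
            )
        cell_types = [t for t in full.cell_types if t in set(cell_types)]
    if not cell_types:
        raise ValueError("no cell type passes the min_cells filter")

    if condition is None:
        obs = expr.obs
    else:
        obs = expr.obs.loc[expr.obs["condition"].astype(str) == condition]
    if obs.empty:
        raise ValueError(f"no cells with condition {condition!r}")
    cond_label = condition if condition is not None else "all"
    samples, sample_code, type_code = _composition_codes(obs, cell_types)
    n_cells = len(obs)
    n_take = int(np.floor(cell_frac * n_cells))
    n_s, n_t = len(samples), len(cell_types)

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(2 * n_iter) % 2**31
    counts: dict[tuple[str, str], int] = {}
    for it in range(n_iter):
        rng = np.random.default_rng(int(iter_seeds[it]))
        for attempt in range(2):
            idx = rng.choice(n_cells, size=n_take, replace=False)
            denom = np.bincount(sample_code[idx], minlength=n_s)
            if (denom > 0).all():
                break
            if attempt == 1:
                empty = [samples[i] for i in np.flatnonzero(denom == 0)]
                raise RuntimeError(
                    f"bootstrap iteration {it}: samples lost all cells twice: {empty}"
                )
        sel_types = type_code[idx]
        keep = sel_types >= 0
        numer = np.bincount(
            sample_code[idx][keep] * n_t + sel_types[keep], minlength=n_s * n_t
        ).reshape(n_s, n_t)
        fractions = numer / denom[:, None]
        ft = FractionTable(
            values=pd.DataFrame(fractions, index=samples, columns=cell_types),
            conditions=pd.Series(cond_label, index=samples, name="condition"),
        )
        states = discretize_fractions(ft, strategy=strategy, seed=int(iter_seeds[n_iter + it]))
        dag = learn_network(
            states,
            alpha=alpha,
            seed=int(iter_seeds[n_iter + it]),
            max_condition_size=max_condition_size,
        )
        for edge in dag.edges:
            counts[edge] = counts.get(edge, 0) + 1

    return EdgeCountTable(
        condition=cond_label, n_iter=n_iter, counts=counts, cell_types=tuple(cell_types)
    )


def differential_edges(
    case: EdgeCountTable, control: EdgeCountTable, threshold: int = 20
) -> list[DifferentialEdge]:
    """Directed pairs whose larger count reaches the threshold, scored
    case - control and sorted by |score| descending then lexicographically."""
    if case.n_iter != control.n_iter:
        raise ValueError(
            f"mismatched n_iter: case {case.n_iter} vs control {control.n_iter}"
        )
    pairs = set(case.counts) | set(control.counts)
    out = [
        DifferentialEdge(
            pair=p, case_count=case.counts.get(p, 0), control_count=control.counts.get(p, 0)
        )
        for p in pairs
        if max(case.counts.get(p, 0), control.counts.get(p, 0)) >= threshold
    ]
    out.sort(key=lambda e: (-abs(e.score), e.pair))
    return out


def differential_frame(edges: list[DifferentialEdge]) -> pd.DataFrame:
    rows = [
        {
            "cell_type1": e.pair[0],
            "cell_type2": e.pair[1],
            "case_count": e.case_count,
            "control_count": e.control_count,
            "score": e.score,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["cell_type1", "cell_type2", "case_count", "control_count", "score"]
    )


def enhancement_analysis(
    original: tuple[EdgeCountTable, EdgeCountTable],
    combined: tuple[EdgeCountTable, EdgeCountTable],
    threshold: int = 20,
) -> pd.DataFrame:
    """Does adding data reinforce previously found differential edges?

    ``original`` and ``combined`` are (case, control) count-table pairs on a
    shared cell-type vocabulary.  For every differential pair of the original
    analysis (at ``threshold``), the signed score is recomputed on the
    combined tables; a pair is *enhanced* when the sign is preserved and the
    magnitude strictly grows (e.g. 40 -> 61, or -16 -> -19).
    """
    orig_diff = differential_edges(original[0], original[1], threshold=threshold)
    combined_types = set(combined[0].cell_types) | set(combined[1].cell_types)
    unmapped = sorted(
        {t for e in orig_diff for t in e.pair if t not in combined_types}
    )
    if unmapped:
        raise VocabularyMismatchError(
            f"cell types absent from the combined vocabulary: {unmapped}"
        )
    rows = []
    for e in orig_diff:
        comb_score = combined[0].counts.get(e.pair, 0) - combined[1].counts.get(e.pair, 0)
        enhanced = (
            np.sign(comb_score) == np.sign(e.score)
            and e.score != 0
            and abs(comb_score) > abs(e.score)
        )
        rows.append(
            {
                "cell_type1": e.pair[0],
                "cell_type2": e.pair[1],
                "original_score": e.score,
                "combined_score": comb_score,
                "enhanced": bool(enhanced),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_type1", "cell_type2", "original_score", "combined_score", "enhanced"],
    )


# ---------------------------------------------------------------------------
# permutation significance of enhancement


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null: np.ndarray = field(repr=False)


def _permute_within_samples(obs: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Per sample, apply a random bijection of cell-type labels: this permutes
    the sample's fraction vector across cell types while preserving its value
    multiset, which is exactly the null the enhancement test needs."""
    types = sorted(obs["cell_type"].unique())
    out = obs.copy()
    for s in sorted(obs["sample_id"].unique()):
        perm = dict(zip(types, rng.permutation(types)))
        sel = out["sample_id"] == s
        out.loc[sel, "cell_type"] = out.loc[sel, "cell_type"].map(perm)
    return out


def _permute_across_samples(obs: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Per cell type, permute which sample its cells belong to (block-wise)."""
    samples = sorted(obs["sample_id"].unique())
    out = obs.copy()
    for t in sorted(obs["cell_type"].unique()):
        perm = dict(zip(samples, rng.permutation(samples)))
        sel = out["cell_type"] == t
        out.loc[sel, "sample_id"] = out.loc[sel, "sample_id"].map(perm)
    return out


def _obs_only(obs: pd.DataFrame) -> ad.AnnData:
    adata = ad.AnnData(X=np.zeros((len(obs), 0)), obs=obs.copy())
    return adata


def permutation_test(
    expr_base: ad.AnnData,
    expr_new: ad.AnnData,
    n_perm: int = 100,
    threshold: int = 20,
    seed: int = 0,
    n_iter: int = 20,
    cell_frac: float = 0.8,
    min_cells: int = 100,
    axis: str = "within_sample",
    alpha: float = 0.05,
) -> PermutationResult:
    """Permutation significance of the enhanced-pair fraction.

    The observed statistic is the fraction of the base dataset's differential
    pairs that are *enhanced* when the new dataset is added.  Under the null,
    the new dataset's cell-type composition structure is destroyed by
    shuffling each sample's fraction vector across cell types (realized as a
    per-sample bijection of cell-type labels at the cell level) and the
    statistic is recomputed.  p uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_perm), so it is never exactly 0.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20: permutation p-value resolution exceeds 0.05")
    conds = sorted(expr_base.obs["condition"].astype(str).unique())
    if len(conds) != 2:
        raise ValueError("base dataset must have exactly 2 conditions")
    if sorted(expr_new.obs["condition"].astype(str).unique()) != conds:
        raise ValueError("new dataset must use the same two condition labels")
    if set(expr_base.obs["sample_id"]) & set(expr_new.obs["sample_id"]):
        raise ValueError("sample ids overlap between base and new datasets")
    permute = {
        "within_sample": _permute_within_samples,
        "across_samples": _permute_across_samples,
    }[axis]

    cols = ["sample_id", "condition", "cell_type"]
    base_obs = expr_base.obs[cols].astype(str)
    new_obs = expr_new.obs[cols].astype(str)

    ss = np.random.SeedSequence(seed)
    boot_seeds = ss.generate_state(2 * n_perm + 4) % 2**31

    def edge_tables(obs: pd.DataFrame, s0: int, s1: int):
        adata = _obs_only(obs)
        case = bootstrap_edges(
            adata, conds[1], n_iter=n_iter, cell_frac=cell_frac,
            min_cells=min_cells, seed=s0, alpha=alpha,
        )
        control = bootstrap_edges(
            adata, conds[0], n_iter=n_iter, cell_frac=cell_frac,
            min_cells=min_cells, seed=s1, alpha=alpha,
        )
        return case, control

    original = edge_tables(base_obs, int(boot_seeds[0]), int(boot_seeds[1]))

    def enhanced_fraction(new_part: pd.DataFrame, s0: int, s1: int) -> float:
        combined = edge_tables(pd.concat([base_obs, new_part]), s0, s1)
        table = enhancement_analysis(original, combined, threshold=threshold)
        return float(table["enhanced"].mean()) if len(table) else 0.0

    observed = enhanced_fraction(new_obs, int(boot_seeds[2]), int(boot_seeds[3]))
    rng = np.random.default_rng(ss.spawn(1)[0])
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = permute(new_obs, rng)
        null[i] = enhanced_fraction(
            shuffled, int(boot_seeds[4 + 2 * i]), int(boot_seeds[5 + 2 * i])
        )
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(p_value=p, observed=observed, null=null)
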