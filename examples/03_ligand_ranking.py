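"""Which ligands drive an inferred cell-type interaction?

Simulates a sender -> receiver pair where three ligands are truly active,
fits the shared-activity LASSO regression (target changes in the receiver
regressed on sender ligand changes folded through the regulatory-potential
prior), ranks the ligands, and runs both negative controls: the autocrine
model (receiver's own ligands) and the shuffled-prior control.
"""

from crosstalk import (
    autocrine_control,
    random_matrix_control,
    rank_ligands,
    run_ltr_pair,
)
from crosstalk.ltr import degenerate_fraction, _pair_vectors
from crosstalk.simulate import simulate_ligand_effect

expr, prior, true_alpha, info = simulate_ligand_effect(seed=5)
print("truly active ligands:", sorted(info["active_ligands"]))

fit, L = run_ltr_pair(
    expr, prior, info["sender"], info["receiver"], info["cond_a"], info["cond_b"], seed=5
)
print(f"\nparacrine fit: mean held-out Pearson = {fit.mean_pearson:.3f}")

ranking = rank_ligands(fit, L)
print("top 5 ranked ligands (score = mean over folds of lfc x activity):")
print(ranking.head(5).to_string(index=False))

auto, _ = autocrine_control(
    expr, prior, info["receiver"], info["cond_a"], info["cond_b"], seed=5
)
auto_r = float("nan") if auto.degenerate else auto.mean_pearson
print(f"\nautocrine control: mean Pearson = {auto_r:.3f} (degenerate={auto.degenerate})")

_, T = _pair_vectors(expr, prior, info["sender"], info["receiver"],
                     info["cond_a"], info["cond_b"])
shuffled = random_matrix_control(prior, T, L, n_shuffles=10, seed=5)
print(
    f"shuffled-prior control: {degenerate_fraction(shuffled):.0%} of fits are "
    "bias-only (no ligand explains anything once target assignments are broken)"
)
print(
    "\nA real interaction shows: high paracrine Pearson, the active ligands at\n"
    "the top of the ranking, a weaker autocrine fit, and degenerate shuffles."
)
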