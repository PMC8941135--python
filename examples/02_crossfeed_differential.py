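"""Start-vs-end differential abundance for one feeding direction.

Generates a seeded synthetic cross-feeding experiment (host spent medium
fed to the symbiont), tests every donor metabolite with Kruskal-Wallis +
BH-FDR, and converts significant negative LFCs to percent depletion.
"""

from exoflux import (
    default_truth,
    depletion_percent_from_lfc,
    differential_abundance,
    generate_crossfeed_experiment,
    pairs_from_tables,
)
from exoflux.model import Direction

spec = default_truth(seed=1, noise_cv=0.3)
start, end, blank, truth = generate_crossfeed_experiment(spec)
class_map = dict(zip(truth["metabolite"], truth["chem_class"]))

direction = Direction.A_fed_to_B  # host spent medium -> symbiont
donor_metabolites = truth.loc[truth["donor"] == "A_host", "metabolite"]
pairs = pairs_from_tables(start, end, direction, class_map)
pairs = pairs[pairs["metabolite"].isin(set(donor_metabolites))].reset_index(drop=True)

res = differential_abundance(pairs, direction).sort_values("lfc")
print(res[["metabolite", "chem_class", "lfc", "p_value", "q_value", "call"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3g}"))

top = res.iloc[0]
print(f"\nMost depleted: {top['metabolite']} (LFC {top['lfc']:.2f}, q={top['q_value']:.3f})"
      f" -> {depletion_percent_from_lfc(top['lfc']):.0f}% of the starting pool consumed.")
print("Planted truth:",
      truth.set_index("metabolite").loc[top["metabolite"], "depletion_fraction"])
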