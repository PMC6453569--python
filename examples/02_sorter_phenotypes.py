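"""From raw per-animal sorter records to mapping-ready traits.

Simulates two plates' worth of animals for 24 strains in control and toxin
conditions, summarizes wells, removes assay-block shifts, prunes outliers
and regresses the toxin traits on control traits.  The printed residual
traits are the toxin-specific responses that feed PCA and mapping.
"""

from toxqtl import sorterproc, synthdata
from toxqtl.core import TraitTable

cfg = synthdata.SimulationConfig(seed=5, wells_per_group=4,
                                 strain_effect_sd=0.15, sorter_block_sd=0.1)
strains = [f"S{i:02d}" for i in range(24)]
records = synthdata.simulate_sorter_plate(
    cfg, strains, [("control", 0.0), ("arsenic", 1000.0)])
print(f"{len(records)} animal records across "
      f"{records.groupby(['plate', 'row', 'col']).ngroups} wells")

summaries = sorterproc.summarize_wells(records, n_sorted=cfg.n_sorted)
table = sorterproc.well_summary_traits(summaries)
table = sorterproc.regress_assay(table)
table = sorterproc.prune_outliers_fence(table)
print("pruned per trait:", table.data.attrs["pruned_counts"])

toxin = TraitTable(table.data[table.data.condition == "arsenic"], stage=table.stage)
control = TraitTable(table.data[table.data.condition == "control"], stage=table.stage)
residuals = sorterproc.subtract_control(toxin, control)
print(residuals.data[["strain", "norm.n", "mean.TOF"]].head(6).to_string(index=False))
# each number is a strain's toxin response after removing what its control
# growth already predicted; positive norm.n = more progeny under toxin than
# expected from its baseline
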