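"""Run miniature binding and steered campaigns and print their readouts.

A scaled-down version of the full study: a few unforced binding replicas
(binding-frequency maps, hydropathy-class breakdown) and a small force grid
(censored dissociation times per force).  Larger replica counts sharpen all
of these numbers; this script is sized to finish in about a minute.
"""

from godmd import CampaignConfig, run_binding_campaign, run_steered_campaign
from godmd.campaign import DimerSpec

config = CampaignConfig(
    ligands=("none", "oligomer"),
    binding_replicas=3,
    binding_duration_ns=0.1,
    steered_replicas=3,
    steered_duration_ns=0.1,
    force_grid_pn=(0.0, 20.0),
    master_seed=7,
)

binding = run_binding_campaign(config)
print("binding campaign summary:")
print(binding.summary().to_string(index=False))
olig = binding.conditions["oligomer"]
top = olig.dimer_profile.to_frame().nlargest(3, "frequency")
print("\ndimer residues most contacted by the oligomer (fraction of frames):")
print(top.to_string(index=False))
print("\ncontact breakdown by hydropathy class pair:")
print(olig.class_breakdown.to_string(index=False))

steered = run_steered_campaign(config)
print("\nsteered campaign, per-force summaries:")
for name, summ in steered.summaries.items():
    print(f"  condition {name}:")
    print(summ.drop(columns=["values"]).to_string(index=False))
# association_fraction is the share of replicas whose interface never lost
# all its contacts; censored replicas enter the mean at the full duration.
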