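"""Rank drought regulators by the composite reporter score.

Fits CPTs from a synthetic binary dataset on the drought network, then
sweeps every non-reporter node — clamping it to 1 (activation) and 0
(inhibition) as likelihood-weighting evidence — and scores each sweep row
by Pr(RD29A=0|E)·Pr(RD22=0|E)·Pr(RD20=0|E)·Pr(ERD1=1|E). Finishes with the
joint intervention activating MYC2 while inhibiting ATAF1.

M is kept modest here so the script runs in seconds; the study-scale
default is M = 600,000 per evidence assignment.
"""

from droughtbn import (
    drought_network,
    fit_cpts,
    forward_sample_dataset,
    multi_node_score,
    random_cpts,
    single_node_sweep,
)

net = drought_network()
truth = random_cpts(net, seed=30, mode="strong")
data = forward_sample_dataset(net, truth, n=104, seed=31)
cpts = fit_cpts(net, data.data)

M = 20_000
for state, label in [(1, "activation"), (0, "inhibition")]:
    table = single_node_sweep(net, cpts, state, M=M, seed=0)
    print(f"top 3 {label} interventions:")
    cols = ["node", "p_RD29A_0", "p_RD22_0", "p_RD20_0", "p_ERD1_1", "score"]
    print(table.head(3)[cols].to_string(index=False, float_format="%.4f"))
    print()

joint = multi_node_score(net, cpts, {"MYC2": 1, "ATAF1": 0}, M=M, seed=0)
print(f"joint MYC2=1, ATAF1=0 score: {joint.score:.4f}")
print("\nA higher score marks an intervention that better pushes ERD1 toward")
print("activation and RD29A/RD22/RD20 toward inhibition, the target pattern")
print("for drought resistance without the yield costs of activating all four.")
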