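"""Between-region statistics at published effect sizes.

Simulates per-animal relative CTTH changes for an activated region
(mean -5.9%, std 1.4) and a control region (Table-scale -0.9%, same
std), 12 animals each, and runs the two-tailed pooled-variance t-test.
"""

from capiflow.groupstats import compare_regions, simulate_change_study

ctrl_mean = 100.0 * (0.227 - 0.229) / 0.229  # control rest->stim change
changes = simulate_change_study(mean_hls1=-5.9, mean_ctrl=ctrl_mean,
                                std=1.4, n_animals=12, seed=0)
comp = compare_regions(changes, "ctth")

print(f"dCTTH activated: {comp.mean['HLS1']:+.2f} +- {comp.std['HLS1']:.2f} %")
print(f"dCTTH control:   {comp.mean['CTRL']:+.2f} +- {comp.std['CTRL']:.2f} %")
print(f"t = {comp.t_statistic:.2f}, p = {comp.p_value:.2e} ({comp.stars})")
# A ~5-point CTTH reduction difference at 1.4-point spread and n = 12
# per region is overwhelmingly significant - capillary flow
# homogenization is localized to the activated cortex.
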