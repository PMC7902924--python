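# Medium damage-feedback condition (generalization condition, N = 30).
condition_id: medium
initial_income: 292.0
initial_property_wealth: 20000000.0
weight_We: 0.7
mitigation_return_M: 0.9
p_env: 0.3
p_property_damage: 0.165
p_injury: 0.50
p_fatality: 0.05
property_loss_fraction: 0.5
injury_income_fraction: 0.10
fatality_income_fraction: 0.20
n_rounds: 30
n_participants: 30
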