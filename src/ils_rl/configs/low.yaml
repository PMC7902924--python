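# Low damage-feedback condition (calibration condition, N = 20).
condition_id: low
initial_income: 292.0            # EC per round
initial_property_wealth: 20000000.0
weight_We: 0.7
mitigation_return_M: 0.9         # free parameter; never printed
p_env: 0.3                       # environmental probability; subsumes rain + terrain
p_property_damage: 0.03
p_injury: 0.10
p_fatality: 0.01
property_loss_fraction: 0.5
injury_income_fraction: 0.10
fatality_income_fraction: 0.20
n_rounds: 30
n_participants: 20
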