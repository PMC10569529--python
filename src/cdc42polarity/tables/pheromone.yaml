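# Pheromone-induced receptor-Far1 pathway (3D sphere geometry only).
# Replaces the constitutive receptor activation of receptor_far1.yaml:
# membrane receptors (Ri_m) must bind a pheromone molecule to become
# active (Ra_m). lambda_11 was chosen so the receptor's equilibrium
# dissociation constant K_D = k_13 / (lambda_11 * V_3D) falls in 6-7 nM.
circuit: pheromone
species:
  Ri_m:      {compartment: membrane,      D: 0.0001, unit: "um^2 s^-1"}
  Pheromone: {compartment: extracellular, D: 150.0,  unit: "um^2 s^-1"}
reactions:
  - {symbol: lambda_11, kind: second_order, reactants: [Ri_m, Pheromone],
     products: [Ra_m], anchor: Ri_m,
     rate_3d: 1.8, unit_3d: "s^-1"}
  - {symbol: lambda_12, kind: second_order, reactants: [Cdc42T, Ri_c],
     products: [Cdc42T, Ri_m],
     rate_3d: 0.625, unit_3d: "s^-1"}
  - {symbol: k_13, kind: first_order, reactants: [Ra_m],
     products: [Ri_m, Pheromone],
     rate_3d: 0.002, unit_3d: "s^-1"}
  - {symbol: k_14, kind: first_order, reactants: [Ra_m],
     products: [Ri_c, Pheromone],
     rate_3d: 0.002, unit_3d: "s^-1"}
  - {symbol: k_15, kind: first_order, reactants: [Ri_m], products: [Ri_c],
     rate_3d: 0.0004, unit_3d: "s^-1"}
constants:
  D_pheromone: {value: 150.0, unit: "um^2 s^-1"}
  R_absorb:    {value: 7.0, unit: "um"}
conservation_groups:
  Receptor: [Ra_m, Ri_c, RaGEF, Ri_m]
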