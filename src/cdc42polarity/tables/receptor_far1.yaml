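# Receptor-Far1 pathway with uniformly (constitutively) active receptors.
# Active receptors (Ra_m) recruit cytosolic Far1-GEF; the resulting RaGEF
# complex activates membrane Cdc42-GDP. Active Cdc42 recruits cytosolic
# receptors (actin-cable delivery abstracted as a bimolecular reaction);
# membrane receptors are internalized by endocytosis at rate k_10, which
# covers both the free receptor and the RaGEF complex.
circuit: receptor_far1
species:
  Far1GEF_c: {compartment: cytosol,  D: 15.0,   unit: "um^2 s^-1"}
  RaGEF:     {compartment: membrane, D: 0.0001, unit: "um^2 s^-1"}
  Ra_m:      {compartment: membrane, D: 0.0001, unit: "um^2 s^-1"}
  Ri_c:      {compartment: cytosol,  D: 15.0,   unit: "um^2 s^-1"}
reactions:
  - {symbol: lambda_8a, kind: second_order, reactants: [Far1GEF_c, Ra_m],
     products: [RaGEF], anchor: Ra_m,
     rate_2d: 300.0, unit_2d: "s^-1", rate_3d: 7500.0, unit_3d: "s^-1"}
  - {symbol: k_8b, kind: first_order, reactants: [RaGEF],
     products: [Far1GEF_c, Ra_m],
     rate_2d: 0.11, unit_2d: "s^-1", rate_3d: 0.11, unit_3d: "s^-1"}
  - {symbol: lambda_2c, kind: second_order, reactants: [RaGEF, Cdc42D_m],
     products: [RaGEF, Cdc42T],
     rate_2d: 180.0, unit_2d: "s^-1", rate_3d: 180.0, unit_3d: "s^-1"}
  - {symbol: lambda_9, kind: second_order, reactants: [Cdc42T, Ri_c],
     products: [Cdc42T, Ra_m],
     rate_2d: 0.025, unit_2d: "s^-1", rate_3d: 0.625, unit_3d: "s^-1"}
  - {symbol: k_10, kind: first_order, reactants: [Ra_m], products: [Ri_c],
     rate_2d: 0.002, unit_2d: "s^-1", rate_3d: 0.002, unit_3d: "s^-1"}
  - {symbol: k_10, kind: first_order, reactants: [RaGEF],
     products: [Far1GEF_c, Ri_c],
     rate_2d: 0.002, unit_2d: "s^-1", rate_3d: 0.002, unit_3d: "s^-1"}
constants:
  D_receptor: {value: 0.0001, unit: "um^2 s^-1"}
default_abundances:
  Far1GEF: 30
  Receptor: 2500
conservation_groups:
  Far1GEF:  [Far1GEF_c, RaGEF]
  Receptor: [Ra_m, Ri_c, RaGEF]
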