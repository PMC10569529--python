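# Core Cdc42/Bem1-GEF polarity circuit: species, reactions and constants.
# Rates are stored verbatim for both geometries; the 2D<->3D conversion
# formulas are used to validate (not populate) these entries, since a few
# 3D rates were tuned rather than derived (e.g. lambda_4a).
circuit: core
species:
  Cdc42D_c:  {compartment: cytosol,  D: 15.0,    unit: "um^2 s^-1"}
  Cdc42D_m:  {compartment: membrane, D: 0.0025,  unit: "um^2 s^-1"}
  Cdc42T:    {compartment: membrane, D: 0.0025,  unit: "um^2 s^-1"}
  Bem1GEF_c: {compartment: cytosol,  D: 15.0,    unit: "um^2 s^-1"}
  Bem1GEF_m: {compartment: membrane, D: 0.0025,  unit: "um^2 s^-1"}
  Cdc42T_Bem1GEF: {compartment: membrane, D: 0.0025, unit: "um^2 s^-1"}
reactions:
  - {symbol: k_1a, kind: first_order, reactants: [Bem1GEF_c], products: [Bem1GEF_m],
     rate_2d: 10.0, unit_2d: "s^-1", rate_3d: 8.333, unit_3d: "um s^-1",
     kind_3d: surface_association}
  - {symbol: k_1b, kind: first_order, reactants: [Bem1GEF_m], products: [Bem1GEF_c],
     rate_2d: 40.0, unit_2d: "s^-1", rate_3d: 40.0, unit_3d: "s^-1"}
  - {symbol: lambda_2a, kind: second_order, reactants: [Bem1GEF_m, Cdc42D_m],
     products: [Bem1GEF_m, Cdc42T],
     rate_2d: 5.3, unit_2d: "s^-1", rate_3d: 5.3, unit_3d: "s^-1"}
  - {symbol: k_2b, kind: first_order, reactants: [Cdc42T], products: [Cdc42D_m],
     rate_2d: 0.35, unit_2d: "s^-1", rate_3d: 0.35, unit_3d: "s^-1"}
  - {symbol: lambda_3, kind: second_order, reactants: [Cdc42T_Bem1GEF, Cdc42D_m],
     products: [Cdc42T_Bem1GEF, Cdc42T],
     rate_2d: 180.0, unit_2d: "s^-1", rate_3d: 180.0, unit_3d: "s^-1"}
  - {symbol: lambda_4a, kind: second_order, reactants: [Cdc42T, Bem1GEF_m],
     products: [Cdc42T_Bem1GEF], anchor: Cdc42T,
     rate_2d: 9.6, unit_2d: "s^-1", rate_3d: 40.0, unit_3d: "s^-1", tuned_3d: true}
  - {symbol: k_4b, kind: first_order, reactants: [Cdc42T_Bem1GEF],
     products: [Cdc42T, Bem1GEF_m],
     rate_2d: 40.0, unit_2d: "s^-1", rate_3d: 40.0, unit_3d: "s^-1"}
  - {symbol: k_5a, kind: first_order, reactants: [Cdc42D_c], products: [Cdc42D_m],
     rate_2d: 36.0, unit_2d: "s^-1", rate_3d: 30.0, unit_3d: "um s^-1",
     kind_3d: surface_association}
  - {symbol: k_5b, kind: first_order, reactants: [Cdc42D_m], products: [Cdc42D_c],
     rate_2d: 13.0, unit_2d: "s^-1", rate_3d: 13.0, unit_3d: "s^-1"}
  - {symbol: lambda_7, kind: second_order, reactants: [Cdc42T, Bem1GEF_c],
     products: [Cdc42T_Bem1GEF], anchor: Cdc42T,
     rate_2d: 256.0, unit_2d: "s^-1", rate_3d: 6400.0, unit_3d: "s^-1"}
constants:
  A_m:  {value: 78.540, unit: "um^2"}
  L:    {value: 8.8623, unit: "um"}
  R:    {value: 2.5, unit: "um"}
  rho:  {value: 0.05, unit: "um"}
  dt:   {value: 1.0e-4, unit: "s"}
default_abundances:
  Cdc42: 3000
  Bem1GEF: 170
conservation_groups:
  Cdc42:   [Cdc42D_c, Cdc42D_m, Cdc42T, Cdc42T_Bem1GEF]
  Bem1GEF: [Bem1GEF_c, Bem1GEF_m, Cdc42T_Bem1GEF]
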