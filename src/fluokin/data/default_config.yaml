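# Default model configuration for the pediatric fluoride PBPK model.
#
# Volumes are fractions of body weight (L per kg, assuming ~1 kg/L tissue
# density); blood flows are fractions of cardiac output and must sum to 1
# over the perfused compartments.  These are sex-averaged reference-child
# values; every entry here is a deliberate knob, not a constant of nature.
version: 1
reference_clearance:
  # Adult fluoride plasma clearance used as the allometric anchor; scaled to
  # the child with (BW / body_weight_kg)^0.75.
  plasma_l_min: 0.09
  body_weight_kg: 70.0
cardiac_output:
  # CO = coefficient * BW^exponent  [L/min]
  coefficient_l_min: 0.235
  exponent: 0.81
blood:
  volume_fraction_bw: 0.077   # ~77 mL/kg whole blood
compartments:
  liver:
    volume_fraction_bw: 0.032
    flow_fraction_co: 0.25
    partition_coefficient: 0.75
  kidney:
    volume_fraction_bw: 0.006
    flow_fraction_co: 0.18
    partition_coefficient: 0.75
  bone:
    # Perfused bone tissue (water space), distinct from the mineral pool.
    volume_fraction_bw: 0.07
    flow_fraction_co: 0.05
    partition_coefficient: 1.0
  rest_of_body:
    volume_fraction_bw: 0.60
    flow_fraction_co: 0.52
    partition_coefficient: 0.5
bone_uptake:
  # "store": bone mineral is a reversible, slowly equilibrating pool of
  #          capacity V_bone * mineral_partition exchanging with arterial
  #          blood at CL_bone.  At steady state net bone flux is zero and
  #          urinary recovery of the dose is complete; the pool's filling
  #          sets the ~150-day approach to urinary steady state.
  # "sink":  irreversible removal at CL_bone * C_art; steady-state urinary
  #          fraction is then CL_renal / (CL_renal + CL_bone).
  mode: store
  mineral_partition: 150.0
clearance_driving:
  # Concentration driving renal clearance and bone uptake: "arterial"
  # (well-mixed blood) or "venous" (flow-weighted tissue exit).
  concentration: arterial
daily_urine_volume_l:
  # Calibration-sensitive: converts excreted amount (mg/day) to the spot
  # concentration scale (mg/L).  Linearly interpolated between listed ages.
  4: 0.5
  8: 0.7
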