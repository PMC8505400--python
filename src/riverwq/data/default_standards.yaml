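# Default standards table: BIS (2012) / WHO (2011) permissible limits,
# literature-assigned MWQI weights, and Hakanson preindustrial reference
# values with toxic-response coefficients.
#
# Units: ions/BOD/DO in mg/l, heavy metals/TP/Chl-a in ug/l, EC in uS/cm,
# turbidity in NTU, Secchi depth in m.
#
# pH is rated against the upper BIS band (8.5) with ideal 7.0; set
# permissible_limit to 6.5 to rate against the lower band instead.
parameters:
  ph:
    name: pH
    unit: pH units
    permissible_limit: 8.5
    assigned_weight: 1.0
    ideal_value: 7.0
    standard_source: BIS (2012)
  tds:
    name: Total dissolved solids
    unit: mg/l
    permissible_limit: 500.0
    assigned_weight: 1.79
    standard_source: WHO (2011)
  turbidity:
    name: Turbidity
    unit: NTU
    permissible_limit: 1.0
    assigned_weight: 1.09
    standard_source: BIS (2012)
  ec:
    name: Electrical conductivity
    unit: uS/cm
    permissible_limit: 300.0
    assigned_weight: 1.78
    standard_source: BIS (2012)
  mg:
    name: Magnesium
    unit: mg/l
    permissible_limit: 30.0
    assigned_weight: 0.72
    standard_source: BIS (2012)
  ca:
    name: Calcium
    unit: mg/l
    permissible_limit: 75.0
    assigned_weight: 0.8
    standard_source: WHO (2011)
  cl:
    name: Chloride
    unit: mg/l
    permissible_limit: 250.0
    assigned_weight: 1.28
    standard_source: WHO (2011)
  so4:
    name: Sulphate
    unit: mg/l
    permissible_limit: 200.0
    assigned_weight: 1.6
    standard_source: BIS (2012)
  no3:
    name: Nitrate
    unit: mg/l
    permissible_limit: 45.0
    assigned_weight: 2.32
    standard_source: WHO (2011)
  bod:
    name: Biological oxygen demand
    unit: mg/l
    permissible_limit: 5.0
    assigned_weight: 1.72
    standard_source: BIS (2012)
  do:
    name: Dissolved oxygen
    unit: mg/l
    permissible_limit: 6.0
    assigned_weight: 2.85
    ideal_value: 14.6
    standard_source: BIS (2012)
  zn:
    name: Zinc
    unit: ug/l
    permissible_limit: 15000.0
    reference_value: 175.0
    toxic_response: 1.0
    standard_source: BIS (2012)
  cd:
    name: Cadmium
    unit: ug/l
    permissible_limit: 10.0
    reference_value: 1.0
    toxic_response: 30.0
    standard_source: BIS (2012)
  pb:
    name: Lead
    unit: ug/l
    permissible_limit: 50.0
    reference_value: 70.0
    toxic_response: 5.0
    standard_source: BIS (2012)
  ni:
    name: Nickel
    unit: ug/l
    permissible_limit: 20.0
    standard_source: BIS (2012)
  cr:
    name: Chromium
    unit: ug/l
    permissible_limit: 50.0
    reference_value: 90.0
    toxic_response: 2.0
    standard_source: WHO (2011)
  fe:
    name: Iron
    unit: ug/l
    permissible_limit: 300.0
    standard_source: WHO (2011)
  sd:
    name: Secchi disk depth
    unit: m
  chla:
    name: Chlorophyll-a
    unit: ug/l
  tp:
    name: Total phosphorus
    unit: ug/l
sets:
  mwqi: [ph, tds, turbidity, ec, mg, ca, cl, so4, no3, bod, do]
  hpi: [zn, cd, pb, ni, cr, fe]
  ri: [cd, pb, cr, zn]
  tsi: [sd, tp, chla]
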