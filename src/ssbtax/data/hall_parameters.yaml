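# Constants of the adult dynamic energy-balance model of Hall et al.
# ("Quantification of the effect of energy imbalance on bodyweight",
# Lancet 2011;378:826-37, web appendix), as also implemented in the
# open-source `bw` R package (INSP-RH).  One entry per model constant;
# units in comments.  Nothing here is fitted to data in this package.

rho_F: 9440.0        # kcal/kg  energy density of fat-mass change
rho_L: 1807.0        # kcal/kg  energy density of lean-mass change
gamma_F: 3.2         # kcal/kg/day  RMR regression slope on fat mass
gamma_L: 21.99       # kcal/kg/day  RMR regression slope on lean mass
eta_F: 180.0         # kcal/kg  biochemical cost of fat deposition
eta_L: 230.0         # kcal/kg  biochemical cost of lean deposition
beta_TEF: 0.10       # -        thermic effect of food, fraction of delta-EI
beta_AT: 0.14        # -        adaptive thermogenesis, fraction of delta-EI
tau_AT: 14.0         # day      adaptive-thermogenesis time constant
forbes_mass_C: 10.4  # kg       Forbes relation dL/dF = C/F (mass form);
                     #          the energy-partition constant is C * rho_L/rho_F
glycogen_init: 0.5   # kg       baseline glycogen store
rho_G: 4180.0        # kcal/kg  energy density of glycogen
hydration_G: 2.7     # kg/kg    water bound per kg glycogen
na_concentration: 3220.0  # mg/L  extracellular sodium concentration
xi_Na: 3000.0        # mg/L/day renal sodium excretion per L ECF deviation
xi_CI: 4000.0        # mg/day   sodium response to carbohydrate restriction
carb_fraction: 0.5   # -        carbohydrate share of energy intake
pal_default: 1.5     # -        sedentary physical activity level

# Mifflin-St Jeor resting metabolic rate (kcal/day; W kg, H cm, A years):
#   male:   9.99 W + 6.25 H - 4.92 A + 5
#   female: 9.99 W + 6.25 H - 4.92 A - 161
rmr:
  weight_coef: 9.99
  height_coef: 6.25   # per cm
  age_coef: -4.92
  intercept_male: 5.0
  intercept_female: -161.0

# Initial body-fat percent (Jackson et al. regression used by Hall 2011):
#   male:   0.14 A + 37.31 ln(BMI) - 103.94
#   female: 0.14 A + 39.96 ln(BMI) - 102.01
fat_init:
  age_coef: 0.14
  log_bmi_coef_male: 37.31
  log_bmi_coef_female: 39.96
  intercept_male: -103.94
  intercept_female: -102.01
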