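# Al-Ahsa diabetes-related amputation projection, 2022-2045.
# Base-year diagnosed diabetes cases (aged >=20) with national growth-factor
# anchors, literature transition rates, and the shipped scenarios.

base_year: 2022
base_count: 54805
final_year: 2045

# ratio of end-year to start-year case count, as a percentage
anchors:
  - {start_year: 2022, end_year: 2030, growth_percent: 131.7}
  - {start_year: 2030, end_year: 2045, growth_percent: 133.9}

rates:
  incidence_major: 94.82        # per 100,000 diabetics per year
  incidence_minor: 139.97       # per 100,000 diabetics per year
  mortality_amputee: 86.8       # per 1,000 person-years
  mortality_nonamputee: 23.81   # per 1,000 person-years

uncertainty_fraction: 0.20
scenario: constant
seed: 0
output_dir: out

scenarios:
  # incidence rates held at their base values for the whole horizon
  constant: {}
  # the decline schedule consistent with the published results tables:
  # first 20% reduction already applied at the base year, then per-3-year
  # factors 0.8 (major) / 0.9 (minor), linearly interpolated between periods
  mixed-decline:
    major: {initial_multiplier: 0.8, period_years: 3, per_period_factor: 0.8, mode: interpolated}
    minor: {initial_multiplier: 0.8, period_years: 3, per_period_factor: 0.9, mode: interpolated}
  # same schedule with geometric (annualized) compounding between periods
  mixed-decline-annualized:
    major: {initial_multiplier: 0.8, period_years: 3, per_period_factor: 0.8, mode: annualized}
    minor: {initial_multiplier: 0.8, period_years: 3, per_period_factor: 0.9, mode: annualized}
  # the narrative reading: a 20% per-3-year decline for BOTH incidence rates
  uniform-decline:
    major: {initial_multiplier: 0.8, period_years: 3, per_period_factor: 0.8, mode: interpolated}
    minor: {initial_multiplier: 0.8, period_years: 3, per_period_factor: 0.8, mode: interpolated}
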