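# Catalogue of the 12 modelled programs, services and capacity levers.
#
# Eight prevention/service programs act on model parameters; four capacity
# levers act on service-capacity growth.  Effect magnitudes are documented
# package defaults anchored to the intervention-effect literature (see the
# per-entry notes); region-specific calibrated magnitudes are not publicly
# available, and every test that depends on magnitudes uses synthetic ground
# truth rather than these values.
#
# target transforms: mul = multiply parameter, add = add to parameter,
# set = overwrite parameter.  "scaled_by_support: true" marks an effect whose
# distance from identity is scaled by the community-support factor.

- id: post_attempt_aftercare
  kind: program
  label: Post-attempt assertive aftercare
  note: >
    Assertive outreach and enhanced contact after a suicide attempt,
    delivered through existing community mental healthcare (CMHC) services;
    re-attempt hazard ratio ~0.7 consistent with aftercare trial
    meta-analyses.  Consumes CMHC contacts for every person in the
    post-attempt state.
  targets:
    - {path: attempt_hazard_post_attempt, transform: mul, effect: 0.70}
    - {path: post_attempt_engage_rate, transform: mul, effect: 1.50}
    - {path: aftercare_cmhc_cost, transform: set, effect: 0.80}
  capacity_cost: {service_id: cmhc, per_enrolled_per_week: 0.80}

- id: gp_training
  kind: program
  label: GP training in suicide-risk referral
  note: >
    Brief GP training increasing referral of suicidal patients to
    specialised psychiatric services and modestly reducing in-care risk.
  targets:
    - {path: refer_specialist, transform: mul, effect: 1.15}
    - {path: attempt_hazard_in_care, transform: mul, effect: 0.97}

- id: community_education
  kind: program
  label: Community-based education programs
  note: >
    Gatekeeper-style education improving recognition of risk and
    help-seeking; effectiveness scales with community support (greater
    identification opportunity when connectedness programs are active).
  targets:
    - {path: help_seeking_multiplier, transform: mul, effect: 1.06,
       scaled_by_support: true}

- id: family_psychoeducation
  kind: program
  label: Family education and support
  note: >
    Education/support of families and carers of patients engaged with
    services, improving treatment success and lowering in-care attempt risk.
  targets:
    - {path: treatment_success.gp, transform: mul, effect: 1.06}
    - {path: treatment_success.specialist, transform: mul, effect: 1.06}
    - {path: treatment_success.cmhc, transform: mul, effect: 1.06}
    - {path: treatment_success.online, transform: mul, effect: 1.06}
    - {path: attempt_hazard_in_care, transform: mul, effect: 0.85}

- id: safety_planning
  kind: program
  label: Safety planning
  note: >
    Personal safety plans (with follow-up calls) for suicidal patients
    presenting to an ED, reducing re-attempt risk among recent presenters.
  targets:
    - {path: attempt_hazard_post_attempt, transform: mul, effect: 0.85}
    - {path: attempt_hazard_untreated, transform: mul, effect: 0.97}

- id: safe_space
  kind: program
  label: Safe space alternative to EDs
  note: >
    Safe-haven-cafe-style alternative contact point for people in acute
    distress; diverts a fraction of would-be ED presentations.
  targets:
    - {path: safe_space_diversion, transform: add, effect: 0.07}

- id: social_connectedness
  kind: program
  label: Social connectedness programs
  note: >
    Community support programs reducing isolation: lower distress onset,
    faster untreated recovery, and full community-support coverage.
  targets:
    - {path: distress_onset_rate, transform: mul, effect: 0.97}
    - {path: recovery_untreated, transform: mul, effect: 1.04}
    - {path: connectedness_coverage, transform: set, effect: 1.0, vary: false}

- id: acute_care_services
  kind: program
  label: Community-based acute care services
  note: >
    Responsive community crisis teams (home- or centre-based); a fraction of
    crises is handled in CMHC-style care instead of the ED.
  targets:
    - {path: acute_care_diversion, transform: add, effect: 0.10}

- id: cap_gp
  kind: capacity_lever
  label: GP mental-health services capacity growth
  note: >
    Multiplies the annual growth rate of GP mental-health consultations
    completable per week (default multiplier 1 = business as usual).
  lever: {service_id: gp, growth_multiplier: 1.6}

- id: cap_specialist
  kind: capacity_lever
  label: Psychiatrist and allied services capacity growth
  note: >
    Multiplies the annual growth rate of psychiatrist/allied sessions per
    week (default multiplier 1 = business as usual).
  lever: {service_id: specialist, growth_multiplier: 1.6}

- id: cap_inpatient
  kind: capacity_lever
  label: Psychiatric hospital capacity growth
  note: >
    Multiplies the annual growth rate of the maximum psychiatric admissions
    per week (default multiplier 1 = business as usual).
  lever: {service_id: inpatient, growth_multiplier: 1.6}

- id: cap_cmhc
  kind: capacity_lever
  label: Community mental healthcare capacity growth
  note: >
    Annual additive increase in CMHC contacts per 10,000 population per week
    (default 0 = no capacity growth).
  lever: {service_id: cmhc, cmhc_increment_per_10k: 0.25}
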