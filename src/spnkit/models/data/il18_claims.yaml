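# Recorded headline claims about the IL-18 atherosclerosis SPN, consumed by
# spnkit.models.validate_recorded_claims.  Each entry is a quantity the
# analysis pipeline recomputes from the bundled model.
n_places: 56
n_transitions: 70
weight2_arcs: 4
is_pure: true
is_ordinary: false
is_connected: true
is_strongly_connected: false
is_structurally_conflict_free: false
has_input_places: false
has_output_places: false
has_input_transitions: true
has_output_transitions: true

n_t_invariants: 223
covered_by_t_invariants: true
n_nontrivial_mct_sets: 11
nontrivial_mct_sets:
  - [t19, t33, t35, t36, t37, t38, t39, t40, t41, t42, t43, t56, t57, t58, t59]
  - [t52, t53, t54, t55, t67, t68, t69]
  - [t12, t13, t14, t64]
  - [t29, t30, t31, t32]
  - [t9, t10, t11]
  - [t24, t25, t26]
  - [t44, t45, t46]
  - [t47, t48, t50]
  - [t0, t3]
  - [t4, t7]
  - [t49, t51]

invariants_containing:
  t11: 32
  t28: 53
invariants_containing_both_t11_t28: 4

knockouts:
  - knock: [t16]
    remaining: 70
  - knock: [t15]
    remaining: 194
    covered: true
  - knock: [t60]
    remaining: 127
    covered: true
    t11_remaining: 32
    t28_remaining: 17
  - knock: [t61]
    remaining: 151
    covered: true
    t11_remaining: 20
    t28_remaining: 41
  - knock: [t62]
    remaining: 151
    t11_remaining: 20
    t28_remaining: 41
  - knock: [t64]
    remaining: 71
    t11_remaining: 0
    t28_remaining: 17
  - knock: [t63]
    remaining: 22
    t11_remaining: 3
    t28_remaining: 13
  - knock: [t60, t64]
    remaining: 39
    t11_remaining: 0
    t28_remaining: 5
  - knock: [t61, t64]
    remaining: 51
    t11_remaining: 0
    t28_remaining: 13

p3_producer_knockout_remaining: 1
cluster_sizes_k6: [216, 3, 1, 1, 1, 1]
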