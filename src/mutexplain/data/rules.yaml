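# Declarative rule catalogue for the six-branch decision scheme.
#
# Each rule fires when every predicate in `when` evaluates true for the
# analyzed substitution.  `severity` is the rule's base severity; rules
# marked `tier_sensitive` are downgraded one step when their best evidence
# is prediction-only.  `sentence` keys into sentences.yaml.  Branches run
# in the fixed order CONTACTS, DOMAIN, MODIFICATION, VARIANT, CONSERVATION,
# PROPERTIES; the PROPERTIES rule marked `fallback` fires only when no
# other rule of that branch fired, so the branch always says something.

- id: contacts.disulfide_lost
  branch: CONTACTS
  when: [at_disulfide, wild_is_cys, mutant_not_cys]
  severity: SEVERE
  sentence: disulfide_lost
  tier_sensitive: true

- id: contacts.salt_bridge_broken
  branch: CONTACTS
  when: [at_salt_bridge, charge_lost_or_flipped]
  severity: SEVERE
  sentence: salt_bridge_broken
  tier_sensitive: true

- id: contacts.ligand_contact_disturbed
  branch: CONTACTS
  when: [at_ligand_contact, size_or_charge_change]
  severity: SEVERE
  sentence: ligand_contact_disturbed
  tier_sensitive: true

- id: contacts.sidechain_hbond_lost
  branch: CONTACTS
  when: [at_hbond, polar_capacity_lost]
  severity: MODERATE
  sentence: sidechain_hbond_lost
  tier_sensitive: true

- id: domain.transmem_charge
  branch: DOMAIN
  when: [in_transmem, charge_gained]
  severity: SEVERE
  sentence: transmem_charge
  tier_sensitive: true

- id: domain.transmem_hydrophobicity
  branch: DOMAIN
  when: [in_transmem, hydrophobicity_changed]
  severity: MODERATE
  sentence: transmem_hydrophobicity
  tier_sensitive: true

- id: domain.active_site
  branch: DOMAIN
  when: [in_active_site]
  severity: SEVERE
  sentence: active_site
  tier_sensitive: true

- id: domain.helix_breaker
  branch: DOMAIN
  when: [in_helix, helix_breaker_gained]
  severity: SEVERE
  sentence: helix_breaker
  tier_sensitive: true

- id: domain.strand_proline
  branch: DOMAIN
  when: [in_strand, mutant_is_proline]
  severity: SEVERE
  sentence: strand_proline
  tier_sensitive: true

- id: domain.named_region
  branch: DOMAIN
  when: [in_named_region]
  severity: INFO
  sentence: named_region
  tier_sensitive: false

- id: modification.phospho_lost
  branch: MODIFICATION
  when: [at_phospho_site, phospho_acceptor_lost]
  severity: SEVERE
  sentence: phospho_lost
  tier_sensitive: true

- id: modification.phospho_kept
  branch: MODIFICATION
  when: [at_phospho_site, phospho_acceptor_kept]
  severity: MODERATE
  sentence: phospho_kept
  tier_sensitive: true

- id: variant.same_substitution
  branch: VARIANT
  when: [variant_exact_match]
  severity: INFO
  sentence: variant_same
  tier_sensitive: false

- id: variant.known_at_position
  branch: VARIANT
  when: [variant_other]
  severity: INFO
  sentence: variant_other
  tier_sensitive: false

- id: conservation.invariant_position
  branch: CONSERVATION
  when: [cons_strict_and_unseen]
  severity: SEVERE
  sentence: conservation_severe
  tier_sensitive: false

- id: conservation.conserved_position
  branch: CONSERVATION
  when: [cons_moderate]
  severity: MODERATE
  sentence: conservation_moderate
  tier_sensitive: false

- id: conservation.variable_position
  branch: CONSERVATION
  when: [cons_variable_seen]
  severity: INFO
  sentence: conservation_variable
  tier_sensitive: false

- id: properties.core_hydrophobicity
  branch: PROPERTIES
  when: [is_buried, hydrophobicity_decreased]
  severity: SEVERE
  sentence: core_destabilization
  tier_sensitive: true

- id: properties.core_clash
  branch: PROPERTIES
  when: [is_buried, volume_increased, densely_packed]
  severity: SEVERE
  sentence: core_clash
  tier_sensitive: true

- id: properties.core_charge
  branch: PROPERTIES
  when: [is_buried, charge_gained]
  severity: SEVERE
  sentence: core_charge
  tier_sensitive: true

- id: properties.surface_change
  branch: PROPERTIES
  when: [is_exposed, any_significant_change]
  severity: MODERATE
  sentence: surface_change
  tier_sensitive: true

- id: properties.neutral_description
  branch: PROPERTIES
  when: []
  severity: INFO
  sentence: property_summary
  tier_sensitive: false
  fallback: true
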